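"""Design rules for CpG oligodeoxynucleotides (ODN) and their physical
properties.

Generators cover the panels used in uptake experiments: a single central CpG
flanked by thymines at any length >= 4, multiple CpG motifs at a fixed
interdistance, tandem-repeat adducts of a single-CpG core, and the GpC
control in which the central motif is inverted.  Thymine is used as the
flanking base throughout (the TLR-9-compatible convention); the 5'/3'
thymine split places the smaller half 5', which reproduces the canonical
pentamer TCGTT.

Every construction is re-verified with the CpG scanner rather than assumed:
the motif count and interdistances of the emitted sequence are checked
against the design's intent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .motif_census import count_cpg_motifs, find_cpg_sites

__all__ = [
    "OligoSpec",
    "OligoProperties",
    "design_central_cpg",
    "design_spaced_cpg",
    "design_adduct",
    "gpc_control",
    "oligo_properties",
    "central_cpg_panel",
    "multi_cpg_panel",
    "interdistance_panel",
    "adduct_panel",
    "panel_dataframe",
]

# Monophosphate residue masses (g/mol) per synthesis-vendor convention; the
# constant 61.96 removes one HPO3 (-80) and adds water (+18.02).
_BASE_MASS = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.2}
_MASS_OFFSET = 61.96


@dataclass(frozen=True)
class OligoSpec:
    """A designed oligonucleotide: its sequence and design provenance."""

    sequence: str
    design: dict[str, Any] = field(default_factory=dict, compare=False)

    @property
    def n_cpg(self) -> int:
        """CpG motif count, always recomputed from the sequence."""
        return count_cpg_motifs(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def design_central_cpg(length: int) -> OligoSpec:
    """A single central CpG flanked by thymines: T*f5 + CG + T*f3.

    ``f5 = floor((L-2)/2)`` puts the smaller thymine run 5', so L=5 yields
    the pentamer TCGTT.
    """
    if length < 4:
        raise ValueError("central-CpG oligos require length >= 4")
    f5 = (length - 2) // 2
    f3 = length - 2 - f5
    seq = "T" * f5 + "CG" + "T" * f3
    spec = OligoSpec(seq, {"generator": "central_cpg", "L": length})
    assert spec.n_cpg == 1
    return spec


def design_spaced_cpg(n_motifs: int, interdistance: int, total_length: int) -> OligoSpec:
    """``n_motifs`` CpG motifs separated by exactly ``interdistance`` thymines.

    The core is ("CG" + T*d) repeated with the trailing spacer dropped;
    flanking thymines split with floor on the 5' side.  The emitted motif
    spacing is verified with the CpG scanner.
    """
    if n_motifs < 2:
        raise ValueError("spaced design requires n_motifs >= 2")
    if interdistance < 0:
        raise ValueError("interdistance must be >= 0")
    core_len = 2 * n_motifs + (n_motifs - 1) * interdistance
    if core_len > total_length:
        raise ValueError(
            f"core of {core_len} bases does not fit in total_length {total_length}"
        )
    core = ("CG" + "T" * interdistance) * n_motifs
    core = core[:core_len]
    flank = total_length - core_len
    f5 = flank // 2
    seq = "T" * f5 + core + "T" * (flank - f5)
    spec = OligoSpec(
        seq,
        {"generator": "spaced_cpg", "n": n_motifs, "d": interdistance, "L": total_length},
    )
    sites = find_cpg_sites(seq)
    if len(sites) != n_motifs or not all(
        int(g) == interdistance for g in np.diff(sites) - 2
    ):
        raise AssertionError("spaced design failed scanner verification")
    return spec


def design_adduct(core: OligoSpec, repeats: int) -> OligoSpec:
    """Tandem repeat of a core sequence (``repeats`` total copies).

    The motif count of the adduct is verified with the scanner; if the
    junction creates an unintended CpG (core ending in C followed by a copy
    starting with G) a warning reports the actual motif count.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    seq = core.sequence * repeats
    spec = OligoSpec(
        seq,
        {"generator": "adduct", "core": core.sequence, "repeats": repeats},
    )
    expected = repeats * core.n_cpg
    if spec.n_cpg != expected:
        warnings.warn(
            f"adduct junctions created extra CpG motifs: expected {expected}, "
            f"found {spec.n_cpg}",
            stacklevel=2,
        )
    return spec


def gpc_control(oligo: OligoSpec) -> OligoSpec:
    """Replace the single CpG of ``oligo`` with GpC, preserving length."""
    sites = find_cpg_sites(oligo.sequence)
    if len(sites) != 1:
        raise ValueError(
            f"GpC control requires exactly one CpG motif, found {len(sites)}"
        )
    p = int(sites[0])
    seq = oligo.sequence[:p] + "GC" + oligo.sequence[p + 2 :]
    return OligoSpec(seq, {"generator": "gpc_control", "source": oligo.sequence})


@dataclass(frozen=True)
class OligoProperties:
    molecular_weight: float  # g/mol
    gc_fraction: float
    melting_temperature: float  # degrees C
    tm_method: str


def oligo_properties(oligo: OligoSpec, tm_method: str = "auto") -> OligoProperties:
    """Molecular weight, C/G content fraction and melting temperature.

    Tm uses the Wallace rule 2(A+T) + 4(G+C) for short oligos (< 14 nt);
    longer sequences use the nearest-neighbor model by default
    (``tm_method="auto"``).  ``tm_method`` may force ``"wallace"`` or
    ``"nn"``.
    """
    seq = oligo.sequence
    if not seq:
        raise ValueError("empty sequence")
    if "N" in seq:
        raise ValueError("properties are undefined for sequences containing N")
    n = {b: seq.count(b) for b in "ACGT"}
    mw = sum(_BASE_MASS[b] * c for b, c in n.items()) - _MASS_OFFSET
    gc = (n["C"] + n["G"]) / len(seq)
    method = tm_method
    if method == "auto":
        method = "wallace" if len(seq) < 14 else "nn"
    if method == "wallace":
        tm = 2.0 * (n["A"] + n["T"]) + 4.0 * (n["G"] + n["C"])
    elif method == "nn":
        from Bio.SeqUtils import MeltingTemp

        tm = float(MeltingTemp.Tm_NN(seq))
    else:
        raise ValueError(f"unknown tm_method {tm_method!r}")
    return OligoProperties(round(mw, 2), gc, tm, method)


# ---------------------------------------------------------------------------
# Panel builders mirroring the experimental ODN tables.

_CENTRAL_LENGTHS = (5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20, 24, 28, 30, 32, 36, 40)
_MULTI_CPG = ((2, 10), (2, 12), (2, 14), (2, 16), (2, 18), (3, 21), (3, 30), (4, 24), (4, 40))


def central_cpg_panel() -> list[OligoSpec]:
    """Seventeen single-CpG ODNs of lengths 5-40."""
    return [design_central_cpg(L) for L in _CENTRAL_LENGTHS]


def multi_cpg_panel() -> list[OligoSpec]:
    """Length-matched ODNs with 2-4 CpG motifs.

    The motif spacing is not pinned by the experimental tables; motifs are
    spread into equal segments, d = floor((L - 2n) / (n + 1)).
    """
    out = []
    for n, L in _MULTI_CPG:
        d = (L - 2 * n) // (n + 1)
        out.append(design_spaced_cpg(n, d, L))
    return out


def interdistance_panel() -> list[OligoSpec]:
    """Eight 14-mers with two CpG motifs at interdistances 1-8."""
    return [design_spaced_cpg(2, d, 14) for d in range(1, 9)]


def adduct_panel() -> list[OligoSpec]:
    """Single-CpG cores of length 5-10 repeated 1-4 times (24 ODNs)."""
    out = []
    for core_len in range(5, 11):
        core = design_central_cpg(core_len)
        for repeats in range(1, 5):
            out.append(design_adduct(core, repeats))
    return out


def panel_dataframe(panel: list[OligoSpec]):
    """Tabulate a panel: sequence, motif count, length, design, properties."""
    import pandas as pd

    rows = []
    for spec in panel:
        props = oligo_properties(spec)
        rows.append(
            {
                "sequence": spec.sequence,
                "n_cpg": spec.n_cpg,
                "length": len(spec),
                "design": spec.design.get("generator", ""),
                "interdistance": spec.design.get("d", ""),
                "repeats": spec.design.get("repeats", ""),
                "mw": props.molecular_weight,
                "gc_fraction": props.gc_fraction,
                "tm": props.melting_temperature,
            }
        )
    return pd.DataFrame(rows)
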