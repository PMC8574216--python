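"""Manifest-driven FASTA datasets, uptake panels and tabular output.

Genome sequences arrive as plain or gzip-compressed FASTA files grouped into
named datasets by a two-column manifest (``label<TAB>path``, one row per
file).  Every sequence is sanitized to the alphabet ``{A,C,G,T,N}`` before any
downstream scan; FASTA records are the unit of contiguity, so no motif or
window ever spans a record boundary.

Uptake panels map a CpG-centred octamer to a fluorescence readout
(optionally tagged with an experimental condition) and are read from
delimited text.  All tabular outputs are tab-separated with a single header
line; frequencies are written with 12 significant digits so that regression
inputs round-trip bit-stably.
"""

from __future__ import annotations

import gzip
import json
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO as _bio_seqio

__all__ = [
    "SequenceRecord",
    "GenomeDataset",
    "UptakeEntry",
    "UptakePanel",
    "sanitize_sequence",
    "read_fasta_dataset",
    "read_manifest",
    "load_dataset",
    "read_uptake_panel",
    "write_census_tsv",
    "read_census_tsv",
    "write_spectrum_tsv",
    "read_spectrum_tsv",
    "write_run_metadata",
]

# IUPAC nucleotide codes accepted on input; everything outside this set is a
# hard error naming the character and its offset.
_IUPAC_UPPER = "ACGTUNRYSWKMBDHV"
_BAD_CHAR_RE = re.compile(f"[^{_IUPAC_UPPER}{_IUPAC_UPPER.lower()}]")
_LOWER_TO_N = str.maketrans({c: "N" for c in _IUPAC_UPPER.lower()})
_CANONICALIZE = str.maketrans(
    {**{c: "N" for c in "RYSWKMBDHV"}, "U": "T"}
)


def sanitize_sequence(raw: str, mask_lowercase: bool = False) -> str:
    """Return ``raw`` mapped onto the alphabet ``{A,C,G,T,N}``.

    Whitespace is removed, lowercase (soft-masked) bases are uppercased, U is
    mapped to T, and every IUPAC ambiguity code other than A/C/G/T becomes N.
    With ``mask_lowercase=True`` soft-masked bases are mapped to N instead,
    which excludes masked windows from all downstream counting.

    Raises ``ValueError`` on any non-IUPAC character, naming the character
    and its offset in the whitespace-stripped input.
    """
    compact = "".join(raw.split())
    bad = _BAD_CHAR_RE.search(compact)
    if bad is not None:
        raise ValueError(
            f"invalid sequence character {bad.group()!r} at offset {bad.start()}"
        )
    if mask_lowercase:
        compact = compact.translate(_LOWER_TO_N)
    return compact.upper().translate(_CANONICALIZE)


@dataclass(frozen=True)
class SequenceRecord:
    """One sanitized FASTA record (a chromosome, contig or plasmid)."""

    record_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeDataset:
    """A labeled collection of sanitized records for one species or group."""

    label: str
    records: list[SequenceRecord] = field(default_factory=list)

    @property
    def total_bases(self) -> int:
        """Total A/C/G/T/N characters summed over records."""
        return sum(len(r) for r in self.records)

    def __iter__(self):
        return iter(self.records)


def read_fasta_dataset(
    label: str,
    paths: Sequence[str | Path],
    mask_lowercase: bool = False,
) -> GenomeDataset:
    """Read one dataset from FASTA (plain or ``.gz``) files.

    Records are sanitized individually and never concatenated across files or
    headers.  Missing files, empty datasets and duplicate record ids are
    fatal.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"dataset {label!r}: missing FASTA file {path}")
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as handle:
            for rec in _bio_seqio.parse(handle, "fasta"):
                if not rec.id:
                    raise ValueError(f"dataset {label!r}: empty record id in {path}")
                if rec.id in seen:
                    raise ValueError(
                        f"dataset {label!r}: duplicate record id {rec.id!r}"
                    )
                seen.add(rec.id)
                records.append(
                    SequenceRecord(rec.id, sanitize_sequence(str(rec.seq), mask_lowercase))
                )
    if not records:
        raise ValueError(f"dataset {label!r} contains no sequence records")
    return GenomeDataset(label, records)


def read_manifest(path: str | Path) -> dict[str, list[Path]]:
    """Read a TSV manifest with columns ``label`` and ``path``.

    A label may appear on several rows; its files are kept in row order.
    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("label", "path"):
        if col not in table.columns:
            raise ValueError(f"manifest {path} lacks required column {col!r}")
    out: dict[str, list[Path]] = {}
    for label, fname in zip(table["label"], table["path"]):
        p = Path(fname)
        if not p.is_absolute():
            p = path.parent / p
        out.setdefault(str(label), []).append(p)
    return out


def load_dataset(
    manifest_path: str | Path, label: str, mask_lowercase: bool = False
) -> GenomeDataset:
    """Load one labeled dataset through the manifest."""
    manifest = read_manifest(manifest_path)
    if label not in manifest:
        raise KeyError(f"label {label!r} not present in manifest {manifest_path}")
    return read_fasta_dataset(label, manifest[label], mask_lowercase)


@dataclass(frozen=True)
class UptakeEntry:
    octamer: str
    value: float
    condition: str | None = None


@dataclass
class UptakePanel:
    """Octamer -> fluorescence readout measurements, in file order."""

    entries: list[UptakeEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def octamers(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.octamer not in seen:
                seen.append(e.octamer)
        return seen

    def conditions(self) -> list[str | None]:
        out: list[str | None] = []
        for e in self.entries:
            if e.condition not in out:
                out.append(e.condition)
        return out

    def mean_by_octamer(self, normalize: bool = True) -> dict[str, float]:
        """Average each octamer's readout across conditions.

        With ``normalize=True`` each condition's values are first divided by
        that condition's mean, so that differently scaled experimental
        approaches (e.g. a FITC label versus an intercalating dye) contribute
        equally; the per-octamer arithmetic mean over conditions is returned.
        """
        by_cond: dict[str | None, dict[str, float]] = {}
        for e in self.entries:
            by_cond.setdefault(e.condition, {})[e.octamer] = e.value
        if normalize and len(by_cond) > 1:
            for cond, vals in by_cond.items():
                mean = sum(vals.values()) / len(vals)
                if mean <= 0:
                    raise ValueError(f"condition {cond!r} has non-positive mean value")
                by_cond[cond] = {o: v / mean for o, v in vals.items()}
        out: dict[str, list[float]] = {}
        for o in self.octamers():
            out[o] = [vals[o] for vals in by_cond.values() if o in vals]
        return {o: sum(v) / len(v) for o, v in out.items()}

    def validate(self) -> None:
        seen: set[tuple[str, str | None]] = set()
        for i, e in enumerate(self.entries):
            if len(e.octamer) != 8 or e.octamer[3:5] != "CG":
                raise ValueError(
                    f"row {i}: octamer {e.octamer!r} lacks a central CpG "
                    "(positions 4-5 must be C,G)"
                )
            if not math.isfinite(e.value) or e.value < 0:
                raise ValueError(f"row {i}: value {e.value!r} is not a finite "
                                 "non-negative number")
            key = (e.octamer, e.condition)
            if key in seen:
                raise ValueError(f"row {i}: duplicate octamer {e.octamer!r} "
                                 f"for condition {e.condition!r}")
            seen.add(key)


def read_uptake_panel(path: str | Path) -> UptakePanel:
    """Read a TSV/CSV uptake panel with columns octamer, value[, condition]."""
    table = pd.read_csv(path, sep=None, engine="python", skipinitialspace=True)
    table.columns = [str(c).strip().lower() for c in table.columns]
    for col in ("octamer", "value"):
        if col not in table.columns:
            raise ValueError(f"uptake panel {path} lacks required column {col!r}")
    entries = []
    for i, row in table.iterrows():
        octamer = str(row["octamer"]).strip().upper()
        try:
            value = float(row["value"])
        except (TypeError, ValueError):
            raise ValueError(
                f"uptake panel {path} row {i}: non-numeric value {row['value']!r}"
            ) from None
        condition = None
        if "condition" in table.columns and not pd.isna(row["condition"]):
            condition = str(row["condition"]).strip()
        entries.append(UptakeEntry(octamer, value, condition))
    panel = UptakePanel(entries)
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# Tabular output.  Frequencies are formatted with 12 significant digits;
# counts are written exactly, so re-reading a table reproduces all counts.

_FREQ_FMT = "{:.12g}"


def write_census_tsv(census, path: str | Path, all_octamers: bool = False) -> None:
    """Write an octamer census as TSV (octamer, count, relfreq, n_cpg_in_octamer).

    By default only observed octamers are written; ``all_octamers=True``
    writes the full 4,096-row table.
    """
    from .motif_census import count_cpg_motifs, index_to_octamer

    relfreq = census.relfreq
    with open(path, "w") as fh:
        fh.write(f"# label={census.dataset_label}\n")
        fh.write(f"# total_cpg_sites={census.total_cpg_sites}\n")
        fh.write(f"# total_bases={census.total_bases}\n")
        fh.write("octamer\tcount\trelfreq\tn_cpg_in_octamer\n")
        for i in range(4096):
            if census.counts[i] == 0 and not all_octamers:
                continue
            octamer = index_to_octamer(i)
            fh.write(
                f"{octamer}\t{census.counts[i]}\t"
                f"{_FREQ_FMT.format(relfreq[i])}\t{count_cpg_motifs(octamer)}\n"
            )


def read_census_tsv(path: str | Path):
    """Re-read a census table written by :func:`write_census_tsv`."""
    from .motif_census import OctamerCensus, octamer_to_index
    import numpy as np

    meta = _read_meta(path)
    table = pd.read_csv(path, sep="\t", comment="#")
    counts = np.zeros(4096, dtype=np.int64)
    for octamer, count in zip(table["octamer"], table["count"]):
        counts[octamer_to_index(str(octamer))] = int(count)
    return OctamerCensus(
        dataset_label=meta.get("label", ""),
        counts=counts,
        total_cpg_sites=int(meta.get("total_cpg_sites", counts.sum())),
        total_bases=int(meta.get("total_bases", 0)),
    )


def write_spectrum_tsv(spectrum, path: str | Path) -> None:
    """Write an interdistance spectrum as TSV (interdistance, count, relfreq)."""
    relfreq = spectrum.relfreq
    with open(path, "w") as fh:
        fh.write(f"# label={spectrum.dataset_label}\n")
        fh.write(f"# total_bases={spectrum.total_bases}\n")
        fh.write(f"# max_id={spectrum.max_id}\n")
        fh.write("interdistance\tcount\trelfreq\n")
        for d in range(spectrum.max_id + 1):
            if spectrum.counts[d]:
                fh.write(f"{d}\t{spectrum.counts[d]}\t{_FREQ_FMT.format(relfreq[d])}\n")
        if spectrum.overflow:
            over_rf = spectrum.overflow / spectrum.total_bases if spectrum.total_bases else 0.0
            fh.write(f"overflow\t{spectrum.overflow}\t{_FREQ_FMT.format(over_rf)}\n")


def read_spectrum_tsv(path: str | Path):
    """Re-read a spectrum table written by :func:`write_spectrum_tsv`."""
    from .motif_census import InterdistanceSpectrum
    import numpy as np

    meta = _read_meta(path)
    max_id = int(meta["max_id"])
    counts = np.zeros(max_id + 1, dtype=np.int64)
    overflow = 0
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"interdistance": str})
    for d, count in zip(table["interdistance"], table["count"]):
        if str(d) == "overflow":
            overflow = int(count)
        else:
            counts[int(d)] = int(count)
    return InterdistanceSpectrum(
        dataset_label=meta.get("label", ""),
        counts=counts,
        overflow=overflow,
        total_bases=int(meta.get("total_bases", 0)),
    )


def _read_meta(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    return meta


def write_run_metadata(path: str | Path, metadata: Mapping) -> None:
    """Write run metadata (seeds, parameters, inputs) as JSON."""
    with open(path, "w") as fh:
        json.dump(dict(metadata), fh, indent=2, sort_keys=True)
        fh.write("\n")
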