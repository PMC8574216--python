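"""CpG motif location, interdistance spectra and the CpG-centred octamer census.

A CpG motif is the dinucleotide 5'-CG-3'.  Two quantities summarize a
genome's CpG context:

* the **interdistance spectrum**: for successive motifs on the same record,
  the number of bases strictly between the G of one motif and the C of the
  next (start-to-start distance minus 2), tallied over the whole dataset and
  expressed relative to the dataset's total base count.  Genomic spectra show
  local maxima at interdistances 1, 4, 7, 10 (d = 3x - 2, i.e. d = 1 mod 3),
  the codon-period spacing of motif starts;
* the **octamer census**: counts over the 4,096 8-mers with a central CpG
  (positions 1-2-3-C-G-6-7-8).  Windows extend 3 bases either side of the
  motif; windows that leave the record or contain N are skipped while the
  motif itself still counts toward ``total_cpg_sites``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .seqio import GenomeDataset

__all__ = [
    "BASES",
    "InterdistanceSpectrum",
    "OctamerCensus",
    "PeakScan",
    "encode",
    "decode",
    "revcomp",
    "find_cpg_sites",
    "count_cpg_motifs",
    "interdistance_spectrum",
    "detect_periodic_peaks",
    "octamer_census",
    "octamer_to_index",
    "index_to_octamer",
    "all_octamers",
    "single_cpg_mask",
]

BASES = "ACGT"

# byte -> code: A=0 C=1 G=2 T=3, everything else (incl. N) = 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_POWERS = (4 ** np.arange(5, -1, -1)).astype(np.int64)
_WINDOW_OFFSETS = np.arange(-3, 5)
_FLANK_IN_WINDOW = np.array([0, 1, 2, 5, 6, 7])

# digits[i] = the six flank base codes of octamer index i (positions 1,2,3,6,7,8)
_DIGITS = np.stack(
    [(np.arange(4096) // p) % 4 for p in _POWERS], axis=1
).astype(np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a sanitized sequence as uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def find_cpg_sites(seq: str) -> np.ndarray:
    """0-based positions p with seq[p] == 'C' and seq[p+1] == 'G', ascending."""
    if len(seq) < 2:
        return np.empty(0, dtype=np.int64)
    codes = encode(seq)
    return _find_sites(codes)


def _find_sites(codes: np.ndarray) -> np.ndarray:
    if codes.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.nonzero((codes[:-1] == 1) & (codes[1:] == 2))[0].astype(np.int64)


def count_cpg_motifs(seq: str) -> int:
    """Number of CpG motifs in ``seq`` (length of :func:`find_cpg_sites`)."""
    return int(find_cpg_sites(seq).size)


def octamer_to_index(octamer: str) -> int:
    """Bijection from a CpG-centred octamer to 0..4095 via its six flank bases."""
    if len(octamer) != 8 or octamer[3:5] != "CG":
        raise ValueError(f"{octamer!r} is not an 8-mer with a central CpG")
    codes = encode(octamer)
    if (codes >= 4).any():
        raise ValueError(f"{octamer!r} contains a non-ACGT base")
    return int(codes[_FLANK_IN_WINDOW] @ _POWERS)


def index_to_octamer(index: int) -> str:
    if not 0 <= index < 4096:
        raise ValueError(f"octamer index {index} out of range 0..4095")
    d = _DIGITS[index]
    flank = decode(d)
    return flank[:3] + "CG" + flank[3:]

def all_octamers() -> list[str]:
    """All 4,096 CpG-centred octamers, in index (= lexicographic) order."""
    return [index_to_octamer(i) for i in range(4096)]


_SINGLE_CPG_MASK: np.ndarray | None = None


def single_cpg_mask() -> np.ndarray:
    """Boolean mask over the 4,096 octamers: True iff the only CpG is the central one."""
    global _SINGLE_CPG_MASK
    if _SINGLE_CPG_MASK is None:
        _SINGLE_CPG_MASK = np.array(
            [count_cpg_motifs(index_to_octamer(i)) == 1 for i in range(4096)]
        )
    return _SINGLE_CPG_MASK.copy()


@dataclass
class InterdistanceSpectrum:
    """CpG interdistance counts for one dataset.

    ``counts[d]`` tallies interdistance d for 0 <= d <= max_id; larger
    interdistances are pooled in ``overflow``.  Relative frequency divides by
    the dataset's total base count.
    """

    dataset_label: str
    counts: np.ndarray
    overflow: int
    total_bases: int

    @property
    def max_id(self) -> int:
        return len(self.counts) - 1

    @property
    def relfreq(self) -> np.ndarray:
        if self.total_bases == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.total_bases

    def as_dict(self) -> dict[int, int]:
        """Non-zero tabulated counts as {interdistance: count} (overflow excluded)."""
        return {int(d): int(c) for d, c in enumerate(self.counts) if c}


def interdistance_spectrum(dataset: GenomeDataset, max_id: int = 1000) -> InterdistanceSpectrum:
    """Tally CpG interdistances per record; no gap spans a record boundary."""
    if max_id < 1:
        raise ValueError("max_id must be >= 1")
    counts = np.zeros(max_id + 1, dtype=np.int64)
    overflow = 0
    for rec in dataset.records:
        sites = find_cpg_sites(rec.sequence)
        if sites.size < 2:
            continue
        gaps = np.diff(sites) - 2
        clipped = gaps[gaps <= max_id]
        counts += np.bincount(clipped, minlength=max_id + 1)
        overflow += int((gaps > max_id).sum())
    return InterdistanceSpectrum(dataset.label, counts, overflow, dataset.total_bases)


@dataclass
class PeakScan:
    """Local maxima of an interdistance spectrum and the 3x-2 periodicity flag."""

    peaks: list[int]
    all_period3: bool


def detect_periodic_peaks(
    spectrum: InterdistanceSpectrum, d_min: int = 1, d_max: int = 20
) -> PeakScan:
    """Find strict local maxima in [d_min, d_max] and test the 3x-2 pattern.

    A distance d is a peak iff counts[d] > counts[d-1] and counts[d] >
    counts[d+1].  The flag is true iff every peak in range satisfies
    d = 1 (mod 3) and every member of {1, 4, 7, 10} within the range is a
    peak.  An all-zero range yields no peaks and a false flag.
    """
    if d_min < 1:
        raise ValueError("d_min must be >= 1")
    if d_max > spectrum.max_id - 1:
        raise ValueError("d_max must be <= spectrum.max_id - 1")
    if d_max < d_min:
        raise ValueError("d_max must be >= d_min")
    counts = spectrum.counts
    if not counts[d_min : d_max + 1].any():
        return PeakScan([], False)
    peaks = [
        d
        for d in range(d_min, d_max + 1)
        if counts[d] > counts[d - 1] and counts[d] > counts[d + 1]
    ]
    expected = [d for d in (1, 4, 7, 10) if d_min <= d <= d_max]
    ok = bool(peaks) and all(d % 3 == 1 for d in peaks) and all(d in peaks for d in expected)
    return PeakScan(peaks, ok)


@dataclass
class OctamerCensus:
    """Counts over the 4,096 CpG-centred octamers for one dataset."""

    dataset_label: str
    counts: np.ndarray
    total_cpg_sites: int
    total_bases: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4096,):
            raise ValueError("octamer census requires a length-4096 count vector")

    @property
    def total_windows(self) -> int:
        return int(self.counts.sum())

    @property
    def relfreq(self) -> np.ndarray:
        """Relative frequency normalized by total valid windows (sums to 1)."""
        total = self.total_windows
        if total == 0:
            return np.zeros(4096)
        return self.counts / total

    def relfreq_per_base(self) -> np.ndarray:
        """Alternative normalization by dataset total bases (mirrors the
        interdistance convention)."""
        if self.total_bases == 0:
            raise ValueError("census carries no total_bases to normalize by")
        return self.counts / self.total_bases


def _census_codes(codes: np.ndarray) -> tuple[np.ndarray, int]:
    """Count windows in one encoded record; return (bincount-4096, n sites)."""
    sites = _find_sites(codes)
    n = codes.size
    if sites.size == 0:
        return np.zeros(4096, dtype=np.int64), 0
    inside = sites[(sites >= 3) & (sites + 5 <= n)]
    if inside.size == 0:
        return np.zeros(4096, dtype=np.int64), int(sites.size)
    windows = codes[inside[:, None] + _WINDOW_OFFSETS]
    valid = (windows < 4).all(axis=1)
    flanks = windows[valid][:, _FLANK_IN_WINDOW].astype(np.int64)
    idx = flanks @ _POWERS
    return np.bincount(idx, minlength=4096), int(sites.size)


def octamer_census(dataset: GenomeDataset, both_strands: bool = False) -> OctamerCensus:
    """Count CpG-centred octamer windows across a dataset.

    Forward strand only by default; with ``both_strands=True`` the reverse
    complement of every record is scanned as well (sites and windows from
    both strands are summed).
    """
    counts = np.zeros(4096, dtype=np.int64)
    total_sites = 0
    for rec in dataset.records:
        codes = encode(rec.sequence)
        c, s = _census_codes(codes)
        counts += c
        total_sites += s
        if both_strands:
            c, s = _census_codes(encode(revcomp(rec.sequence)))
            counts += c
            total_sites += s
    return OctamerCensus(dataset.label, counts, total_sites, dataset.total_bases)
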