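"""Octamer ranking, top-k comparison, flanking composition and similarity.

Comparative summaries built on the octamer census: rank orders over the
4,096 CpG-centred octamers, overlap of top-k lists between datasets, the
6 x 4 positional composition of the bases flanking the central CpG, Pearson
similarity of composition matrices between datasets, and the selection of
representative octamers (most frequent, single-CpG, exclusive to one
dataset's top-k) used to design oligonucleotides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motif_census import (
    _DIGITS,
    BASES,
    OctamerCensus,
    index_to_octamer,
    single_cpg_mask,
)

__all__ = [
    "RankedList",
    "CompositionMatrix",
    "rank_octamers",
    "top_octamers",
    "topk_overlap",
    "positional_composition",
    "composition_from_weights",
    "composition_similarity",
    "select_representative_octamers",
]

FLANK_POSITIONS = (1, 2, 3, 6, 7, 8)  # 1-based octamer positions around the CpG


@dataclass
class RankedList:
    """All 4,096 octamers ordered from most to least frequent.

    Ties are broken lexicographically; unobserved octamers follow the
    observed, lexicographically, so ranks are a permutation of 1..4096.
    """

    dataset_label: str
    octamers: list[str]
    counts: np.ndarray
    relfreq: np.ndarray

    def rank_of(self, octamer: str) -> int:
        """1-based rank of ``octamer``."""
        return self.octamers.index(octamer) + 1

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, 4097),
                "octamer": self.octamers,
                "count": self.counts,
                "relfreq": self.relfreq,
            }
        )


def rank_octamers(census: OctamerCensus) -> RankedList:
    """Rank octamers by descending count, lexicographic on ties."""
    counts = census.counts
    # index order is lexicographic octamer order, so a stable sort on -count
    # realizes the tie-break and places unobserved octamers lexicographically.
    order = np.argsort(-counts, kind="stable")
    relfreq = census.relfreq
    return RankedList(
        dataset_label=census.dataset_label,
        octamers=[index_to_octamer(int(i)) for i in order],
        counts=counts[order].copy(),
        relfreq=relfreq[order].copy(),
    )


def top_octamers(census: OctamerCensus, k: int = 20) -> list[str]:
    """The up-to-k most frequent *observed* octamers, in rank order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = rank_octamers(census)
    out = []
    for octamer, count in zip(ranked.octamers, ranked.counts):
        if count == 0 or len(out) == k:
            break
        out.append(octamer)
    return out


def topk_overlap(census_a: OctamerCensus, census_b: OctamerCensus, k: int = 20) -> int:
    """Number of octamers shared between the two censuses' top-k lists."""
    return len(set(top_octamers(census_a, k)) & set(top_octamers(census_b, k)))


@dataclass
class CompositionMatrix:
    """Base frequencies at the six positions flanking the central CpG.

    ``freq`` is 6 x 4; rows follow octamer positions 1,2,3,6,7,8 and columns
    the bases A,C,G,T.  Every row sums to 1 for a non-empty source census.
    """

    dataset_label: str
    freq: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freq,
            index=[f"pos{p}" for p in FLANK_POSITIONS],
            columns=list(BASES),
        )


def composition_from_weights(weights: np.ndarray, label: str = "") -> CompositionMatrix:
    """Positional composition implied by a non-negative weight vector over
    the 4,096 octamers (weights are normalized to sum to 1)."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (4096,) or (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be a non-negative length-4096 vector "
                         "with positive sum")
    w = weights / weights.sum()
    freq = np.zeros((6, 4))
    for base in range(4):
        freq[:, base] = w @ (_DIGITS == base)
    return CompositionMatrix(label, freq)


def positional_composition(
    census: OctamerCensus, weighted: bool = True
) -> CompositionMatrix:
    """Occurrence-weighted base frequencies at the six flank positions.

    With ``weighted=False`` every distinct observed octamer contributes
    equally (a sensitivity-analysis mode).
    """
    if census.total_windows == 0:
        raise ValueError(f"census {census.dataset_label!r} has no octamer windows")
    weights = census.counts.astype(float) if weighted else (census.counts > 0).astype(float)
    return composition_from_weights(weights, census.dataset_label)


def composition_similarity(
    a: CompositionMatrix, b: CompositionMatrix, mode: str = "flat"
) -> float:
    """Pearson correlation between two composition matrices.

    ``mode="flat"`` (default) correlates the 24 paired entries;
    ``mode="per-position"`` averages the six row-wise correlations.  Zero
    variance in either input makes the coefficient undefined: NaN is
    returned with a warning.
    """
    if mode == "flat":
        return _pearson(a.freq.ravel(), b.freq.ravel())
    if mode == "per-position":
        rs = [_pearson(a.freq[i], b.freq[i]) for i in range(6)]
        return float(np.mean(rs))
    raise ValueError(f"unknown mode {mode!r}")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        warnings.warn(
            "composition similarity undefined: zero variance in an input",
            stacklevel=3,
        )
        return float("nan")
    return float((xd * yd).sum() / denom)


def select_representative_octamers(
    censuses: Mapping[str, OctamerCensus],
    n_select: int = 3,
    k_top: int = 20,
    rule: str = "exclusive",
) -> dict[str, list[str]]:
    """Pick each dataset's representative octamers from its own top-k list.

    Within a dataset's top-``k_top`` observed octamers (rank order), an
    octamer is eligible iff it contains exactly one CpG motif (the central
    one) and, under ``rule="exclusive"``, is absent from every other
    dataset's top-k; under ``rule="shared-at-most-once"`` it may appear in at
    most one other dataset's top-k.  The first ``n_select`` eligible octamers
    are returned per dataset; a warning is raised for datasets with fewer.
    """
    if len(censuses) < 2:
        raise ValueError("representative selection requires at least two censuses")
    if rule not in ("exclusive", "shared-at-most-once"):
        raise ValueError(f"unknown exclusivity rule {rule!r}")
    mask = single_cpg_mask()
    tops = {label: top_octamers(c, k_top) for label, c in censuses.items()}
    top_sets = {label: set(t) for label, t in tops.items()}
    picks: dict[str, list[str]] = {}
    for label in censuses:
        chosen: list[str] = []
        for octamer in tops[label]:
            from .motif_census import octamer_to_index

            if not mask[octamer_to_index(octamer)]:
                continue
            n_shared = sum(
                octamer in top_sets[other] for other in censuses if other != label
            )
            limit = 0 if rule == "exclusive" else 1
            if n_shared > limit:
                continue
            chosen.append(octamer)
            if len(chosen) == n_select:
                break
        if len(chosen) < n_select:
            warnings.warn(
                f"dataset {label!r}: only {len(chosen)} of {n_select} "
                "representative octamers are eligible",
                stacklevel=2,
            )
        picks[label] = chosen
    return picks
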