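"""Synthetic genomes, uptake panels and assay tables with planted structure.

The generators emulate the three experimental inputs of the pipeline so
every stage is testable without multi-gigabyte downloads:

* **genomes** with a tunable CpG placement law (supporting period-3 peaks at
  interdistances 1, 4, 7, 10) and CpG-flank octamer composition drawn from a
  4,096-weight vector.  The i.i.d. background is scrubbed of accidental CG
  dinucleotides (the C is rewritten to A) so that the planted motifs are the
  only CpG sites and ground truth stays exact;
* **uptake panels** generated from a planted linear relation between one
  species' octamer frequencies and fluorescence, plus Gaussian noise;
* **assay tables**, balanced two-factor (species-of-origin x octamer rank)
  replicate designs with planted group effects.

Flank contexts can only be written around a CpG whose neighbours are at
least 7 bases of interdistance away; closer motifs keep the CG-free
background in their flanks (counted in ``n_context_skipped``).  Recovery of
planted octamer weights by the census therefore requires an interdistance
law supported on d >= 7, while periodicity recovery needs only the CG
placements.  Exact recovery also requires weights supported on single-CpG
octamers: a flank containing its own CG would create extra census windows.

All draws come from one ``numpy.random.default_rng`` stream per artifact;
identical seeds give identical outputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motif_census import (
    _DIGITS,
    OctamerCensus,
    _find_sites,
    decode,
    index_to_octamer,
    single_cpg_mask,
)
from .seqio import GenomeDataset, SequenceRecord, UptakeEntry, UptakePanel

__all__ = [
    "GenomeSimConfig",
    "GenomeGroundTruth",
    "UptakeSimConfig",
    "UptakeGroundTruth",
    "generate_genome",
    "generate_uptake_panel",
    "generate_assay_table",
    "periodic_interdistance_law",
    "uniform_interdistance_law",
    "single_cpg_weights",
]

# minimum interdistance to both neighbours for a flank context to be written
# without colliding with another planted motif's flanks or junctions
_CONTEXT_CLEARANCE = 7


def periodic_interdistance_law(
    d_max: int = 12,
    peaks: Sequence[int] = (1, 4, 7, 10),
    peak_boost: float = 8.0,
    decay: float = 0.7,
) -> dict[int, float]:
    """A placement law with boosted mass at the 3x-2 interdistances.

    The baseline decays geometrically with distance, as genomic spectra do
    over the short range studied here; each peak distance carries
    ``peak_boost`` times its baseline mass, so every planted peak dominates
    both neighbours in expectation.
    """
    weights = {d: decay**d for d in range(d_max + 1)}
    for d in peaks:
        weights[d] *= peak_boost
    total = sum(weights.values())
    return {d: w / total for d, w in weights.items()}


def uniform_interdistance_law(d_min: int = 7, d_max: int = 20) -> dict[int, float]:
    """Uniform law on [d_min, d_max]; d_min >= 7 keeps every flank writable."""
    n = d_max - d_min + 1
    return {d: 1.0 / n for d in range(d_min, d_max + 1)}


def single_cpg_weights(
    rng: np.random.Generator | None = None, n_support: int | None = None
) -> np.ndarray:
    """A 4,096-weight vector supported on single-CpG octamers.

    Weights are uniform when ``rng`` is None and i.i.d. uniform(0, 1)
    otherwise.  ``n_support`` restricts the support to that many octamers
    (chosen at random with ``rng``, lexicographically first without),
    emulating the concentrated flank composition of real genomes.
    """
    mask = single_cpg_mask()
    support = np.nonzero(mask)[0]
    if n_support is not None:
        if not 1 <= n_support <= support.size:
            raise ValueError(f"n_support must be in 1..{support.size}")
        if rng is None:
            support = support[:n_support]
        else:
            support = rng.choice(support, size=n_support, replace=False)
    weights = np.zeros(4096)
    weights[support] = 1.0 if rng is None else rng.uniform(size=support.size)
    return weights / weights.sum()


@dataclass
class GenomeSimConfig:
    seed: int
    n_records: int = 4
    record_length: int = 50_000
    background_base_freqs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    n_cpg_insertions: int = 3_000
    interdistance_law: Mapping[int, float] | None = None  # default: period-3 peaked
    flank_octamer_weights: np.ndarray | None = None  # default: uniform single-CpG
    label: str = "SIM"

    def __post_init__(self):
        freqs = np.asarray(self.background_base_freqs, dtype=float)
        if freqs.shape != (4,) or (freqs < 0).any() or abs(freqs.sum() - 1) > 1e-9:
            raise ValueError("background_base_freqs must be 4 frequencies summing to 1")
        if self.interdistance_law is not None:
            probs = np.array(list(self.interdistance_law.values()), dtype=float)
            if (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
                raise ValueError("interdistance_law must be a probability map")
        if self.flank_octamer_weights is not None:
            w = np.asarray(self.flank_octamer_weights, dtype=float)
            if w.shape != (4096,) or (w < 0).any() or w.sum() <= 0:
                raise ValueError(
                    "flank_octamer_weights must be 4,096 non-negative weights "
                    "with positive sum"
                )


@dataclass
class GenomeGroundTruth:
    """What was planted: motif positions, gap multiset, context multiset."""

    seed: int
    cpg_positions: dict[str, np.ndarray]
    intended_gaps: Counter
    placed_octamers: Counter  # octamer index -> count, contexts actually written
    n_context_skipped: int
    flank_weights: np.ndarray
    law: dict[int, float]

    def placed_weight_relfreq(self) -> np.ndarray:
        """Empirical distribution of the written contexts over the 4,096 octamers."""
        out = np.zeros(4096)
        for idx, c in self.placed_octamers.items():
            out[idx] = c
        total = out.sum()
        if total == 0:
            raise ValueError("no octamer contexts were written")
        return out / total


def generate_genome(config: GenomeSimConfig) -> tuple[GenomeDataset, GenomeGroundTruth]:
    """Simulate a genome dataset with planted CpG spacing and flank contexts."""
    rng = np.random.default_rng(config.seed)
    law = dict(config.interdistance_law or periodic_interdistance_law())
    gap_values = np.array(sorted(law), dtype=np.int64)
    gap_probs = np.array([law[int(d)] for d in gap_values])
    weights = (
        np.asarray(config.flank_octamer_weights, dtype=float)
        if config.flank_octamer_weights is not None
        else single_cpg_weights()
    )
    weights = weights / weights.sum()
    weights_single_cpg = weights[~single_cpg_mask()].sum() == 0

    records: list[SequenceRecord] = []
    positions_by_record: dict[str, np.ndarray] = {}
    intended_gaps: Counter = Counter()
    placed: Counter = Counter()
    n_skipped = 0
    remaining = config.n_cpg_insertions

    for r in range(config.n_records):
        L = config.record_length
        codes = rng.choice(4, size=L, p=config.background_base_freqs).astype(np.uint8)
        # scrub accidental background CG dinucleotides (C -> A); rewrites
        # cannot create new CG pairs and cannot overlap each other
        bg_cg = np.nonzero((codes[:-1] == 1) & (codes[1:] == 2))[0]
        codes[bg_cg] = 0

        # each motif consumes >= 2 bases, so one batch of draws always suffices
        gap_batch = rng.choice(gap_values, size=min(remaining, L // 2 + 1), p=gap_probs)
        positions: list[int] = []
        p = 3
        n_placed_here = 0
        while remaining > 0 and p + 1 <= L - 1:
            positions.append(p)
            remaining -= 1
            gap = int(gap_batch[n_placed_here])
            n_placed_here += 1
            next_p = p + 2 + gap
            if remaining > 0 and next_p + 1 <= L - 1:
                intended_gaps[gap] += 1
            p = next_p
        pos = np.array(positions, dtype=np.int64)
        record_id = f"sim{r}"
        positions_by_record[record_id] = pos
        if pos.size:
            codes[pos] = 1
            codes[pos + 1] = 2
            oct_idx = rng.choice(4096, size=pos.size, p=weights)
            for i, c in enumerate(pos):
                c = int(c)
                if c - 3 < 0 or c + 4 > L - 1:
                    n_skipped += 1
                    continue
                if i > 0 and (c - int(pos[i - 1]) - 2) < _CONTEXT_CLEARANCE:
                    n_skipped += 1
                    continue
                if i + 1 < pos.size and (int(pos[i + 1]) - c - 2) < _CONTEXT_CLEARANCE:
                    n_skipped += 1
                    continue
                digits = _DIGITS[oct_idx[i]]
                codes[c - 3 : c] = digits[:3]
                codes[c + 2 : c + 5] = digits[3:]
                # junction fixes: flank edges may pair with background bases
                if c - 4 >= 0 and codes[c - 4] == 1 and codes[c - 3] == 2:
                    codes[c - 4] = 0  # C -> A
                if c + 5 < L and codes[c + 4] == 1 and codes[c + 5] == 2:
                    codes[c + 5] = 3  # G -> T
                placed[int(oct_idx[i])] += 1
        if weights_single_cpg:
            actual = _find_sites(codes)
            if not np.array_equal(actual, pos):
                raise RuntimeError(
                    "internal error: planted CpG positions do not match the "
                    "scanned record"
                )
        records.append(SequenceRecord(record_id, decode(codes)))

    if remaining > 0:
        raise ValueError(
            f"records too short for requested insertions: {remaining} of "
            f"{config.n_cpg_insertions} CpG motifs could not be placed"
        )
    dataset = GenomeDataset(config.label, records)
    truth = GenomeGroundTruth(
        seed=config.seed,
        cpg_positions=positions_by_record,
        intended_gaps=intended_gaps,
        placed_octamers=placed,
        n_context_skipped=n_skipped,
        flank_weights=weights,
        law=law,
    )
    return dataset, truth


@dataclass
class UptakeSimConfig:
    seed: int
    target_species_census: OctamerCensus
    n_octamers: int = 31
    slope: float = 1.5e6
    intercept: float = 150.0
    noise_sd: float = 40.0
    frequency_mode: str = "raw"  # or "normalized"
    reference_census: OctamerCensus | None = None
    condition: str | None = None

    def __post_init__(self):
        if self.n_octamers < 3:
            raise ValueError("n_octamers must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.frequency_mode not in ("raw", "normalized"):
            raise ValueError(f"unknown frequency_mode {self.frequency_mode!r}")
        if self.frequency_mode == "normalized" and self.reference_census is None:
            raise ValueError("normalized mode requires a reference_census")


@dataclass
class UptakeGroundTruth:
    seed: int
    octamer_indices: np.ndarray
    frequencies: np.ndarray
    slope: float
    intercept: float
    noise_sd: float
    n_floored: int  # draws clipped at zero to satisfy non-negativity


def generate_uptake_panel(config: UptakeSimConfig) -> tuple[UptakePanel, UptakeGroundTruth]:
    """Simulate an uptake panel linear in one species' octamer frequencies.

    ``n_octamers`` single-CpG octamers with a defined positive frequency in
    the target are sampled without replacement (panels are built from
    sequences actually present in the genome they represent);
    uptake_i = intercept + slope * freq_i + N(0, sd), floored at zero
    (panels carry non-negative fluorescence).
    """
    rng = np.random.default_rng(config.seed)
    census = config.target_species_census
    if census.total_windows == 0:
        raise ValueError("target species census is empty")
    if config.frequency_mode == "raw":
        freq = census.relfreq
    else:
        from .correlation_screen import normalize_to_reference

        freq = normalize_to_reference(census, config.reference_census)
    with np.errstate(invalid="ignore"):
        eligible = np.nonzero(single_cpg_mask() & np.isfinite(freq) & (freq > 0))[0]
    if eligible.size < config.n_octamers:
        raise ValueError(
            f"only {eligible.size} single-CpG octamers have a defined "
            f"positive frequency; {config.n_octamers} requested"
        )
    idx = rng.choice(eligible, size=config.n_octamers, replace=False)
    x = freq[idx]
    noise = rng.normal(0.0, config.noise_sd, size=config.n_octamers)
    uptake = config.intercept + config.slope * x + noise
    n_floored = int((uptake < 0).sum())
    uptake = np.maximum(uptake, 0.0)
    entries = [
        UptakeEntry(index_to_octamer(int(i)), float(v), config.condition)
        for i, v in zip(idx, uptake)
    ]
    panel = UptakePanel(entries)
    panel.validate()
    truth = UptakeGroundTruth(
        config.seed, idx, x, config.slope, config.intercept, config.noise_sd, n_floored
    )
    return panel, truth


def generate_assay_table(
    species_means: Mapping[str, float],
    rank_offsets: Sequence[float] = (0.0, 0.0, 0.0),
    n_replicates: int = 5,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a balanced species x rank replicate table of assay ratios.

    readout = species mean + rank offset + N(0, sd), for every combination
    of species group, within-species octamer rank (1..len(rank_offsets))
    and replicate experiment.
    """
    if not species_means:
        raise ValueError("at least one species group is required")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        for species, mean in species_means.items():
            for rank, offset in enumerate(rank_offsets, start=1):
                rows.append(
                    {
                        "experiment_id": f"E{rep}",
                        "octamer": f"{species}{rank}",
                        "species": species,
                        "rank": rank,
                        "readout": mean + offset + rng.normal(0.0, noise_sd),
                    }
                )
    table = pd.DataFrame(rows)
    truth = {
        "seed": seed,
        "species_means": dict(species_means),
        "rank_offsets": list(rank_offsets),
        "n_replicates": n_replicates,
        "noise_sd": noise_sd,
    }
    return table, truth
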