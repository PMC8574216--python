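"""Naive re-scan oracles used to cross-check the vectorized implementations.

Each oracle tests every offset of the raw string directly, independently of
the production code paths.
"""

from collections import Counter

import numpy as np

# The classic immunostimulatory 30-mer used as a printed-sequence fixture.
SEQ1 = "TCGTCGTTTTGTCGTTTTGTCGTTCATGAA"

ACGT = set("ACGT")


def naive_cpg_sites(seq: str) -> list[int]:
    return [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]


def naive_gaps(seq: str) -> list[int]:
    sites = naive_cpg_sites(seq)
    return [b - a - 2 for a, b in zip(sites, sites[1:])]


def naive_census(seq: str) -> tuple[Counter, int]:
    """(octamer window counts, CpG site count) by scanning every offset."""
    counts: Counter = Counter()
    n_sites = 0
    for i in range(len(seq) - 1):
        if seq[i : i + 2] != "CG":
            continue
        n_sites += 1
        if i - 3 < 0 or i + 5 > len(seq):
            continue
        window = seq[i - 3 : i + 5]
        if set(window) <= ACGT:
            counts[window] += 1
    return counts, n_sites


def naive_positional_composition(seqs: list[str]) -> np.ndarray:
    """6 x 4 base frequencies at offsets -3,-2,-1,+2,+3,+4 around each CpG
    with a full valid window, tallied directly from the sequences."""
    tallies = np.zeros((6, 4))
    base_col = {b: j for j, b in enumerate("ACGT")}
    for seq in seqs:
        for i in naive_cpg_sites(seq):
            if i - 3 < 0 or i + 5 > len(seq):
                continue
            window = seq[i - 3 : i + 5]
            if not set(window) <= ACGT:
                continue
            for row, off in enumerate((-3, -2, -1, 2, 3, 4)):
                tallies[row, base_col[seq[i + off]]] += 1
    total = tallies.sum(axis=1, keepdims=True)
    return np.divide(tallies, total, out=np.zeros_like(tallies), where=total > 0)


def random_sequence(rng: np.random.Generator, max_len: int = 500, n_frac: float = 0.05) -> str:
    n = int(rng.integers(0, max_len + 1))
    return "".join(rng.choice(list("ACGTN"), size=n,
                              p=[(1 - n_frac) / 4] * 4 + [n_frac]))
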