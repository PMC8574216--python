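import numpy as np
import pytest

from cpgscope.composition import (
    composition_from_weights,
    composition_similarity,
    positional_composition,
    rank_octamers,
    select_representative_octamers,
    top_octamers,
    topk_overlap,
)
from cpgscope.motif_census import (
    OctamerCensus,
    index_to_octamer,
    octamer_census,
    octamer_to_index,
    single_cpg_mask,
)
from cpgscope.seqio import GenomeDataset, SequenceRecord

from oracles import naive_positional_composition, random_sequence


def census_from_counts(mapping, label="X"):
    counts = np.zeros(4096, dtype=np.int64)
    for octamer, n in mapping.items():
        counts[octamer_to_index(octamer)] = n
    return OctamerCensus(label, counts, total_cpg_sites=int(counts.sum()))


def test_rank_octamers_orders_and_breaks_ties():
    ranked = rank_octamers(census_from_counts({"AAACGAAA": 3, "TTTCGTTT": 1}))
    assert ranked.octamers[0] == "AAACGAAA"
    assert ranked.octamers[1] == "TTTCGTTT"
    # first unobserved octamer follows, lexicographically
    assert ranked.octamers[2] == "AAACGAAC"
    assert ranked.rank_of("TTTCGTTT") == 2


def test_rank_octamers_is_a_permutation_with_monotone_relfreq():
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 50, size=4096)
    census = OctamerCensus("R", counts, int(counts.sum()))
    ranked = rank_octamers(census)
    assert sorted(ranked.octamers) == [index_to_octamer(i) for i in range(4096)]
    assert (np.diff(ranked.relfreq) <= 0).all()
    assert ranked.octamers[-1] != ranked.octamers[0]


def test_equal_counts_rank_lexicographically():
    ranked = rank_octamers(census_from_counts({"TTTCGTTT": 2, "AAACGAAA": 2}))
    assert ranked.octamers[:2] == ["AAACGAAA", "TTTCGTTT"]


def test_topk_overlap_bounds():
    rng = np.random.default_rng(9)
    counts = rng.integers(1, 100, size=4096)
    a = OctamerCensus("A", counts, int(counts.sum()))
    assert topk_overlap(a, a, 20) == 20

    top = [index_to_octamer(i) for i in range(40)]
    b = census_from_counts({o: 10 for o in top[:20]}, "B")
    c = census_from_counts({o: 10 for o in top[20:]}, "C")
    assert topk_overlap(b, c, 20) == 0
    assert topk_overlap(b, c, 20) == topk_overlap(c, b, 20)


def test_no_octamer_common_to_all_eight_top20_lists():
    """Eight censuses built so the all-dataset top-20 intersection is empty."""
    octs = [index_to_octamer(i) for i in range(200)]
    censuses = []
    for d in range(8):
        # dataset d's top-20 is a window offset by 15: adjacent windows share
        # five octamers, but no octamer is in every window
        window = octs[15 * d : 15 * d + 20]
        censuses.append(census_from_counts({o: 100 - j for j, o in enumerate(window)}, f"D{d}"))
    tops = [set(top_octamers(c, 20)) for c in censuses]
    assert set.intersection(*tops) == set()
    assert all(len(t) == 20 for t in tops)


def test_positional_composition_examples():
    comp = positional_composition(census_from_counts({"AAACGAAA": 1}))
    assert np.allclose(comp.freq[:, 0], 1.0)  # A everywhere

    uniform = OctamerCensus("U", np.ones(4096, dtype=np.int64), 4096)
    assert np.allclose(positional_composition(uniform).freq, 0.25)

    comp = positional_composition(census_from_counts({"AAACGAAA": 1, "TTTCGTTT": 3}))
    assert np.allclose(comp.freq[:, 0], 0.25)  # A
    assert np.allclose(comp.freq[:, 3], 0.75)  # T
    assert np.allclose(comp.freq.sum(axis=1), 1.0, atol=1e-12)


def test_positional_composition_empty_census_fatal():
    with pytest.raises(ValueError, match="no octamer windows"):
        positional_composition(census_from_counts({}))


def test_positional_composition_matches_direct_rescan(rng):
    for _ in range(200):
        seq = random_sequence(rng, max_len=300)
        ds = GenomeDataset("S", [SequenceRecord("r", seq)])
        census = octamer_census(ds)
        if census.total_windows == 0:
            continue
        comp = positional_composition(census)
        assert np.allclose(comp.freq, naive_positional_composition([seq]), atol=1e-12)


def test_unweighted_composition_counts_distinct_octamers_once():
    comp = positional_composition(
        census_from_counts({"AAACGAAA": 1, "TTTCGTTT": 99}), weighted=False
    )
    assert np.allclose(comp.freq[:, 0], 0.5)


def test_similarity_identity_and_antithesis():
    a = positional_composition(census_from_counts({"AAACGAAA": 2, "AAACGAAT": 1}))
    assert composition_similarity(a, a) == pytest.approx(1.0)

    all_a = positional_composition(census_from_counts({"AAACGAAA": 1}))
    all_t = positional_composition(census_from_counts({"TTTCGTTT": 1}))
    # hand computation over the 24 entries with mean 0.25 gives -1/3
    assert composition_similarity(all_a, all_t) == pytest.approx(-1 / 3)
    assert composition_similarity(all_t, all_a) == pytest.approx(-1 / 3)


def test_similarity_undefined_for_uniform_composition():
    uniform = positional_composition(OctamerCensus("U", np.ones(4096, dtype=np.int64), 4096))
    other = positional_composition(census_from_counts({"AAACGAAA": 1}))
    with pytest.warns(UserWarning, match="zero variance"):
        assert np.isnan(composition_similarity(uniform, other))


def test_similarity_invariant_under_consistent_reordering():
    rng = np.random.default_rng(3)
    a = composition_from_weights(rng.uniform(size=4096))
    b = composition_from_weights(rng.uniform(size=4096))
    r = composition_similarity(a, b)
    perm = rng.permutation(24)
    ra = a.freq.ravel()[perm]
    rb = b.freq.ravel()[perm]
    from cpgscope.composition import _pearson

    assert _pearson(ra, rb) == pytest.approx(r, abs=1e-12)


def test_per_position_similarity_mode_runs():
    rng = np.random.default_rng(4)
    a = composition_from_weights(rng.uniform(size=4096))
    b = composition_from_weights(rng.uniform(size=4096))
    r = composition_similarity(a, b, mode="per-position")
    assert -1.0 <= r <= 1.0


def test_select_representative_octamers_planted():
    single = [index_to_octamer(int(i)) for i in np.nonzero(single_cpg_mask())[0]]
    multi = [
        index_to_octamer(i) for i in range(4096)
        if not single_cpg_mask()[i]
    ]
    # dataset W: top octamer has two CpGs, then three unique single-CpG picks
    w = census_from_counts(
        {multi[0]: 50, single[0]: 40, single[1]: 30, single[2]: 20, single[10]: 1},
        "W",
    )
    h = census_from_counts({single[100]: 10, single[101]: 9, single[102]: 8}, "H")
    picks = select_representative_octamers({"W": w, "H": h}, n_select=3)
    assert picks["W"] == [single[0], single[1], single[2]]  # multi-CpG skipped
    assert picks["H"] == [single[100], single[101], single[102]]


def test_select_identical_censuses_yields_nothing_under_exclusive_rule():
    c = census_from_counts({"AAACGAAA": 5, "AAACGAAT": 3, "TTTCGTTT": 2})
    with pytest.warns(UserWarning, match="only 0 of 3"):
        picks = select_representative_octamers(
            {"A": c, "B": census_from_counts({"AAACGAAA": 5, "AAACGAAT": 3, "TTTCGTTT": 2}, "B")}
        )
    assert picks == {"A": [], "B": []}


def test_select_shared_at_most_once_rule_is_laxer():
    c1 = census_from_counts({"AAACGAAA": 5})
    c2 = census_from_counts({"AAACGAAA": 5}, "B")
    c3 = census_from_counts({"TTTCGTTT": 5}, "C")
    picks = select_representative_octamers(
        {"A": c1, "B": c2, "C": c3}, n_select=1, rule="shared-at-most-once"
    )
    assert picks["A"] == ["AAACGAAA"]  # shared with exactly one other top-20
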