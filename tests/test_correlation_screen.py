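import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

from cpgscope.correlation_screen import (
    bonferroni_adjust,
    linear_fit,
    normalize_to_reference,
    species_screen,
)
from cpgscope.motif_census import OctamerCensus, index_to_octamer, single_cpg_mask
from cpgscope.seqio import UptakeEntry, UptakePanel


def _census(counts, label="X"):
    counts = np.asarray(counts, dtype=np.int64)
    return OctamerCensus(label, counts, int(counts.sum()))


def test_linear_fit_exact_line():
    fit = linear_fit([1, 2, 3], [2, 4, 6])
    assert fit.slope == pytest.approx(2.0)
    assert fit.r2 == pytest.approx(1.0)
    assert fit.p_raw < 1e-10


def test_linear_fit_hand_ols():
    fit = linear_fit([1, 2, 3, 4], [1, 3, 2, 4])
    assert fit.slope == pytest.approx(0.8)
    assert fit.r2 == pytest.approx(0.64)


def test_linear_fit_constant_y():
    fit = linear_fit([1, 2, 3, 4], [5, 5, 5, 5])
    assert (fit.slope, fit.r2, fit.p_raw) == (0.0, 0.0, 1.0)


def test_linear_fit_constant_x_fatal():
    with pytest.raises(ValueError, match="constant"):
        linear_fit([2, 2, 2, 2], [1, 2, 3, 4])


def test_linear_fit_drops_nan_pairwise():
    fit = linear_fit([1, 2, np.nan, 3, 4], [2, 4, 10, np.nan, 8])
    assert fit.n == 3
    assert fit.n_dropped == 2
    assert fit.slope == pytest.approx(2.0)


def test_linear_fit_needs_three_pairs():
    with pytest.raises(ValueError, match="at least 3"):
        linear_fit([1, np.nan, 3], [1, 2, 3])


def test_linear_fit_matches_normal_equations_oracle(rng):
    for _ in range(300):
        n = int(rng.integers(3, 30))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        fit = linear_fit(x, y)
        # normal equations solved directly
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        resid = y - X @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        assert fit.r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)
        # t statistic consistent with r2 and n
        if fit.r2 < 1:
            assert fit.t_stat**2 == pytest.approx(
                fit.r2 * (n - 2) / (1 - fit.r2), abs=1e-9 * max(1, fit.t_stat**2)
            )


@pytest.mark.parametrize(
    "p, m, expected", [(2e-5, 705, 0.0141), (0.01, 705, 1.0), (0.0, 50, 0.0)]
)
def test_bonferroni_adjust(p, m, expected):
    assert bonferroni_adjust(p, m) == pytest.approx(expected)


@given(st.floats(0, 1), st.integers(1, 2000), st.integers(1, 2000))
def test_bonferroni_monotone_and_capped(p, m1, m2):
    lo, hi = sorted((m1, m2))
    assert bonferroni_adjust(p, lo) <= bonferroni_adjust(p, hi) <= 1.0


def test_table2_worked_example_against_t_oracle():
    """r2 = 0.50 at n = 31 gives a slope p that prints as 0.01 after x705."""
    r2, n, m = 0.50, 31, 705
    t = math.sqrt(r2 * (n - 2) / (1 - r2))
    from scipy import stats

    p_raw = 2 * stats.t.sf(t, n - 2)
    # independent oracle: numerically integrate the t density's tail
    df = n - 2
    const = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    tail, _ = integrate.quad(lambda u: const * (1 + u**2 / df) ** (-(df + 1) / 2), t, np.inf)
    assert p_raw == pytest.approx(2 * tail, rel=1e-8)
    assert p_raw == pytest.approx(9e-6, rel=0.05)
    assert round(bonferroni_adjust(p_raw, m), 2) == 0.01


def test_normalize_to_reference():
    a = np.zeros(4096, dtype=np.int64)
    a[:4] = [2, 1, 1, 0]
    ref = np.zeros(4096, dtype=np.int64)
    ref[:4] = [1, 1, 0, 2]
    out = normalize_to_reference(_census(a), _census(ref))
    assert out[0] == pytest.approx(2.0)
    assert out[1] == pytest.approx(1.0)
    assert np.isnan(out[2])  # absent from reference -> NA
    assert out[3] == pytest.approx(0.0)
    same = normalize_to_reference(_census(ref), _census(ref))
    observed = np.isfinite(same)
    assert np.allclose(same[observed], 1.0)


def test_normalize_pseudocount_policy_has_no_nan():
    a = np.zeros(4096, dtype=np.int64)
    a[0] = 10
    ref = np.zeros(4096, dtype=np.int64)
    ref[1] = 10
    out = normalize_to_reference(_census(a), _census(ref), zero_policy="pseudocount")
    assert np.isfinite(out).all()


def test_normalize_empty_reference_fatal():
    with pytest.raises(ValueError, match="reference"):
        normalize_to_reference(_census(np.ones(4096)), _census(np.zeros(4096)))


def _panel_from(census, indices, values):
    return UptakePanel(
        [UptakeEntry(index_to_octamer(int(i)), float(v), None) for i, v in zip(indices, values)]
    )


def test_species_screen_identical_censuses_agree():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 200, size=4096)
    counts[~single_cpg_mask()] = 0
    a = _census(counts, "A")
    b = _census(counts.copy(), "B")
    ref = _census(rng.integers(1, 200, size=4096), "H")
    idx = np.nonzero(counts)[0][:10]
    panel = _panel_from(a, idx, rng.uniform(10, 100, size=10))
    result = species_screen({"A": a, "B": b}, ref, panel)
    rows = {(r.species_label, r.mode): r.result for r in result.rows}
    for mode in ("raw", "normalized"):
        assert rows[("A", mode)].slope == rows[("B", mode)].slope
        assert rows[("A", mode)].p_adj == rows[("B", mode)].p_adj
    # auto multiplier counts the fits actually performed
    assert result.m_tests == 4


def test_species_screen_null_rarely_passes(rng):
    """Uncorrelated uptake rarely reaches r2 >= 0.2 with positive slope at n=31."""
    n_pass = n_fit = 0
    for _ in range(200):
        x = rng.uniform(size=31)
        y = rng.uniform(size=31)
        fit = linear_fit(x, y)
        n_fit += 1
        n_pass += fit.r2 >= 0.2 and fit.slope > 0
    assert n_pass / n_fit < 0.10


def test_species_screen_skips_all_na_species():
    counts = np.zeros(4096, dtype=np.int64)
    counts[:40] = 5 + np.arange(40)  # varying raw frequencies
    species = _census(counts, "S")
    ref = np.zeros(4096, dtype=np.int64)
    ref[40:80] = 5  # reference disjoint from the panel octamers
    panel = _panel_from(species, np.arange(10), np.arange(10) + 1.0)
    with pytest.warns(UserWarning, match="insufficient usable"):
        result = species_screen({"S": species}, _census(ref, "H"), panel)
    assert {r.mode for r in result.rows} == {"raw"}
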