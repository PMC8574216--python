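"""Frequency-vs-uptake regression screening with Bonferroni correction.

For each candidate species, octamer relative frequencies (raw, and
normalized by dividing through the human reference genome's frequencies)
are regressed against measured DNA uptake over a panel of octamers by
ordinary least squares.  The p-value tests the slope against zero (two-sided
t, n-2 df) and is Bonferroni-multiplied by the number of regressions in the
screen (the original study performed 705).  A species "passes" when its
goodness of fit r^2 reaches the threshold (default 0.2) with a positive
slope; the best-fit species is the maximal-r^2 positive-slope candidate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motif_census import OctamerCensus, octamer_to_index
from .seqio import UptakePanel

__all__ = [
    "RegressionResult",
    "ScreenRow",
    "ScreenResult",
    "normalize_to_reference",
    "linear_fit",
    "bonferroni_adjust",
    "species_screen",
]


@dataclass(frozen=True)
class RegressionResult:
    """One ordinary-least-squares fit of uptake on frequency."""

    n: int
    slope: float
    intercept: float
    r2: float
    t_stat: float
    p_raw: float
    p_adj: float
    m_tests: int
    n_dropped: int = 0


def bonferroni_adjust(p_raw: float, m_tests: int) -> float:
    """min(1, p_raw * m_tests)."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError("p_raw must lie in [0, 1]")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return min(1.0, p_raw * m_tests)


def linear_fit(x: Sequence[float], y: Sequence[float], m_tests: int = 1) -> RegressionResult:
    """OLS of y on x with a two-sided slope t-test (n-2 df).

    NaN pairs are dropped pairwise (count reported in ``n_dropped``).  A
    constant x is fatal; a constant y yields slope 0, r^2 = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~keep).sum())
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 finite (x, y) pairs, have {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    if np.ptp(y) == 0:
        return RegressionResult(
            n, 0.0, float(y.mean()), 0.0, 0.0, 1.0,
            bonferroni_adjust(1.0, m_tests), m_tests, n_dropped,
        )
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2
    t_stat = fit.slope / fit.stderr if fit.stderr > 0 else math.inf * np.sign(fit.slope)
    return RegressionResult(
        n=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(r2),
        t_stat=float(t_stat),
        p_raw=float(fit.pvalue),
        p_adj=bonferroni_adjust(float(fit.pvalue), m_tests),
        m_tests=m_tests,
        n_dropped=n_dropped,
    )


def normalize_to_reference(
    census: OctamerCensus,
    reference: OctamerCensus,
    zero_policy: str = "na",
) -> np.ndarray:
    """Per-octamer relative frequency divided by the reference's.

    Octamers absent from the reference are NaN under ``zero_policy="na"``
    (the default; they drop out of any later regression) or handled by
    adding a pseudo-count of 1 to every reference count under
    ``zero_policy="pseudocount"``.
    """
    if reference.total_windows == 0:
        raise ValueError("reference census has no octamer windows")
    num = census.relfreq
    if zero_policy == "na":
        den = reference.relfreq
        out = np.full(4096, np.nan)
        nz = den > 0
        out[nz] = num[nz] / den[nz]
        return out
    if zero_policy == "pseudocount":
        counts = reference.counts + 1
        den = counts / counts.sum()
        return num / den
    raise ValueError(f"unknown zero_policy {zero_policy!r}")


@dataclass(frozen=True)
class ScreenRow:
    species_label: str
    mode: str  # "raw" or "normalized"
    result: RegressionResult
    passes_threshold: bool


@dataclass
class ScreenResult:
    """All per-species fits from one screen plus the multiplier used."""

    rows: list[ScreenRow]
    m_tests: int
    r2_threshold: float

    def summary(self, mode: str) -> dict:
        """Fraction of species passing and the best-fit species for one mode."""
        rows = [r for r in self.rows if r.mode == mode]
        if not rows:
            raise ValueError(f"no rows for mode {mode!r}")
        passing = [r for r in rows if r.passes_threshold]
        positive = [r for r in rows if r.result.slope > 0]
        best = max(positive, key=lambda r: r.result.r2) if positive else None
        return {
            "mode": mode,
            "n_species": len(rows),
            "fraction_passing": len(passing) / len(rows),
            "best_fit_species": best.species_label if best else None,
            "best_fit_r2": best.result.r2 if best else float("nan"),
            "best_fit_p_adj": best.result.p_adj if best else float("nan"),
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": r.species_label,
                "mode": r.mode,
                "n": r.result.n,
                "slope": r.result.slope,
                "r2": r.result.r2,
                "p_raw": r.result.p_raw,
                "p_adj": r.result.p_adj,
                "passes": r.passes_threshold,
            }
            for r in self.rows
        )


def species_screen(
    censuses: Mapping[str, OctamerCensus],
    reference: OctamerCensus,
    panel: UptakePanel,
    r2_threshold: float = 0.2,
    m_tests: int | str = "auto",
    zero_policy: str = "na",
    strict_threshold: bool = False,
    modes: Sequence[str] = ("raw", "normalized"),
) -> ScreenResult:
    """Regress panel uptake on each species' octamer frequencies.

    One raw-mode and one normalized-mode fit per species.  ``m_tests="auto"``
    sets the Bonferroni multiplier to the number of fits performed in this
    run; an integer (e.g. the study-wide 705) may be supplied instead.  The
    pass gate is r^2 >= threshold (or > with ``strict_threshold=True``) with
    a positive slope.  Species whose normalized frequencies are all-NA over
    the panel are skipped with a warning.
    """
    panel.validate()
    values = panel.mean_by_octamer()
    octs = list(values)
    if len(octs) < 3:
        raise ValueError("panel must cover at least 3 octamers")
    idx = np.array([octamer_to_index(o) for o in octs])
    y = np.array([values[o] for o in octs])

    fits: list[tuple[str, str, np.ndarray]] = []
    for label, census in censuses.items():
        for mode in modes:
            if mode == "raw":
                x = census.relfreq[idx]
            elif mode == "normalized":
                x = normalize_to_reference(census, reference, zero_policy)[idx]
            else:
                raise ValueError(f"unknown mode {mode!r}")
            finite = np.isfinite(x)
            if finite.sum() < 3 or np.ptp(x[finite]) == 0:
                warnings.warn(
                    f"species {label!r} mode {mode!r}: insufficient usable "
                    "frequencies; skipped",
                    stacklevel=2,
                )
                continue
            fits.append((label, mode, x))

    m = len(fits) if m_tests == "auto" else int(m_tests)
    m = max(m, 1)
    rows = []
    for label, mode, x in fits:
        res = linear_fit(x, y, m_tests=m)
        passes = (
            (res.r2 > r2_threshold if strict_threshold else res.r2 >= r2_threshold)
            and res.slope > 0
        )
        rows.append(ScreenRow(label, mode, res, passes))
    return ScreenResult(rows, m, r2_threshold)
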