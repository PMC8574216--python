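"""Ratio readouts for NK-cell functional assays and the two-way ANOVA.

Flow-cytometry readouts are reduced to control-normalized ratios:

* ``escape_ratio``: the fraction of labeled target cells escaping lysis,
  adjusted by targets cultured alone, then divided by the same adjusted
  fraction for the no-DNA co-culture.  A ratio > 1 means the DNA diminished
  lysis.  The targets-alone baseline cancels algebraically; it is accepted
  so callers can pass the three gated percentages exactly as recorded.
* ``response_ratio``: a plain treated/control quotient, used for the IFN-g
  readout, the trypsin-resistant (internalized) FITC fraction and the
  surface-DNA fraction.

Significance across replicate experiments uses an ordinary two-way
fixed-effects ANOVA with species-of-origin and within-species octamer rank
as crossed factors, so that species differences are assessed independently
of the distribution of first/second/third-ranked octamers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "REQUIRED_COLUMNS",
    "AnovaResult",
    "escape_ratio",
    "response_ratio",
    "normalize_to_control",
    "two_way_anova",
]

REQUIRED_COLUMNS = ("experiment_id", "octamer", "species", "rank", "readout")


def escape_ratio(
    pct_live_targets_cocult_dna: float,
    pct_live_targets_cocult_nodna: float,
    pct_live_targets_alone: float,
) -> float:
    """Lysis-escape ratio: (dna/alone) / (nodna/alone); > 1 = diminished lysis."""
    for name, v in (
        ("pct_live_targets_cocult_dna", pct_live_targets_cocult_dna),
        ("pct_live_targets_cocult_nodna", pct_live_targets_cocult_nodna),
        ("pct_live_targets_alone", pct_live_targets_alone),
    ):
        if not 0 < v <= 100:
            raise ValueError(f"{name} must be a percentage in (0, 100], got {v}")
    adjusted_dna = pct_live_targets_cocult_dna / pct_live_targets_alone
    adjusted_nodna = pct_live_targets_cocult_nodna / pct_live_targets_alone
    return adjusted_dna / adjusted_nodna


def response_ratio(treated: float, control: float) -> float:
    """treated / control; > 1 enhancement, < 1 diminishment."""
    if control <= 0:
        raise ValueError(f"control readout must be positive, got {control}")
    return treated / control


def normalize_to_control(
    table: pd.DataFrame, control_col: str = "control_readout"
) -> pd.DataFrame:
    """Divide each row's readout by its per-experiment control readout.

    Applied before pooling replicates across experiments so that differently
    scaled experiments contribute comparably.
    """
    if control_col not in table.columns:
        raise ValueError(f"table lacks control column {control_col!r}")
    if (table[control_col] <= 0).any():
        raise ValueError("control readouts must be positive")
    out = table.copy()
    out["readout"] = out["readout"] / out[control_col]
    return out


@dataclass
class AnovaResult:
    """Two-way fixed-effects decomposition: SS, df, F and p per factor."""

    table: pd.DataFrame  # index: factor names (+ interaction) and Residual
    formula: str
    interaction: bool

    def p_value(self, factor: str) -> float:
        return float(self.table.loc[factor, "PR(>F)"])

    def sum_sq(self, factor: str) -> float:
        return float(self.table.loc[factor, "sum_sq"])

    @property
    def residual_df(self) -> int:
        return int(self.table.loc["Residual", "df"])


def two_way_anova(
    table: pd.DataFrame,
    response: str = "readout",
    factor_a: str = "species",
    factor_b: str = "rank",
    interaction: bool | None = None,
    allow_unbalanced: bool = False,
) -> AnovaResult:
    """Ordinary two-way ANOVA of ``response`` on two crossed factors.

    ``interaction=None`` includes the interaction term when every cell has
    more than one replicate.  The design must be balanced (equal cell
    counts) unless ``allow_unbalanced=True``, which switches to a type-II
    decomposition for unbalanced data.
    """
    for col in (response, factor_a, factor_b):
        if col not in table.columns:
            raise ValueError(f"assay table lacks column {col!r}")
    if not np.isfinite(table[response]).all():
        raise ValueError("readouts must be finite")
    cells = table.groupby([factor_a, factor_b], observed=True).size()
    n_a = table[factor_a].nunique()
    n_b = table[factor_b].nunique()
    if len(cells) != n_a * n_b:
        raise ValueError(
            f"factors are not fully crossed: {len(cells)} of {n_a * n_b} "
            f"cells occupied\n{cells}"
        )
    balanced = cells.nunique() == 1
    if not balanced and not allow_unbalanced:
        raise ValueError(
            "unbalanced design (pass allow_unbalanced=True for a type-II "
            f"analysis); cell counts:\n{cells}"
        )
    if interaction is None:
        interaction = bool((cells > 1).all())
    op = "*" if interaction else "+"
    formula = f"Q('{response}') ~ C(Q('{factor_a}')) {op} C(Q('{factor_b}'))"
    model = ols(formula, data=table).fit()
    out = anova_lm(model, typ=2)
    rename = {
        f"C(Q('{factor_a}'))": factor_a,
        f"C(Q('{factor_b}'))": factor_b,
        f"C(Q('{factor_a}')):C(Q('{factor_b}'))": f"{factor_a}:{factor_b}",
    }
    out = out.rename(index=rename)
    return AnovaResult(out, formula, interaction)
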