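"""Statistical design of the mesocosm experiment.

pH is controlled in header tanks (4 per treatment), each gravity-feeding 3
incubation tanks that hold one colony per species, so colonies are nested in
header tanks nested in treatments.  The analysis follows the conventional
two-stage approach for such designs:

1. a nested ANOVA with treatment fixed and header tank random; if the tank
   effect is non-significant at the liberal threshold p > 0.25 the tank term
   is dropped and colonies are treated as independent replicates;
2. a one-way ANOVA across treatments with Tukey HSD pairwise comparisons.

F ratios use the expected-mean-squares rules for the balanced nested layout:
the tank effect is tested over the residual mean square; the treatment effect
is reported both over the tank mean square (the conservative test while the
tank term is retained) and over the residual mean square (the test after
dropping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DesignError

__all__ = [
    "validate_design",
    "TankGateResult",
    "tank_effect_gate",
    "TreatmentTestResult",
    "treatment_test",
    "LinearFit",
    "linear_fit",
]

DESIGN_COLUMNS = ("treatment", "header_tank")


def validate_design(table: pd.DataFrame, response: str) -> pd.DataFrame:
    """Check the nesting structure required by the tank-gate ANOVA."""
    missing = [c for c in (*DESIGN_COLUMNS, response) if c not in table.columns]
    if missing:
        raise DesignError(f"design table missing columns: {missing}")
    df = table.dropna(subset=[response]).copy()
    if df.empty:
        raise DesignError("design table has no usable rows")
    tanks_per_treatment = df.groupby("treatment")["header_tank"].nunique()
    if (tanks_per_treatment < 2).any():
        bad = tanks_per_treatment[tanks_per_treatment < 2].index.tolist()
        raise DesignError(f"treatments with fewer than 2 header tanks: {bad}")
    shared = df.groupby("header_tank")["treatment"].nunique()
    if (shared > 1).any():
        bad = shared[shared > 1].index.tolist()
        raise DesignError(f"header tanks assigned to multiple treatments: {bad}")
    return df


@dataclass(frozen=True)
class TankGateResult:
    decision: str                  # "keep_tank" | "drop_tank"
    p_tank: float
    f_tank: float
    p_treatment_over_tank: float
    f_treatment_over_tank: float
    p_treatment_over_residual: float
    f_treatment_over_residual: float
    anova: pd.DataFrame


def tank_effect_gate(
    table: pd.DataFrame, response: str, threshold: float = 0.25
) -> TankGateResult:
    """Fit the nested ANOVA and decide whether the header-tank term is dropped.

    The tank term is dropped when its p-value exceeds ``threshold`` (default
    0.25, the liberal pooling rule for random blocking factors).
    """
    df = validate_design(table, response)
    df = df.rename(columns={response: "_y"})
    if df["_y"].nunique() == 1:
        # constant response: all sums of squares vanish identically
        aov = pd.DataFrame(
            {"sum_sq": [0.0, 0.0, 0.0], "df": [np.nan, np.nan, np.nan],
             "F": [0.0, 0.0, np.nan], "PR(>F)": [1.0, 1.0, np.nan]},
            index=["C(treatment)", "C(header_tank)", "Residual"],
        )
        return TankGateResult(
            decision="drop_tank", p_tank=1.0, f_tank=0.0,
            p_treatment_over_tank=1.0, f_treatment_over_tank=0.0,
            p_treatment_over_residual=1.0, f_treatment_over_residual=0.0,
            anova=aov,
        )
    model = smf.ols("_y ~ C(treatment) + C(header_tank)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=1)

    ss_treat = float(aov.loc["C(treatment)", "sum_sq"])
    df_treat = float(aov.loc["C(treatment)", "df"])
    ss_tank = float(aov.loc["C(header_tank)", "sum_sq"])
    df_tank = float(aov.loc["C(header_tank)", "df"])
    ss_res = float(aov.loc["Residual", "sum_sq"])
    df_res = float(aov.loc["Residual", "df"])

    ms_treat = ss_treat / df_treat
    ms_tank = ss_tank / df_tank
    ms_res = ss_res / df_res if df_res > 0 else np.nan

    def _f_p(ms_num, ms_den, dfn, dfd):
        if not np.isfinite(ms_den) or ms_den == 0:
            # degenerate sums of squares: no evidence against the null
            return (0.0, 1.0) if ms_num == 0 else (np.inf, 0.0)
        f = ms_num / ms_den
        return f, float(sps.f.sf(f, dfn, dfd))

    f_tank, p_tank = _f_p(ms_tank, ms_res, df_tank, df_res)
    f_tr_tank, p_tr_tank = _f_p(ms_treat, ms_tank, df_treat, df_tank)
    f_tr_res, p_tr_res = _f_p(ms_treat, ms_res, df_treat, df_res)

    decision = "drop_tank" if p_tank > threshold else "keep_tank"
    return TankGateResult(
        decision=decision,
        p_tank=p_tank,
        f_tank=f_tank,
        p_treatment_over_tank=p_tr_tank,
        f_treatment_over_tank=f_tr_tank,
        p_treatment_over_residual=p_tr_res,
        f_treatment_over_residual=f_tr_res,
        anova=aov,
    )


@dataclass(frozen=True)
class TreatmentTestResult:
    p_value: float
    f_value: float
    anova: pd.DataFrame
    tukey: pd.DataFrame


def treatment_test(table: pd.DataFrame, response: str) -> TreatmentTestResult:
    """One-way ANOVA across treatments plus Tukey HSD pairwise comparisons.

    Applied after the tank gate, treating colonies as replicates.
    """
    if response not in table.columns or "treatment" not in table.columns:
        raise DesignError(f"table must have 'treatment' and {response!r} columns")
    df = table.dropna(subset=[response]).copy()
    counts = df.groupby("treatment")[response].size()
    if df.empty or (counts < 2).any() or counts.size < 2:
        raise DesignError("each treatment needs at least 2 observations")

    df = df.rename(columns={response: "_y"})
    model = smf.ols("_y ~ C(treatment)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=1)
    f = float(aov.loc["C(treatment)", "F"])
    p = float(aov.loc["C(treatment)", "PR(>F)"])
    if not np.isfinite(f):  # zero residual variance
        ss_tr = float(aov.loc["C(treatment)", "sum_sq"])
        f, p = (0.0, 1.0) if ss_tr == 0 else (np.inf, 0.0)

    thsd = pairwise_tukeyhsd(df["_y"].to_numpy(), df["treatment"].to_numpy())
    groups = np.asarray(thsd.groupsunique)
    pairs = [(groups[i], groups[j]) for i in range(len(groups)) for j in range(i + 1, len(groups))]
    tukey = pd.DataFrame({
        "group1": [a for a, _ in pairs],
        "group2": [b for _, b in pairs],
        "meandiff": thsd.meandiffs,
        "p_adj": thsd.pvalues,
        "lower": thsd.confint[:, 0],
        "upper": thsd.confint[:, 1],
        "reject": thsd.reject,
    })
    return TreatmentTestResult(p_value=p, f_value=f, anova=aov, tukey=tukey)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    p_value: float       # t-test on the slope
    r_squared: float
    stderr_slope: float
    stderr_intercept: float

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares y = a + b x with the standard slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise DesignError("need at least 3 points for a linear fit")
    if np.ptp(x) == 0:
        raise DesignError("x is constant: slope is not identifiable")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        p_value=float(model.pvalues[1]),
        r_squared=float(model.rsquared),
        stderr_slope=float(model.bse[1]),
        stderr_intercept=float(model.bse[0]),
    )
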