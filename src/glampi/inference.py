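"""Group-level statistics: two-way ANOVA, nominal-value t-tests, correlations, power.

The observation unit for the ANOVAs is the participant-condition cell (three
rows per participant), matching how per-condition behavioural means and
fitted parameters are compared across groups and environmental conditions.
Unbalanced designs are handled with Type-III sums of squares under
sum-to-zero contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AnovaResult",
    "two_way_anova",
    "nominal_t_test",
    "demographic_correlation",
    "anova_power",
    "bonferroni",
]


def bonferroni(p, m) -> float:
    """Bonferroni-adjusted p-value: min(1, m*p)."""
    return float(min(1.0, m * p))


@dataclass
class AnovaResult:
    """One fixed effect of a two-way ANOVA plus pairwise group post hocs."""

    effect: str
    F: float
    df1: float
    df2: float
    p: float
    cohen_f: float
    posthoc: pd.DataFrame | None = None  # pairwise Bonferroni-adjusted group tests


def two_way_anova(df: pd.DataFrame, value: str, group: str = "group", condition: str = "condition") -> list[AnovaResult]:
    """Fixed-effects group x condition ANOVA with interaction.

    Requires at least two levels per factor.  Returns one ``AnovaResult`` per
    effect (group, condition, interaction); the group effect carries
    Bonferroni-adjusted pairwise comparisons (the family is the set of
    pairwise group contrasts within this one measure).
    """
    data = df[[value, group, condition]].dropna().rename(columns={value: "y", group: "g", condition: "c"})
    if data["g"].nunique() < 2:
        raise ValueError("need at least two group levels")
    one_condition = data["c"].nunique() < 2
    formula = "y ~ C(g, Sum)" if one_condition else "y ~ C(g, Sum) * C(c, Sum)"
    model = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(model, typ=3)
    ss_res = float(table.loc["Residual", "sum_sq"])
    df_res = float(table.loc["Residual", "df"])
    name_map = {
        "C(g, Sum)": "group",
        "C(c, Sum)": "condition",
        "C(g, Sum):C(c, Sum)": "interaction",
    }
    if one_condition:
        name_map = {"C(g, Sum)": "group"}
    results = []
    for key, label in name_map.items():
        F = float(table.loc[key, "F"])
        p = float(table.loc[key, "PR(>F)"])
        cohen_f = float(np.sqrt(table.loc[key, "sum_sq"] / ss_res))
        posthoc = _pairwise_groups(data) if label == "group" else None
        results.append(
            AnovaResult(effect=label, F=F, df1=float(table.loc[key, "df"]), df2=df_res, p=p, cohen_f=cohen_f, posthoc=posthoc)
        )
    return results


def _pairwise_groups(data: pd.DataFrame) -> pd.DataFrame:
    levels = sorted(data["g"].unique())
    pairs = list(combinations(levels, 2))
    rows = []
    for a, b in pairs:
        xa = data.loc[data["g"] == a, "y"]
        xb = data.loc[data["g"] == b, "y"]
        t, p = st.ttest_ind(xa, xb)
        rows.append({"a": a, "b": b, "t": float(t), "p_raw": float(p), "p_adj": bonferroni(p, len(pairs))})
    return pd.DataFrame(rows)


def nominal_t_test(values, nominal: float):
    """Two-tailed one-sample t-test against a parameter's error-free value.

    Returns ``(t, df, p)``.  Zero-variance samples off the nominal yield an
    infinite t (flagged by p = 0); exactly-nominal constant samples give
    t = 0, p = 1.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("need at least two values")
    if np.ptp(x) == 0:
        if x[0] == nominal:
            return 0.0, len(x) - 1, 1.0
        return float(np.inf) * np.sign(x[0] - nominal), len(x) - 1, 0.0
    t, p = st.ttest_1samp(x, nominal)
    return float(t), len(x) - 1, float(p)


def demographic_correlation(x, y):
    """Pearson correlation (r, two-tailed p) between a confound and a parameter."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        raise ValueError("need at least three paired finite values")
    r, p = st.pearsonr(x[keep], y[keep])
    return float(r), float(p)


def anova_power(effect_size_f: float, alpha: float, n_groups: int, n_total: int) -> float:
    """Achieved power of a fixed-effects one-factor main effect.

    Noncentral-F power with noncentrality ``lambda = f^2 * N`` at the given
    alpha; monotone increasing in both ``f`` and ``N``, equal to ``alpha`` at
    ``f = 0``.
    """
    if effect_size_f < 0:
        raise ValueError("effect size must be >= 0")
    df1 = n_groups - 1
    df2 = n_total - n_groups
    if df1 < 1 or df2 < 1:
        raise ValueError("invalid degrees of freedom")
    nc = effect_size_f**2 * n_total
    crit = st.f.isf(alpha, df1, df2)
    if nc == 0:
        return float(alpha)
    return float(st.ncf.sf(crit, df1, df2, nc))
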