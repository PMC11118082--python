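"""Group statistics on per-animal region summaries.

The emulated design has two groups (GBM, sham) and two regions per animal
(tumor/ipsilateral, contralateral).  The analysis per parameter is:

* Shapiro-Wilk normality check,
* a two-way (group x region) ANOVA over the four cells with Tukey HSD
  post hoc for the between-group comparisons (Type II sums of squares for
  the unbalanced 10-vs-4 design),
* a paired t-test for the within-group region comparison with a
  Holm-Sidak step-down adjustment across the family of parameters tested
  together,
* a 1.5 x IQR boxplot summary (linear-interpolation quantiles).

Significance is declared at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TestResult",
    "BoxplotSummary",
    "normality_check",
    "two_way_anova",
    "group_comparison",
    "paired_comparison",
    "holm_sidak",
    "boxplot_summary",
    "ALPHA",
]

ALPHA = 0.05


@dataclass
class TestResult:
    comparison: str
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str

    def __post_init__(self) -> None:
        for p in (self.p_raw, self.p_adjusted):
            if np.isfinite(p) and not 0.0 <= p <= 1.0 + 1e-12:
                raise ValueError("p-values must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_adjusted < ALPHA)


def normality_check(values) -> TestResult:
    """Shapiro-Wilk test of normality; requires 3 <= n <= 5000, non-constant."""
    values = np.asarray(values, dtype=float)
    if values.size < 3 or values.size > 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {values.size}")
    if np.ptp(values) == 0:
        raise ValueError("constant input: normality is undefined")
    w, p = sps.shapiro(values)
    return TestResult("normality", float(w), float(p), float(p), "shapiro-wilk")


def _validate_cells(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    df = table[table["parameter"] == parameter].copy()
    if df.empty:
        raise ValueError(f"no rows for parameter {parameter!r}")
    counts = df.groupby(["group", "region"], observed=True)["value"].count()
    for g in df["group"].unique():
        for r in df["region"].unique():
            n = counts.get((g, r), 0)
            if n < 2:
                raise ValueError(f"cell group={g!r}, region={r!r} has n={n} < 2")
    if df.groupby(["group", "region"], observed=True)["value"].var().fillna(0).sum() == 0:
        raise ValueError("all cells have zero variance: ANOVA undefined")
    return df


def two_way_anova(table: pd.DataFrame, parameter: str, typ: int = 2) -> list[TestResult]:
    """Two-way (group x region) ANOVA on the tidy table; Type II SS default
    (appropriate for the unbalanced 10-vs-4 design)."""
    df = _validate_cells(table, parameter)
    return _anova_results(df, typ)


def _anova_results(df: pd.DataFrame, typ: int) -> list[TestResult]:
    model = smf.ols("value ~ C(group) * C(region)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=typ)
    return [
        TestResult(str(effect).strip(), float(row["F"]), float(row["PR(>F)"]),
                   float(row["PR(>F)"]), f"two-way anova (type {typ})")
        for effect, row in anova.iterrows()
        if effect != "Residual"
    ]


def group_comparison(table: pd.DataFrame, parameter: str, typ: int = 2) -> dict:
    """Two-way ANOVA (group x region) plus Tukey HSD over the four cells.

    ``table`` is tidy with columns animal, group, region, parameter, value.
    Returns ``{"anova": [TestResult...], "tukey": [TestResult...]}``; Tukey
    p-values are family-wise adjusted by construction.
    """
    df = _validate_cells(table, parameter)
    anova_results = _anova_results(df, typ)
    cell = df["group"].astype(str) + ":" + df["region"].astype(str)
    tk = pairwise_tukeyhsd(df["value"].to_numpy(), cell.to_numpy(), alpha=ALPHA)
    tukey_results = []
    for row in tk.summary().data[1:]:
        g1, g2, meandiff, p_adj = row[0], row[1], row[2], row[3]
        tukey_results.append(
            TestResult(f"{g1} vs {g2}", float(meandiff), float(p_adj), float(p_adj), "tukey-hsd")
        )
    return {"anova": anova_results, "tukey": tukey_results}


def holm_sidak(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjustment.

    Sorted ascending, adj_i = 1 - (1 - p_i)^(m - i) for 0-based rank i, with
    monotonicity enforced; returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty_like(p)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def paired_comparison(
    table: pd.DataFrame, parameters: list[str] | str, group: str
) -> list[TestResult]:
    """Paired t-test (region A vs region B within ``group``) per parameter,
    Holm-Sidak adjusted across the parameter family of this call.

    Each animal must contribute exactly one value per region; the two
    regions present in the group define the pairing.
    """
    if isinstance(parameters, str):
        parameters = [parameters]
    sub = table[table["group"] == group]
    if sub.empty:
        raise ValueError(f"no rows for group {group!r}")
    regions = sorted(sub["region"].unique())
    if len(regions) != 2:
        raise ValueError(f"paired comparison needs exactly 2 regions, got {regions}")

    stats_p = []
    for param in parameters:
        d = sub[sub["parameter"] == param]
        wide = d.pivot(index="animal", columns="region", values="value")
        if wide.isna().any().any():
            missing = wide[wide.isna().any(axis=1)].index.tolist()
            raise ValueError(f"{param}: unpaired animals {missing}")
        a, b = wide[regions[0]].to_numpy(), wide[regions[1]].to_numpy()
        if np.allclose(a, b):
            stats_p.append((0.0, 1.0))
            continue
        t, p = sps.ttest_rel(a, b)
        stats_p.append((float(t), float(p)))

    adj = holm_sidak([p for _, p in stats_p])
    return [
        TestResult(
            f"{group}: {regions[0]} vs {regions[1]} ({param})",
            t, p, float(pa), "paired t, holm-sidak",
        )
        for param, (t, p), pa in zip(parameters, stats_p, adj)
    ]


@dataclass
class BoxplotSummary:
    median: float
    mean: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def boxplot_summary(values) -> BoxplotSummary:
    """Median/quartile/whisker summary per the 1.5 x IQR convention.

    Quartiles use linear interpolation; whiskers extend to the most extreme
    data points within 1.5 x IQR of the nearest quartile.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_lim) & (v <= hi_lim)]
    return BoxplotSummary(
        median=float(med),
        mean=float(v.mean()),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=np.sort(v[(v < lo_lim) | (v > hi_lim)]),
    )
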