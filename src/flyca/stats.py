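"""Statistical battery for the imaging metrics.

Covers the tests used for fly-level comparisons: two-tailed Student t tests
(paired/unpaired, classical pooled variance), one-way ANOVA with
Bonferroni-Holm-corrected pairwise t tests, unbalanced two-way ANOVA
(Type II sums of squares) with Tukey-Kramer HSD on cell means, and a
Monte-Carlo Lilliefors normality test.  Results come back as
:class:`StatResult` records with significance stars at 0.05/0.01/0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "t_test",
    "holm_adjust",
    "one_way_anova_holm",
    "two_way_anova_tukey",
    "tukey_hsd_cellmeans",
    "lilliefors",
    "lilliefors_statistic",
    "lilliefors_critical_value",
    "significance_stars",
]


@dataclass
class StatResult:
    test: str
    statistic: float
    df: tuple | float
    p: float
    p_adjusted: float | None = None
    adjust_method: str | None = None
    groups: tuple = ()

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted if self.p_adjusted is not None
                                  else self.p)


def significance_stars(p: float) -> str:
    """'*' p<0.05, '**' p<0.01, '***' p<0.001, else 'ns'."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def t_test(x, y, paired: bool = False, welch: bool = False) -> StatResult:
    """Two-tailed Student t test for paired or independent samples.

    Unpaired tests use the classical pooled-variance statistic by default;
    ``welch=True`` switches to the unequal-variance form.  A paired test on
    differences with zero variance is undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        if len(x) < 2:
            raise ValueError("need n >= 2")
        d = x - y
        if np.std(d, ddof=1) == 0:
            raise ValueError("zero variance of paired differences: t undefined")
        res = sps.ttest_rel(x, y)
        return StatResult("paired t", float(res.statistic), float(len(x) - 1),
                          float(res.pvalue))
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per group")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = res.df if hasattr(res, "df") else len(x) + len(y) - 2
    name = "welch t" if welch else "unpaired t"
    return StatResult(name, float(res.statistic), float(df), float(res.pvalue))


def holm_adjust(pvals) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment.

    Sort ascending, multiply the i-th smallest by (m - i), take the running
    maximum, cap at 1, and restore the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def one_way_anova_holm(groups, labels=None) -> tuple[StatResult, list[StatResult]]:
    """One-way ANOVA followed by Holm-corrected pairwise two-tailed t tests."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    f, p = sps.f_oneway(*groups)
    df = (len(groups) - 1, sum(len(g) for g in groups) - len(groups))
    omnibus = StatResult("one-way ANOVA", float(f), df, float(p),
                         groups=tuple(labels))
    pairs = list(combinations(range(len(groups)), 2))
    raw = [t_test(groups[i], groups[j]) for i, j in pairs]
    adj = holm_adjust([r.p for r in raw])
    pairwise = [
        StatResult("unpaired t", r.statistic, r.df, r.p, float(a), "holm",
                   (labels[i], labels[j]))
        for r, a, (i, j) in zip(raw, adj, pairs)
    ]
    return omnibus, pairwise


def two_way_anova_tukey(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "A",
    factor_b: str = "B",
) -> tuple[list[StatResult], pd.DataFrame]:
    """Unbalanced two-way ANOVA (Type II SS) + Tukey-Kramer HSD on cell means.

    Main effects and (when every A x B cell is populated) the interaction
    are tested from an OLS fit with Type II sums of squares.  Pairwise
    comparisons between the A x B cell means use the studentized-range
    distribution with the Tukey-Kramer unequal-n standard error.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for fac in (factor_a, factor_b):
        if table[fac].nunique() < 2:
            raise ValueError(f"factor {fac!r} needs at least 2 levels")
    df = table.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    cells = df.groupby(["_a", "_b"], observed=True)["_y"]
    counts = cells.count()
    n_a, n_b = df["_a"].nunique(), df["_b"].nunique()
    full_grid = len(counts) == n_a * n_b
    if not full_grid:
        warnings.warn("empty cells: interaction term dropped", stacklevel=2)
        model = smf.ols("_y ~ C(_a) + C(_b)", data=df).fit()
    else:
        model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    effects = []
    name_map = {"C(_a)": factor_a, "C(_b)": factor_b,
                "C(_a):C(_b)": f"{factor_a}:{factor_b}"}
    resid_df = float(aov.loc["Residual", "df"])
    for row, label in name_map.items():
        if row in aov.index:
            effects.append(StatResult(
                f"two-way ANOVA: {label}", float(aov.loc[row, "F"]),
                (float(aov.loc[row, "df"]), resid_df),
                float(aov.loc[row, "PR(>F)"])))
    mse = float(aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"])
    samples = {key: grp.to_numpy() for key, grp in cells}
    tukey = tukey_hsd_cellmeans(samples, mse=mse, df_resid=resid_df)
    return effects, tukey


def tukey_hsd_cellmeans(samples: dict, mse: float | None = None,
                        df_resid: float | None = None) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons between cell means.

    ``samples`` maps cell label -> observations.  By default the error
    variance is the pooled within-cell variance; pass ``mse``/``df_resid``
    to reuse a fitted model's residual variance.  The q statistic uses the
    Tukey-Kramer unequal-n standard error
    ``sqrt(mse/2 * (1/n_i + 1/n_j))`` (harmonic-mean cell sizes), so for
    two cells q reduces to ``|t| * sqrt(2)`` of the pooled two-sample t.
    """
    labels = list(samples)
    arrs = {c: np.asarray(samples[c], dtype=float) for c in labels}
    if mse is None or df_resid is None:
        n_total = sum(len(a) for a in arrs.values())
        df_resid = float(n_total - len(labels))
        if df_resid <= 0:
            raise ValueError("no residual degrees of freedom")
        mse = sum(((a - a.mean()) ** 2).sum() for a in arrs.values()) / df_resid
    k = len(labels)
    rows = []
    for ca, cb in combinations(labels, 2):
        a, b = arrs[ca], arrs[cb]
        diff = a.mean() - b.mean()
        se = np.sqrt(mse / 2.0 * (1.0 / len(a) + 1.0 / len(b)))
        q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_resid))
        rows.append({"cell_1": ca, "cell_2": cb, "diff": diff, "q": q,
                     "p_tukey": p, "stars": significance_stars(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Lilliefors

def lilliefors_statistic(sample: np.ndarray) -> float:
    """KS distance of the standardized sample to the standard normal CDF."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("zero-variance sample")
    z = (x - x.mean()) / s
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - cdf, cdf - (i - 1) / n)))


def _null_statistics(n: int, n_mc: int, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal((n_mc, n))
    z.sort(axis=1)
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    return np.maximum(i / n - cdf, cdf - (i - 1) / n).max(axis=1)


def lilliefors(sample, n_mc: int = 10_000, seed: int = 0) -> StatResult:
    """Lilliefors normality test with a seeded Monte-Carlo null.

    The KS statistic is computed against a normal with estimated mean/sd;
    its null distribution is parameter free, so the p value comes from
    ``n_mc`` standard-normal samples of the same size (identical seeds give
    identical p values).
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 4:
        raise ValueError("need n >= 4")
    d = lilliefors_statistic(x)
    rng = np.random.default_rng(seed)
    null = _null_statistics(len(x), n_mc, rng)
    p = (1.0 + np.count_nonzero(null >= d)) / (n_mc + 1.0)
    return StatResult("lilliefors", d, float(len(x)), float(p))


def lilliefors_critical_value(n: int, alpha: float = 0.05,
                              n_mc: int = 20_000, seed: int = 0) -> float:
    """Monte-Carlo critical value of the Lilliefors statistic.

    Rejecting when D exceeds this value is equivalent to ``p < alpha`` under
    a shared null sample — handy when screening many datasets.
    """
    rng = np.random.default_rng(seed)
    null = _null_statistics(n, n_mc, rng)
    return float(np.quantile(null, 1.0 - alpha))
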