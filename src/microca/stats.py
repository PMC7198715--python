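"""Cohort-level statistics.

The statistical conventions of the source workflow: data summarised as
median ± IQR; normality screened by a one-sample Kolmogorov–Smirnov test;
outliers flagged by Tukey fences; age groups compared by Kruskal–Wallis
with Dunn's pairwise post hoc z tests (Bonferroni family-wise adjustment);
control-vs-CR comparisons by the Mann–Whitney U test; age × sex (or diet)
interactions by two-way ANOVA with Bonferroni-adjusted post-hoc pairwise
comparisons.

The analysis level matters: per-cell metrics (frequency, amplitude, T-half,
AUC) and per-mouse metrics (fraction active, Spearman r, formation
velocity) must not be mixed; :class:`GroupedValues` carries the declared
level so pipelines can enforce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "GroupedValues",
    "ComparisonResult",
    "tukey_outliers",
    "ks_normality",
    "kruskal_dunn",
    "mann_whitney",
    "twoway_bonferroni",
    "median_iqr",
]

ALPHA = 0.05
# total-N bound below which the Kruskal-Wallis omnibus p is computed by full
# enumeration of group assignments instead of the chi-square approximation
KW_EXACT_N_MAX = 12


@dataclass
class GroupedValues:
    """Values with group labels and a declared analysis level."""

    values: np.ndarray
    labels: np.ndarray
    unit: str = ""
    level: str = "per_cell"  # or "per_mouse"
    labels2: Optional[np.ndarray] = None  # optional second factor

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if len(self.values) != len(self.labels):
            raise ValueError("values and labels must have equal length")
        if self.labels2 is not None:
            self.labels2 = np.asarray(self.labels2)
            if len(self.labels2) != len(self.values):
                raise ValueError("labels2 must match values in length")

    def groups(self) -> dict:
        return {
            lab: self.values[self.labels == lab] for lab in pd.unique(self.labels)
        }


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    pairwise: list[tuple] = field(default_factory=list)  # (a, b, adjusted_p)
    alpha: float = ALPHA
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Descriptives and screening
# ---------------------------------------------------------------------------

def median_iqr(values: Sequence[float]) -> dict:
    """Median, IQR and the percentiles behind box-and-whisker summaries.

    Quartiles use linear interpolation; whisker percentiles are 10/90 as in
    the box plots this summary feeds.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("median_iqr of empty data")
    q10, q25, q50, q75, q90 = np.percentile(v, [10, 25, 50, 75, 90])
    return {
        "median": float(q50),
        "iqr": float(q75 - q25),
        "q1": float(q25),
        "q3": float(q75),
        "p10": float(q10),
        "p90": float(q90),
        "n": int(v.size),
    }


def tukey_outliers(values: Sequence[float]) -> np.ndarray:
    """Inclusion mask by the Tukey fences.

    True where a value lies inside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; quartiles
    by linear interpolation.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for Tukey fences")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)


def ks_normality(values: Sequence[float]) -> float:
    """One-sample KS test against a normal with the sample mean and SD.

    Estimating the reference parameters from the sample makes the test
    conservative (as commonly applied); use it as a screen, not a verdict.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 values for the KS normality screen")
    sd = np.std(v, ddof=1)
    if sd == 0:
        raise ValueError("zero variance: KS normality test undefined")
    return float(sstats.kstest(v, "norm", args=(np.mean(v), sd)).pvalue)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def _kw_statistic(values: np.ndarray, group_sizes: Sequence[int]) -> float:
    """Tie-corrected Kruskal-Wallis H for values ordered by group."""
    ranks = sstats.rankdata(values)
    n = len(values)
    h = 0.0
    pos = 0
    for gn in group_sizes:
        h += np.sum(ranks[pos : pos + gn]) ** 2 / gn
        pos += gn
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def _kw_exact_p(values: np.ndarray, group_sizes: Sequence[int]) -> float:
    """Exact omnibus p by full enumeration of group assignments."""
    from itertools import combinations as comb

    h_obs = _kw_statistic(values, group_sizes)
    idx_all = tuple(range(len(values)))
    count = 0
    total = 0

    def recurse(remaining: tuple, sizes: list[int], chosen: list):
        nonlocal count, total
        if not sizes:
            perm = np.concatenate([values[list(c)] for c in chosen])
            h = _kw_statistic(perm, group_sizes)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
            return
        for c in comb(remaining, sizes[0]):
            rest = tuple(i for i in remaining if i not in c)
            recurse(rest, sizes[1:], chosen + [list(c)])

    recurse(idx_all, list(group_sizes), [])
    return count / total


def kruskal_dunn(
    grouped: GroupedValues,
    alpha: float = ALPHA,
    method: str = "auto",
) -> ComparisonResult:
    """Kruskal-Wallis omnibus test with Dunn's pairwise post hoc.

    The omnibus H statistic is tie-corrected. With ``method="auto"`` the
    omnibus p is exact (full enumeration) for small samples (total
    N ≤ 12) and the chi-square approximation otherwise. If the omnibus test
    is significant at ``alpha``, Dunn's pairwise z tests are run over all
    group pairs with Bonferroni family-wise adjustment (the common "Dunn's
    multiple comparisons" convention).

    Raises
    ------
    ValueError
        With fewer than 3 groups or any group of n < 3 (named in the error).
    """
    groups = grouped.groups()
    if len(groups) < 3:
        raise ValueError(f"need >= 3 groups, got {len(groups)}")
    for name, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {name!r} has n = {len(vals)} < 3")
    names = list(groups)
    arrays = [groups[name] for name in names]
    sizes = [len(a) for a in arrays]
    pooled = np.concatenate(arrays)
    n = len(pooled)

    h = _kw_statistic(pooled, sizes)
    if method == "exact" or (method == "auto" and n <= KW_EXACT_N_MAX):
        p = _kw_exact_p(pooled, sizes)
        p_method = "exact"
    elif method in ("auto", "chi2"):
        p = float(sstats.chi2.sf(h, df=len(names) - 1))
        p_method = "chi2"
    else:
        raise ValueError(f"unknown method {method!r}")

    pairwise: list[tuple] = []
    if p < alpha:
        ranks = sstats.rankdata(pooled)
        mean_ranks = {}
        pos = 0
        for name, gn in zip(names, sizes):
            mean_ranks[name] = np.mean(ranks[pos : pos + gn])
            pos += gn
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1))
        m = len(names) * (len(names) - 1) // 2
        for (na, ga), (nb, gb) in combinations(zip(names, sizes), 2):
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ga + 1.0 / gb))
            z = (mean_ranks[na] - mean_ranks[nb]) / se
            p_raw = 2.0 * sstats.norm.sf(abs(z))
            pairwise.append((na, nb, min(1.0, m * p_raw)))

    return ComparisonResult(
        test_name="kruskal_dunn",
        statistic=float(h),
        p_value=p,
        pairwise=pairwise,
        alpha=alpha,
        details={"groups": names, "n": sizes, "p_method": p_method},
    )


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def mann_whitney(
    a: Sequence[float], b: Sequence[float], alpha: float = ALPHA
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    Exact p for small samples without ties, normal approximation with
    tie/continuity correction otherwise (scipy's ``method="auto"`` rule).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"both samples need n >= 3 (got {len(a)}, {len(b)})")
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return ComparisonResult(
        test_name="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alpha=alpha,
        details={"n": [len(a), len(b)]},
    )


# ---------------------------------------------------------------------------
# Two-way ANOVA + Bonferroni post hoc
# ---------------------------------------------------------------------------

def twoway_bonferroni(
    grouped: GroupedValues,
    alpha: float = ALPHA,
    posthoc_factor: str = "A",
) -> ComparisonResult:
    """Two-factor ANOVA with interaction and Bonferroni post-hoc comparisons.

    Type II sums of squares (robust to unbalanced cells). Post hoc: pairwise
    t comparisons (pooled residual MSE) between levels of the factor of
    interest at each level of the other factor, p values multiplied by the
    total number of comparisons (capped at 1).

    The omnibus ``statistic``/``p_value`` reported are those of the
    interaction term; main-effect F and p live in ``details``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if grouped.labels2 is None:
        raise ValueError("two-way ANOVA needs a second factor (labels2)")
    df = pd.DataFrame(
        {
            "y": grouped.values,
            "A": pd.Categorical(grouped.labels),
            "B": pd.Categorical(grouped.labels2),
        }
    )
    counts = df.groupby(["A", "B"], observed=False).size()
    empty = counts[counts == 0]
    if len(empty):
        cell = empty.index[0]
        raise ValueError(f"empty design cell {cell[0]!r} × {cell[1]!r}")
    small = counts[counts < 2]
    if len(small):
        cell = small.index[0]
        raise ValueError(f"design cell {cell[0]!r} × {cell[1]!r} has n < 2")

    if np.ptp(grouped.values) == 0:
        # degenerate: no variance anywhere; all effects vanish
        return ComparisonResult(
            test_name="twoway_bonferroni",
            statistic=0.0,
            p_value=1.0,
            alpha=alpha,
            details={"F_A": 0.0, "p_A": 1.0, "F_B": 0.0, "p_B": 1.0, "degenerate": True},
        )

    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    f_a, p_a = table.loc["C(A)", ["F", "PR(>F)"]]
    f_b, p_b = table.loc["C(B)", ["F", "PR(>F)"]]
    f_int, p_int = table.loc["C(A):C(B)", ["F", "PR(>F)"]]
    mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    df_resid = float(table.loc["Residual", "df"])

    fac, other = ("A", "B") if posthoc_factor == "A" else ("B", "A")
    comps = []
    for lev_other in df[other].cat.categories:
        sub = df[df[other] == lev_other]
        for la, lb in combinations(df[fac].cat.categories, 2):
            ya = sub.loc[sub[fac] == la, "y"].to_numpy()
            yb = sub.loc[sub[fac] == lb, "y"].to_numpy()
            if len(ya) == 0 or len(yb) == 0:
                continue
            se = np.sqrt(mse * (1.0 / len(ya) + 1.0 / len(yb)))
            tstat = (np.mean(ya) - np.mean(yb)) / se
            p_raw = 2.0 * sstats.t.sf(abs(tstat), df_resid)
            comps.append((f"{la}|{lev_other}", f"{lb}|{lev_other}", p_raw))
    m = len(comps)
    pairwise = [(a_, b_, min(1.0, m * p_)) for a_, b_, p_ in comps]

    return ComparisonResult(
        test_name="twoway_bonferroni",
        statistic=float(f_int),
        p_value=float(p_int),
        pairwise=pairwise,
        alpha=alpha,
        details={
            "F_A": float(f_a),
            "p_A": float(p_a),
            "F_B": float(f_b),
            "p_B": float(p_b),
            "anova_typ": 2,
            "n_comparisons": m,
        },
    )
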