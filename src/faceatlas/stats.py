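"""Rater-variability and atlas-comparison statistics.

Implements the tests used to analyse segmentation agreement: a tie-corrected
Friedman test across repeated conditions, Bonferroni-corrected pairwise
post-hoc tests (Wilcoxon signed-rank for paired series, Mann-Whitney U for
independent groups), a single-measure absolute-agreement intraclass
correlation coefficient from repeated-measures ANOVA mean squares,
Kruskal-Wallis analysis of variance, and the t-test on the slope of an
ordinary least-squares fit (used against the cubic root of segmentation
volume).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "friedman_test",
    "pairwise_posthoc",
    "icc",
    "kruskal_wallis",
    "slope_ttest",
    "standardized_effect",
]


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    df: float | tuple
    significant: bool
    alpha: float
    name: str = ""
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def _as_table(data) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2D cases x conditions table")
    if not np.all(np.isfinite(arr)):
        raise ValueError("table has missing or non-finite cells")
    return arr


# enumeration ceilings below which the exact permutation null is computed
_FRIEDMAN_EXACT_LIMIT = 20_000
_KW_EXACT_LIMIT = 50_000


def _friedman_stat(ranks: np.ndarray) -> float:
    n, k = ranks.shape
    mean_rank = (k + 1) / 2.0
    denom = np.sum((ranks - mean_rank) ** 2)
    if denom == 0:  # every case ranks all conditions identically
        return 0.0
    return float((k - 1) * np.sum((ranks.sum(axis=0) - n * mean_rank) ** 2) / denom)


def friedman_test(data, alpha: float = 0.05, exact: bool | None = None) -> StatResult:
    """Friedman test on a cases x conditions table (tie-corrected).

    Within-case ranks (ties averaged) give the statistic
    ``chi2_F = (k-1) * sum_j (R_j - n(k+1)/2)^2 / sum_ij (r_ij - (k+1)/2)^2``
    which reduces to the textbook form when there are no ties.  For small
    tables (up to ~20k within-case permutations) the p-value is computed by
    exact enumeration of the permutation null, where the chi-squared
    approximation with k-1 degrees of freedom is unreliable; larger tables
    use the chi-squared tail.  ``exact`` forces either path.
    """
    table = _as_table(data)
    n, k = table.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 cases and >= 2 conditions")
    ranks = np.apply_along_axis(sps.rankdata, 1, table)
    stat = _friedman_stat(ranks)
    import itertools
    import math

    n_perm = math.factorial(k) ** n
    use_exact = exact if exact is not None else n_perm <= _FRIEDMAN_EXACT_LIMIT
    if use_exact:
        perms = [list(p) for p in itertools.permutations(range(k))]
        count = 0
        for combo in itertools.product(perms, repeat=n):
            permuted = np.array([ranks[i, c] for i, c in enumerate(combo)])
            count += _friedman_stat(permuted) >= stat - 1e-12
        p = count / n_perm
    else:
        p = float(sps.chi2.sf(stat, k - 1))
    return StatResult(float(stat), p, k - 1, p < alpha, alpha, name="friedman")


def _kw_stat(rank_sums: np.ndarray, sizes: np.ndarray, n_total: int, tie_term: float) -> float:
    h = 12.0 / (n_total * (n_total + 1)) * np.sum(rank_sums**2 / sizes) - 3 * (n_total + 1)
    return float(h / tie_term) if tie_term > 0 else 0.0


def kruskal_wallis(groups, alpha: float = 0.05, exact: bool | None = None) -> StatResult:
    """Kruskal-Wallis rank ANOVA across independent groups (tie-corrected).

    For small designs (up to ~50k distinct assignments of the pooled values
    to the groups) the p-value is the exact permutation tail; otherwise the
    chi-squared approximation with g-1 degrees of freedom is used.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    g = len(groups)
    if np.ptp(pooled) == 0:
        return StatResult(0.0, 1.0, g - 1, False, alpha, name="kruskal-wallis")
    sizes = np.array([len(x) for x in groups])
    n_total = int(sizes.sum())
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    bounds = np.cumsum(sizes)[:-1]
    rank_sums = np.array([s.sum() for s in np.split(ranks, bounds)])
    stat = _kw_stat(rank_sums, sizes, n_total, tie_term)

    import itertools
    import math

    n_assign = math.factorial(n_total) // math.prod(math.factorial(s) for s in sizes)
    use_exact = exact if exact is not None else n_assign <= _KW_EXACT_LIMIT
    if use_exact:
        count = total = 0

        def recurse(remaining: tuple, gi: int, sums: list):
            nonlocal count, total
            if gi == g - 1:
                s = list(sums) + [ranks[list(remaining)].sum()]
                total += 1
                count += _kw_stat(np.array(s), sizes, n_total, tie_term) >= stat - 1e-12
                return
            for pick in itertools.combinations(remaining, int(sizes[gi])):
                rest = tuple(i for i in remaining if i not in pick)
                recurse(rest, gi + 1, sums + [ranks[list(pick)].sum()])

        recurse(tuple(range(n_total)), 0, [])
        p = count / total
    else:
        p = float(sps.chi2.sf(stat, g - 1))
    return StatResult(float(stat), p, g - 1, p < alpha, alpha, name="kruskal-wallis")


def pairwise_posthoc(
    data,
    comparisons: list[tuple],
    alpha_adjusted: float,
    paired: bool = True,
) -> list[StatResult]:
    """Bonferroni-style post-hoc tests for named condition pairs.

    ``data`` maps condition ids to value arrays (dict or DataFrame columns).
    Paired comparisons use the Wilcoxon signed-rank test (conditions share
    cases); unpaired use Mann-Whitney U.  Each result is flagged significant
    at the supplied adjusted level (0.05 / m for m comparisons).
    """
    cols = dict(data)
    out = []
    for a, b in comparisons:
        if a not in cols or b not in cols:
            raise KeyError(f"unknown condition id in comparison ({a}, {b})")
        x = np.asarray(cols[a], dtype=float)
        y = np.asarray(cols[b], dtype=float)
        if paired:
            if len(x) != len(y):
                raise ValueError("paired comparison requires equal-length series")
            if np.allclose(x, y):
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.wilcoxon(x, y)
        else:
            stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        out.append(
            StatResult(
                float(stat),
                float(p),
                (len(x), len(y)),
                p < alpha_adjusted,
                alpha_adjusted,
                name=f"{a} vs {b}",
            )
        )
    return out


def icc(volumes, alpha: float = 0.05, form: str = "A-1") -> StatResult:
    """Intraclass correlation of a cases x raters table from two-way
    repeated-measures ANOVA mean squares.

    Default form ``"A-1"``: two-way, absolute agreement, single measure,
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``.
    Form ``"C-1"`` (consistency) is ``(MSR - MSE) / (MSR + (k-1) MSE)``.
    The p-value is from the F test of the case effect, MSR/MSE.
    """
    table = _as_table(volumes)
    n, k = table.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 cases and >= 2 raters")
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = np.sum((table - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 0 or (ss_rows == 0 and ss_err == 0 and ss_cols == 0):
        raise ValueError("zero between-case variance: ICC undefined")
    if form == "A-1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "C-1":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC form: {form!r} (use 'A-1' or 'C-1')")
    value = (msr - mse) / denom if denom > 0 else 1.0
    if mse == 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = msr / mse
        p = float(sps.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))
    return StatResult(
        float(value),
        p,
        (n - 1, (n - 1) * (k - 1)),
        p < alpha,
        alpha,
        name=f"ICC({form})",
        extra={"msr": msr, "msc": msc, "mse": mse, "f": float(f_stat)},
    )


def slope_ttest(x, y, alpha: float = 0.05) -> StatResult:
    """Two-sided t-test on the OLS slope of y against x (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope undefined")
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    resid = y - (y.mean() + slope * (x - x.mean()))
    dof = len(x) - 2
    se2 = np.sum(resid**2) / dof / sxx
    if se2 <= 0:
        p = 1.0 if slope == 0 else 0.0  # exact fit: p below any tolerance
        t = 0.0 if slope == 0 else np.inf
    else:
        t = slope / np.sqrt(se2)
        p = float(2 * sps.t.sf(abs(t), dof))
    return StatResult(
        float(slope),
        p,
        dof,
        p < alpha,
        alpha,
        name="slope t-test",
        extra={"t": float(t), "intercept": float(y.mean() - slope * x.mean())},
    )


def standardized_effect(inter_values, intra_values) -> float:
    """(mean inter - mean intra) / pooled SD, a plain standardized difference."""
    a = np.asarray(inter_values, dtype=float)
    b = np.asarray(intra_values, dtype=float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)
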