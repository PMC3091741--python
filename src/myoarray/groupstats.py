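"""Group-comparison statistics: one-way ANOVA, Newman-Keuls, regression.

These back the wet-lab validation stages (qPCR fold changes, densitometry
ratios, weight correlations).  The ANOVA is the standard fixed-effects
sum-of-squares decomposition; the post hoc is the Newman-Keuls step-down
procedure on the studentized range, with the Kramer pairwise standard error
``sqrt(MSE/2 * (1/n_i + 1/n_j))`` so unbalanced groups are handled; the
regression is ordinary least squares with the two-sided correlation t-test
``t = r * sqrt((n-2) / (1 - r^2))`` on n-2 degrees of freedom.

Newman-Keuls step-down: means are sorted; a pair spanning ``p`` means is
compared against the studentized-range critical value ``q_crit(p, df, alpha)``;
whenever a range is non-significant, every pair nested inside it is declared
non-significant without testing (``blocked``).  This keeps the procedure
coherent (no significant pair inside a non-significant range).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    mse: float
    group_means: tuple[float, ...]
    group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class PairComparison:
    """One Newman-Keuls pair, in sorted-mean coordinates."""

    group_i: int          # caller's group index, smaller mean
    group_j: int          # caller's group index, larger mean
    span: int             # number of means spanned, inclusive
    q: float              # studentized-range statistic
    q_critical: float
    p_value: float        # tail probability of q at this span
    significant: bool
    blocked: bool         # True if declared non-significant without testing


@dataclass(frozen=True)
class PosthocResult:
    alpha: float
    comparisons: tuple[PairComparison, ...]

    def significant_pairs(self) -> list[tuple[int, int]]:
        return [(c.group_i, c.group_j) for c in self.comparisons if c.significant]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    n: int


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2:
        raise ValidationError("need at least two groups")
    for i, g in enumerate(out):
        if g.ndim != 1 or len(g) < 2:
            raise ValidationError(f"group {i} needs at least two observations")
        if not np.all(np.isfinite(g)):
            raise ValidationError(f"group {i} contains non-finite values")
    return out


def one_way_anova(groups) -> AnovaResult:
    """Fixed-effects one-way ANOVA via the sum-of-squares decomposition."""
    gs = _as_groups(groups)
    k = len(gs)
    ns = np.array([len(g) for g in gs])
    n_total = int(ns.sum())
    means = np.array([g.mean() for g in gs])
    grand = sum(g.sum() for g in gs) / n_total
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(gs, means)))
    df_b, df_w = k - 1, n_total - k
    mse = ss_within / df_w
    if ss_within == 0:
        f = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df_b) / mse
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(
        f_statistic=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        mse=mse,
        group_means=tuple(means),
        group_sizes=tuple(int(n) for n in ns),
    )


def studentized_range_critical(span: int, df: int, alpha: float) -> float:
    """Upper-alpha critical value of the studentized range q(span, df)."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    return float(stats.studentized_range.ppf(1 - alpha, span, df))


def newman_keuls(groups, alpha: float = 0.05) -> PosthocResult:
    """Newman-Keuls step-down comparison of all group-mean pairs.

    Groups are referenced by their position in ``groups``; each returned
    :class:`PairComparison` reports the pair with the smaller mean first.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    gs = _as_groups(groups)
    anova = one_way_anova(gs)
    means = np.array(anova.group_means)
    ns = np.array(anova.group_sizes)
    order = np.argsort(means, kind="stable")  # ascending means
    k = len(gs)
    df_w = anova.df_within

    # nonsig[a][b]: sorted-position range (a, b) found (or declared) non-sig
    results: dict[tuple[int, int], PairComparison] = {}
    nonsig_ranges: list[tuple[int, int]] = []

    for span in range(k, 1, -1):
        for a in range(0, k - span + 1):
            b = a + span - 1
            gi, gj = order[a], order[b]
            diff = means[gj] - means[gi]
            se = np.sqrt(anova.mse / 2.0 * (1.0 / ns[gi] + 1.0 / ns[gj]))
            blocked = any(lo <= a and b <= hi for lo, hi in nonsig_ranges)
            if anova.mse == 0:
                q = np.inf if diff > 0 else 0.0
                p_tail = 0.0 if diff > 0 else 1.0
            else:
                q = diff / se
                p_tail = float(stats.studentized_range.sf(q, span, df_w))
            crit = studentized_range_critical(span, df_w, alpha)
            significant = (not blocked) and q > crit
            if not significant:
                nonsig_ranges.append((a, b))
            results[(a, b)] = PairComparison(
                group_i=int(gi),
                group_j=int(gj),
                span=span,
                q=float(q),
                q_critical=float(crit),
                p_value=p_tail,
                significant=significant,
                blocked=blocked,
            )
    ordered = tuple(results[key] for key in sorted(results))
    return PosthocResult(alpha=alpha, comparisons=ordered)


def linear_regression(x, y) -> RegressionResult:
    """Least-squares line with the two-sided test of zero slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("regression needs at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("regression requires finite values")
    sxx = float(((x - x.mean()) ** 2).sum())
    syy = float(((y - y.mean()) ** 2).sum())
    if sxx == 0:
        raise ValidationError("x is constant; slope undefined")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy == 0:
        warnings.warn("y is constant; correlation undefined, reported as 0",
                      UserWarning, stacklevel=2)
        return RegressionResult(slope=0.0, intercept=float(y.mean()),
                                r=0.0, r_squared=0.0, p_value=1.0, n=n)
    r = sxy / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return RegressionResult(slope=float(slope), intercept=intercept,
                            r=r, r_squared=r * r, p_value=p, n=n)
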