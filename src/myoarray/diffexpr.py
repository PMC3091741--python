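"""Per-contrast F-tests, signed geometric-mean fold changes, gene collapsing.

Each contrast compares two cells of the 2x2 (timepoint x treatment) design
with a one-way fixed-effects F-test on log2 expression — for two groups this
is exactly the pooled-variance t-test (F = t^2).  Fold changes are ratios of
group geometric means reported with the signed convention used throughout
denervation-atrophy microarray work: +r for ratios >= 1 and -1/r otherwise,
so a halving is written -2.0 rather than 0.5.

Probe-level results are collapsed to unique known genes by keeping, for each
gene symbol, the probe with the smallest p-value (ties: larger absolute fold
change, then lexicographic probe ID).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ComputationError, ValidationError
from .expression_io import (
    NANDROLONE,
    VEHICLE,
    ExpressionMatrix,
    ProbeAnnotation,
    SampleDesign,
)

Group = tuple[int, str]  # (timepoint in days, treatment)


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison within the 2x2 design."""

    name: str
    group_a: Group
    group_b: Group
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValidationError("contrast groups must differ")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


#: The three standard contrasts: drug effect at each timepoint at alpha 0.05,
#: and the pure time effect in vehicle-treated muscle at the stricter 0.01.
NAN7 = Contrast("NAN7", (7, NANDROLONE), (7, VEHICLE), alpha=0.05)
NAN35 = Contrast("NAN35", (35, NANDROLONE), (35, VEHICLE), alpha=0.05)
TIME = Contrast("TIME", (35, VEHICLE), (7, VEHICLE), alpha=0.01)
STANDARD_CONTRASTS = {c.name: c for c in (NAN7, NAN35, TIME)}


class DegenerateVarianceWarning(UserWarning):
    """Raised when within-group variance is exactly zero but means differ."""


# ---------------------------------------------------------------------------
# core statistics
# ---------------------------------------------------------------------------

def group_f_test(values, labels) -> float:
    """One-way fixed-effects F-test p-value on a single probe's log2 values.

    ``labels`` assigns each observation to a group (any hashable labels,
    k >= 2 groups of >= 2 observations each).  With zero within-group
    variance the p-value degenerates: 0 if any means differ (with a
    :class:`DegenerateVarianceWarning`), 1 if all means are equal.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValidationError("values and labels must have equal length")
    if not np.all(np.isfinite(values)):
        raise ValidationError("F-test requires finite values")
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValidationError("F-test needs at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValidationError("every group needs at least two observations")
    blocks = [np.asarray(g)[None, :] for g in groups]
    p = _f_test_rows(blocks)[0]
    return float(p)


def _f_test_rows(group_blocks: list[np.ndarray]) -> np.ndarray:
    """Vectorized one-way ANOVA p-values.

    ``group_blocks[i]`` is an (n_rows x n_i) block of observations for group
    i; the F statistic is computed independently for every row.
    """
    ns = np.array([b.shape[1] for b in group_blocks])
    k = len(group_blocks)
    n_total = int(ns.sum())
    means = np.column_stack([b.mean(axis=1) for b in group_blocks])
    grand = np.column_stack([b.sum(axis=1) for b in group_blocks]).sum(axis=1) / n_total
    ss_between = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = np.zeros_like(ss_between)
    for b, m in zip(group_blocks, means.T):
        ss_within += ((b - m[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n_total - k
    p = np.ones_like(ss_between)
    ok = ss_within > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between[ok] / df_b) / (ss_within[ok] / df_w)
    p[ok] = stats.f.sf(f, df_b, df_w)
    degenerate = (~ok) & (ss_between > 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} probe(s) with zero within-group variance "
            "and unequal means; p set to 0",
            DegenerateVarianceWarning,
            stacklevel=3,
        )
        p[degenerate] = 0.0
    return p


def geometric_fold_change(values_a, values_b) -> float:
    """Signed ratio of geometric means: +r if geomean(a) >= geomean(b), else -1/r."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if (a <= 0).any() or (b <= 0).any():
        raise ValidationError("geometric fold change requires positive values "
                              "(has the floor been applied?)")
    log2fc = np.mean(np.log2(a)) - np.mean(np.log2(b))
    return float(_signed_from_log2(np.array([log2fc]))[0])


def _signed_from_log2(log2fc: np.ndarray) -> np.ndarray:
    """Map log2 ratios to the signed ratio convention (+r / -1/r, |.| >= 1)."""
    r = np.exp2(np.abs(log2fc))
    return np.where(log2fc >= 0, r, -r)


# ---------------------------------------------------------------------------
# contrast runner
# ---------------------------------------------------------------------------

def run_contrast(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    contrast: Contrast,
) -> pd.DataFrame:
    """Test every probe of a preprocessed (normalized, floored) matrix.

    Returns a DETable: a DataFrame indexed by probe ID with columns
    ``p_value``, ``fold_change`` (signed geometric-mean ratio), ``geomean_a``,
    ``geomean_b`` and ``significant`` (strict ``p < alpha``).
    """
    arrays_a = design.arrays_for(*contrast.group_a)
    arrays_b = design.arrays_for(*contrast.group_b)
    for grp, arrs in ((contrast.group_a, arrays_a), (contrast.group_b, arrays_b)):
        if len(arrs) < 2:
            raise ValidationError(
                f"contrast {contrast.name}: group {grp} has {len(arrs)} "
                "array(s); at least 2 required"
            )
    values = matrix.frame
    if (values.to_numpy() <= 0).any():
        raise ValidationError("run_contrast expects floored positive intensities")
    log_a = np.log2(values[arrays_a].to_numpy(dtype=float))
    log_b = np.log2(values[arrays_b].to_numpy(dtype=float))
    p = _f_test_rows([log_a, log_b])
    log2fc = log_a.mean(axis=1) - log_b.mean(axis=1)
    table = pd.DataFrame(
        {
            "p_value": p,
            "fold_change": _signed_from_log2(log2fc),
            "geomean_a": np.exp2(log_a.mean(axis=1)),
            "geomean_b": np.exp2(log_b.mean(axis=1)),
        },
        index=pd.Index(matrix.probe_ids, name="probe_id"),
    )
    table["significant"] = table["p_value"] < contrast.alpha
    return table


def collapse_to_genes(de: pd.DataFrame, annotation: ProbeAnnotation) -> pd.DataFrame:
    """Collapse a probe-level DETable to unique known genes.

    Probes without a gene symbol are dropped.  Among probes sharing a symbol
    the representative is the one with the smallest p-value; ties are broken
    by larger |fold change|, then lexicographically smaller probe ID.  The
    result is indexed by gene symbol and keeps the representative probe in a
    ``probe_id`` column.
    """
    if annotation.n_known == 0:
        raise ValidationError(
            "annotation assigns no gene symbols; gene-level analysis "
            "cannot run without known genes"
        )
    symbols = annotation.symbol_of()
    work = de.copy()
    work["gene_symbol"] = symbols.reindex(work.index).to_numpy()
    work = work.dropna(subset=["gene_symbol"])
    if work.empty:
        return work.set_index("gene_symbol")
    work = work.reset_index()
    order = np.lexsort(
        (
            work["probe_id"].to_numpy(),
            -np.abs(work["fold_change"].to_numpy()),
            work["p_value"].to_numpy(),
        )
    )
    work = work.iloc[order]
    collapsed = work.drop_duplicates(subset="gene_symbol", keep="first")
    return collapsed.set_index("gene_symbol").sort_index()


def benjamini_hochberg(de: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Optional extension: recompute ``significant`` with BH-adjusted p-values.

    Off by default everywhere; the standard analysis uses raw p-values.
    Adds a ``p_adjusted`` column.
    """
    from statsmodels.stats.multitest import multipletests

    if de.empty:
        out = de.copy()
        out["p_adjusted"] = np.array([], dtype=float)
        return out
    reject, p_adj, _, _ = multipletests(
        de["p_value"].to_numpy(), alpha=alpha, method="fdr_bh"
    )
    out = de.copy()
    out["p_adjusted"] = p_adj
    out["significant"] = reject
    return out


def run_all_contrasts(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    contrasts=None,
) -> dict[str, pd.DataFrame]:
    """Run every contrast (default: NAN7, NAN35, TIME) on one matrix."""
    contrasts = list(STANDARD_CONTRASTS.values()) if contrasts is None else contrasts
    out = {}
    for contrast in contrasts:
        out[contrast.name] = run_contrast(matrix, design, contrast)
    if not out:
        raise ComputationError("no contrasts supplied")
    return out
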