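"""Relative quantification of qPCR (2^-ΔΔCt) and densitometry normalization.

qPCR reactions are run in triplicate; the arithmetic mean of the triplicate
quantification cycles (Ct) is used.  For each sample,
``ΔCt = mean Ct(target) - mean Ct(reference gene)`` (reference gene 18S by
default), and expression is reported as fold change relative to a designated
reference *group* (the 7-day vehicle animals):
``fold = 2^-(ΔCt - mean ΔCt of reference group)``.  Anchoring to the group
mean rather than a single calibrator sample matches how such data are
normally presented (reference-group mean fold = 1).

Western-blot band intensities are normalized by dividing the target band by
a neighboring non-specific band from the same lane; group comparison of the
resulting ratios is delegated to the ANOVA/Newman-Keuls machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .groupstats import newman_keuls, one_way_anova

DEFAULT_REFERENCE_GENE = "18S"
DEFAULT_REFERENCE_GROUP = "vehicle_7d"


@dataclass(frozen=True)
class CtTable:
    """Triplicate Ct measurements in long form.

    ``data`` has one row per well: columns ``sample``, ``gene``, ``ct``.
    ``groups`` maps each sample to its group label.  The reference gene and
    reference group define the two normalizations of the ΔΔCt method.
    """

    data: pd.DataFrame
    groups: dict[str, str]
    reference_gene: str = DEFAULT_REFERENCE_GENE
    reference_group: str = DEFAULT_REFERENCE_GROUP

    def __post_init__(self) -> None:
        missing = [c for c in ("sample", "gene", "ct") if c not in self.data.columns]
        if missing:
            raise ValidationError(f"Ct table missing columns {missing}")
        if not np.all(np.isfinite(self.data["ct"].to_numpy(dtype=float))):
            raise ValidationError("Ct values must be finite")
        unknown = set(self.data["sample"]) - set(self.groups)
        if unknown:
            raise ValidationError(f"samples without group label: {sorted(unknown)[:5]}")
        if self.reference_group not in set(self.groups.values()):
            raise ValidationError(
                f"reference group {self.reference_group!r} has no samples"
            )

    def target_genes(self) -> list[str]:
        return sorted(set(self.data["gene"]) - {self.reference_gene})


@dataclass(frozen=True)
class RelativeQuantResult:
    """Per-sample ΔCt and fold changes for one target gene."""

    gene: str
    per_sample: pd.DataFrame  # index: sample; columns: group, delta_ct, fold
    reference_group: str
    group_summary: pd.DataFrame = field(default=None)  # mean, sem, n per group


def delta_delta_ct(ct: CtTable, gene: str | None = None):
    """Apply the 2^-ΔΔCt method.

    With ``gene`` given, returns one :class:`RelativeQuantResult`; otherwise
    a dict mapping every target gene to its result.  Triplicates are averaged
    arithmetically on the Ct scale before any differencing.
    """
    if gene is None:
        return {g: delta_delta_ct(ct, g) for g in ct.target_genes()}
    data = ct.data
    mean_ct = (
        data[data["gene"].isin([gene, ct.reference_gene])]
        .groupby(["sample", "gene"])["ct"]
        .mean()
        .unstack("gene")
    )
    for needed in (gene, ct.reference_gene):
        if needed not in mean_ct.columns:
            raise ValidationError(f"no Ct measurements for gene {needed!r}")
    no_ref = mean_ct.index[mean_ct[ct.reference_gene].isna()]
    if len(no_ref):
        raise ValidationError(
            f"sample {no_ref[0]!r} lacks reference-gene ({ct.reference_gene}) wells"
        )
    mean_ct = mean_ct.dropna(subset=[gene])
    delta_ct = mean_ct[gene] - mean_ct[ct.reference_gene]
    group = pd.Series({s: ct.groups[s] for s in delta_ct.index})
    ref_samples = group[group == ct.reference_group].index
    if len(ref_samples) == 0:
        raise ValidationError(
            f"gene {gene!r}: no samples in reference group {ct.reference_group!r}"
        )
    calibrator = float(delta_ct.loc[ref_samples].mean())
    fold = np.exp2(-(delta_ct - calibrator))
    per_sample = pd.DataFrame(
        {"group": group, "delta_ct": delta_ct, "fold": fold}
    ).rename_axis("sample")
    summary = _summarize_folds(per_sample)
    return RelativeQuantResult(
        gene=gene,
        per_sample=per_sample,
        reference_group=ct.reference_group,
        group_summary=summary,
    )


def _summarize_folds(per_sample: pd.DataFrame) -> pd.DataFrame:
    def sem(v):
        if len(v) < 2:
            warnings.warn("single-sample group: SEM undefined", UserWarning,
                          stacklevel=4)
            return np.nan
        return v.std(ddof=1) / np.sqrt(len(v))

    g = per_sample.groupby("group")["fold"]
    return pd.DataFrame({"mean": g.mean(), "sem": g.apply(sem), "n": g.size()})


def normalize_bands(records: pd.DataFrame) -> pd.DataFrame:
    """Normalize band intensities to the neighboring non-specific band.

    ``records`` needs columns ``target`` and ``reference`` (positive
    intensities); the returned copy adds ``ratio = target / reference``.
    """
    for col in ("target", "reference"):
        if col not in records.columns:
            raise ValidationError(f"band records missing column {col!r}")
        vals = records[col].to_numpy(dtype=float)
        if (vals <= 0).any() or not np.all(np.isfinite(vals)):
            raise ValidationError(f"non-positive {col} band intensity")
    out = records.copy()
    out["ratio"] = out["target"].to_numpy(dtype=float) / \
        out["reference"].to_numpy(dtype=float)
    return out


def group_fold_report(values: pd.Series, groups: pd.Series,
                      alpha: float = 0.05) -> dict:
    """Per-group mean ± SEM with ANOVA p-value and Newman-Keuls pair flags.

    ``values`` are per-sample folds or ratios; ``groups`` the matching group
    labels.  Returns a dict with ``summary`` (DataFrame), ``anova``
    (:class:`~myoarray.groupstats.AnovaResult`) and ``posthoc``
    (:class:`~myoarray.groupstats.PosthocResult`, pairs indexed in the order
    of ``summary``'s rows).
    """
    frame = pd.DataFrame({"fold": values, "group": groups})
    summary = _summarize_folds(frame.rename(columns={"fold": "fold"}))
    labels = list(summary.index)
    samples = [frame.loc[frame["group"] == g, "fold"].to_numpy() for g in labels]
    if len(samples) < 2:
        raise ValidationError("group comparison needs at least two groups")
    anova = one_way_anova(samples)
    posthoc = newman_keuls(samples, alpha=alpha)
    return {"summary": summary, "group_order": labels,
            "anova": anova, "posthoc": posthoc}
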