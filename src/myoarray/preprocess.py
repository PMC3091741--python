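"""Median normalization, intensity flooring, and the variability filter.

Arrays are brought onto a common scale by matching their medians, low
intensities are clamped to a floor so that ratios stay finite and noise near
background does not masquerade as fold change, and probes whose profile is
essentially flat across arrays are excluded before any test is run.  The
filter keeps a probe only when at least ``min_fraction`` of the arrays differ
from the probe's median by ``fold_threshold`` or more on the ratio scale
(``max(v/m, m/v) >= fold_threshold``, boundary inclusive).

Statistics downstream run on log2 of the floored, normalized values; the
:func:`log2_matrix` helper performs that transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .expression_io import ExpressionMatrix

DEFAULT_FLOOR = 10.0
DEFAULT_MIN_FRACTION = 0.20
DEFAULT_FOLD_THRESHOLD = 1.5


@dataclass(frozen=True)
class PreprocessParams:
    """Settings of the normalization/flooring/filter stage.

    floor_value
        Intensity below which expression values are clamped (arbitrary
        scanner units; default 10).
    min_fraction
        Minimum proportion of arrays that must deviate from the probe median
        for the probe to be kept (default 0.20).
    fold_threshold
        Ratio-scale deviation that counts as "different" (default 1.5).
    """

    floor_value: float = DEFAULT_FLOOR
    min_fraction: float = DEFAULT_MIN_FRACTION
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD

    def __post_init__(self) -> None:
        if not self.floor_value > 0:
            raise ValidationError("floor_value must be > 0")
        if not 0 < self.min_fraction <= 1:
            raise ValidationError("min_fraction must be in (0, 1]")
        if not self.fold_threshold > 1:
            raise ValidationError("fold_threshold must be > 1")


def median_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every array so its median equals the median of array medians.

    Each array is multiplied by ``reference_median / its_median`` where the
    reference is the median of the per-array medians of the input, making the
    operation idempotent and invariant to rescaling any single array.
    """
    values = matrix.values
    medians = np.median(values, axis=0)
    bad = np.where(medians <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"array {matrix.array_ids[bad[0]]!r} has non-positive median "
            f"{medians[bad[0]]:g}; cannot median-normalize"
        )
    reference = np.median(medians)
    return matrix.with_values(values * (reference / medians))


def apply_floor(matrix: ExpressionMatrix,
                floor_value: float = DEFAULT_FLOOR) -> ExpressionMatrix:
    """Clamp every value below ``floor_value`` up to ``floor_value``."""
    if not floor_value > 0:
        raise ValidationError("floor_value must be > 0")
    return matrix.with_values(np.maximum(matrix.values, floor_value))


def variability_filter(
    matrix: ExpressionMatrix,
    params: PreprocessParams = PreprocessParams(),
) -> tuple[list[str], list[str]]:
    """Split probes into (kept, excluded) by across-array variability.

    A probe is kept iff the number of arrays whose value deviates from the
    probe median by at least ``fold_threshold`` on the ratio scale reaches
    ``ceil(min_fraction * n_arrays)``.  "Or more different" is inclusive: a
    ratio of exactly the threshold counts.
    """
    values = matrix.values
    n_arrays = values.shape[1]
    medians = np.median(values, axis=1, keepdims=True)
    if (medians <= 0).any() or (values <= 0).any():
        raise ValidationError("variability filter requires positive, "
                              "floored intensities")
    with np.errstate(divide="ignore"):
        ratio = np.maximum(values / medians, medians / values)
    deviating = (ratio >= params.fold_threshold).sum(axis=1)
    # round before ceil so 0.2 * 10 (= 2.0000000000000004 in floats) needs 2
    # arrays, not 3
    needed = math.ceil(round(params.min_fraction * n_arrays, 9))
    keep = deviating >= needed
    probes = np.asarray(matrix.probe_ids, dtype=object)
    return list(probes[keep]), list(probes[~keep])


def log2_matrix(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform a floored matrix (all values must be positive)."""
    values = matrix.values
    if (values <= 0).any():
        raise ValidationError("log2 transform requires positive values; "
                              "apply the floor first")
    return matrix.with_values(np.log2(values))


def preprocess(
    matrix: ExpressionMatrix,
    params: PreprocessParams = PreprocessParams(),
) -> tuple[ExpressionMatrix, list[str], list[str]]:
    """Run normalize -> floor -> filter; return (filtered matrix, kept, excluded).

    The returned matrix is normalized and floored and contains only kept
    probes, ready for log2 transformation and testing.
    """
    normalized = median_normalize(matrix)
    floored = apply_floor(normalized, params.floor_value)
    kept, excluded = variability_filter(floored, params)
    return floored.subset_probes(kept), kept, excluded
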