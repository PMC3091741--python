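"""Per-array log2 ratio matrices for heat-map rendering.

For a chosen timepoint, every selected row (gene or probe) is expressed as
``log2(value / arithmetic mean of the vehicle arrays at that timepoint)``.
The arithmetic mean is deliberate: heat maps of this kind display intensity
relative to the plain vehicle average, whereas the test statistics use
geometric means — the two conventions are kept distinct.

Rendering is out of scope; the numeric matrix is the artifact, with an
optional basic PNG convenience.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .expression_io import VEHICLE, ExpressionMatrix, SampleDesign


def heatmap_matrix(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    row_ids: list[str],
    timepoint: int,
    group_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """log2 ratios vs the vehicle-group arithmetic mean at one timepoint.

    ``row_ids`` select rows of ``matrix`` (probes, or genes if the matrix is
    gene-keyed); missing IDs raise an error listing them.  Columns are all
    arrays at ``timepoint`` (vehicle and drug).  ``group_labels`` may attach
    a free-text biological-function label per row (carried in a
    ``function`` column).
    """
    missing = [r for r in row_ids if r not in matrix.frame.index]
    if missing:
        raise ValidationError(f"rows absent from matrix: {missing}")
    vehicle_arrays = design.arrays_for(timepoint, VEHICLE)
    if not vehicle_arrays:
        raise ValidationError(f"no vehicle arrays at timepoint {timepoint}")
    tp_of = dict(zip(design.table["array_id"], design.table["timepoint"]))
    tp_arrays = [a for a in design.array_ids
                 if tp_of[a] == timepoint and a in matrix.array_ids]
    sub = matrix.frame.loc[row_ids, tp_arrays]
    ref = sub[vehicle_arrays].mean(axis=1)
    if (ref <= 0).any():
        raise ValidationError("vehicle mean must be positive (apply the floor)")
    out = np.log2(sub.div(ref, axis=0))
    if not np.all(np.isfinite(out.to_numpy())):
        raise ValidationError("heatmap matrix contains non-finite entries; "
                              "input must be floored positive intensities")
    if group_labels:
        out.insert(0, "function", [group_labels.get(r, "") for r in row_ids])
    return out


def save_heatmap_png(hm: pd.DataFrame, path) -> None:
    """Convenience PNG of a heat-map matrix (matplotlib, red/green diverging)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = hm.drop(columns=["function"], errors="ignore")
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * data.shape[1]), max(3, 0.25 * data.shape[0]))
    )
    vmax = float(np.nanmax(np.abs(data.to_numpy()))) or 1.0
    im = ax.imshow(data.to_numpy(), cmap="RdYlGn_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(data.shape[1]), labels=data.columns, rotation=90,
                  fontsize=6)
    ax.set_yticks(range(data.shape[0]), labels=data.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="log2 ratio vs vehicle mean")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
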