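import numpy as np
import pandas as pd
import pytest

from myoarray import ExpressionMatrix, SampleDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_matrix():
    """3 probes x 4 arrays with distinct, hand-checkable values."""
    frame = pd.DataFrame(
        [[100.0, 200.0, 150.0, 120.0],
         [10.0, 40.0, 20.0, 30.0],
         [5.0, 5.0, 5.0, 5.0]],
        index=["p1", "p2", "p3"],
        columns=["a1", "a2", "a3", "a4"],
    )
    return ExpressionMatrix(frame)


@pytest.fixture
def design_2x2():
    """Standard 2x2 design, 3 arrays per group, 12 arrays."""
    rows = []
    for tp in (7, 35):
        for tr in ("vehicle", "nandrolone"):
            short = "nan" if tr == "nandrolone" else "veh"
            for rep in (1, 2, 3):
                rows.append((f"{short}{tp}_r{rep}", tp, tr, rep))
    return SampleDesign(pd.DataFrame(
        rows, columns=["array_id", "timepoint", "treatment", "replicate"]))


def make_matrix(values, probes=None, arrays=None) -> ExpressionMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    arrays = arrays or [f"a{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=arrays))
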