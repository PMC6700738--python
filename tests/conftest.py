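import numpy as np
import pandas as pd
import pytest

from refstab.ct_io import CtMatrix
from refstab.datasets import published_stability_ranks
from refstab.preprocess import q_transform


@pytest.fixture
def published_ranks() -> pd.DataFrame:
    """The 22-gene published consensus worked example."""
    return published_stability_ranks()


@pytest.fixture
def hand_ct() -> CtMatrix:
    """Hand-checkable 3-gene x 3-sample Ct matrix.

    'flat' is constant; 'ramp' rises one cycle per sample so its Q
    vector is (1, 0.5, 0.25) and its log2 ratios against 'flat' are
    (0, -1, -2) with sample SD exactly 1.
    """
    return CtMatrix(
        pd.DataFrame(
            {
                "s1": [20.0, 20.0, 15.0],
                "s2": [20.0, 21.0, 15.5],
                "s3": [20.0, 22.0, 16.0],
            },
            index=["flat", "ramp", "half-ramp"],
        )
    )


@pytest.fixture
def hand_q(hand_ct):
    return q_transform(hand_ct)


def make_ct(values: np.ndarray, genes=None, samples=None, groups=None) -> CtMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CtMatrix(pd.DataFrame(values, index=genes, columns=samples), groups)
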