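import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ctprofiler import CtMatrix, GroupDesign, WellRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_matrix(values, mirnas=None, samples=None, groups=None) -> CtMatrix:
    """Compact CtMatrix builder for tests."""
    arr = np.asarray(values, dtype=float)
    n, m = arr.shape
    mirnas = mirnas or [f"miR-{i + 1}" for i in range(n)]
    samples = samples or [f"s{j + 1}" for j in range(m)]
    groups = groups or ["g1"] * m
    return CtMatrix(
        pd.DataFrame(arr, index=mirnas, columns=samples),
        pd.Series(dict(zip(samples, groups))),
    )


def make_well(sample="s1", group="g1", mirna="miR-1", ct=20.0,
              amp_score=1.5, cq_conf=0.95) -> WellRecord:
    return WellRecord(sample, group, mirna, ct, amp_score, cq_conf)


@pytest.fixture
def two_group_design() -> GroupDesign:
    return GroupDesign({"A": ["A1", "A2", "A3"], "B": ["B1", "B2", "B3"]})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
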