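import logging

import numpy as np
import pytest
from skbio import TreeNode

from asvkit.core_io import AsvTable


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    logging.getLogger("asvkit").setLevel(logging.ERROR)
    yield


@pytest.fixture
def three_tip_tree() -> TreeNode:
    return TreeNode.read(["((A:1,B:1):1,C:2);"])


@pytest.fixture
def small_table() -> AsvTable:
    counts = np.array(
        [
            [5, 1, 0, 4],
            [0, 2, 3, 5],
            [1, 1, 1, 7],
        ]
    )
    return AsvTable(["s1", "s2", "s3"], ["A", "B", "C", "D"], counts)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_table(rng: np.random.Generator, n_samples: int, n_asvs: int,
                 depth: int = 200) -> AsvTable:
    p = rng.dirichlet(np.ones(n_asvs))
    counts = np.vstack([rng.multinomial(depth, p) for _ in range(n_samples)])
    return AsvTable(
        [f"s{i}" for i in range(n_samples)],
        [f"t{j}" for j in range(n_asvs)],
        counts,
    )
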