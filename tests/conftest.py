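import sys
from pathlib import Path

import numpy as np
import pytest

from consensus_grn import ExpressionMatrix, standardize

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def fixture_expression_csv() -> Path:
    """Committed synthetic 8-gene x 10-condition matrix with 3 planted edges."""
    return DATA_DIR / "synthetic_expr_8x10.csv"


@pytest.fixture
def fixture_truth_csv() -> Path:
    return DATA_DIR / "synthetic_truth_8x10.csv"


def random_matrix(p: int, n: int, seed: int = 0) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        gene_ids=[f"g{i + 1}" for i in range(p)],
        condition_ids=[f"c{j + 1}" for j in range(n)],
        values=rng.standard_normal((p, n)),
    )


@pytest.fixture
def std_matrix_10x12() -> ExpressionMatrix:
    return standardize(random_matrix(10, 12, seed=0))


@pytest.fixture
def std_matrix_6x8() -> ExpressionMatrix:
    return standardize(random_matrix(6, 8, seed=3))
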