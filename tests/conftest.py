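import numpy as np
import pytest

from ecvnet.core_io import ExpressionMatrix


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        gene_ids=["TP53", "MYC", "EGFR"],
        sample_ids=["S1", "S2"],
        values=np.array([[1.0, 2.0], [3.0, 4.5], [-0.5, 0.25]]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
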