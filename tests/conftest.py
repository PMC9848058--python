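import numpy as np
import pytest

from sciber import ExpressionMatrix, default_preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """Tiny 12-gene x 20-cell batch with two obvious cell populations."""
    values = rng.gamma(2.0, 0.5, size=(12, 20))
    values[:4, :10] += 3.0  # population A up-regulates genes 0..3
    values[4:8, 10:] += 3.0  # population B up-regulates genes 4..7
    return ExpressionMatrix(
        values,
        gene_ids=[f"g{i}" for i in range(12)],
        cell_ids=[f"c{j}" for j in range(20)],
        batch_id="b0",
    )


@pytest.fixture(scope="session")
def preset_run():
    """One default-preset simulation shared across tests (seed 0)."""
    batches, truth = default_preset(seed=0)
    return batches, truth


def assert_reference_untouched(reference, snapshot_bytes):
    """Reference batch must come out of any run bit-identical."""
    assert reference.values.tobytes() == snapshot_bytes
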