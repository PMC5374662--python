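import numpy as np
import pytest

from batchbench import (
    ExpressionMatrix,
    SampleMetadata,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        np.array([[1.0, 2.0], [3.0, 4.0]]), ["P1", "P2"], ["S1", "S2"]
    )


@pytest.fixture
def eight_sample_meta() -> SampleMetadata:
    """4 + 4 class design, split evenly over two batches."""
    samples = [f"S{j}" for j in range(1, 9)]
    cls = {s: ("D" if j < 4 else "D*") for j, s in enumerate(samples)}
    batch = {s: ("1" if j % 4 < 2 else "2") for j, s in enumerate(samples)}
    return SampleMetadata(cls, batch)


@pytest.fixture
def small_dataset():
    """A 400-protein default-condition simulated clean/noisy pair."""
    return simulate_dataset(SimulationConfig(n_proteins=400, seed=11))


@pytest.fixture
def default_dataset():
    """A full-size default-condition replicate (1100 proteins, 4+4 samples)."""
    return simulate_dataset(SimulationConfig(seed=5))
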