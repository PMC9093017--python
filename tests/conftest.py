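import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from orfunc import GeneratorConfig, OrthologAlignment, ResponseMatrix
from orfunc.simulate import generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_alignment():
    """Four receptors differing only at column 2 (A vs V)."""
    return OrthologAlignment(
        (("R1", "MAKG"), ("R2", "MAKG"), ("R3", "MVKG"), ("R4", "MVKG")),
        reference_id="R1",
    )


@pytest.fixture
def toy_responses():
    """Responses determined entirely by the residue at column 2."""
    return ResponseMatrix(
        pd.DataFrame(
            [[100.0, 0.0], [100.0, 0.0], [0.0, 100.0], [0.0, 100.0]],
            index=["R1", "R2", "R3", "R4"],
            columns=["o1", "o2"],
        )
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """Default planted-signal synthetic dataset (14 receptors, 5 planted)."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def null_dataset():
    """Responses carry no sequence signal (no planted effects)."""
    return generate_dataset(GeneratorConfig(seed=1, planted_positions=(), effect_scale=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
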