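import numpy as np
import pytest

from fuzzywave import FWNNParameters, GeneratorConfig, generate_dataset, load_reference_parameters


@pytest.fixture(scope="session")
def reference_params() -> FWNNParameters:
    """The packaged eight-rule, five-input parameter set."""
    return load_reference_parameters()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A 50-sample noisy kinetic-teacher dataset, fixed seed."""
    df, _ = generate_dataset(GeneratorConfig(n_samples=50, seed=7))
    return df


def tiny_params(n_rules=2, n_inputs=2, seed=0) -> FWNNParameters:
    rng = np.random.default_rng(seed)
    shape = (n_rules, n_inputs)
    return FWNNParameters(
        centers=rng.uniform(-1, 1, shape),
        spreads=rng.uniform(0.5, 2.0, shape),
        dilations=rng.uniform(0.5, 2.0, shape),
        translations=rng.uniform(-1, 1, shape),
        weights=rng.uniform(-2, 2, n_rules),
    )
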