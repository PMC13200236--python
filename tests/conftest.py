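import pytest

from gnasr import (
    SpinSystemConstants,
    TumblingExchangeModel,
    generate_ground_truth_profile,
    lean_modelfree_profile,
    simulate_rate_tables,
)
from gnasr.synthetic import representative_slow_architecture


@pytest.fixture(scope="session")
def constants():
    return SpinSystemConstants()


@pytest.fixture(scope="session")
def gel_model():
    return TumblingExchangeModel()


@pytest.fixture(scope="session")
def clean_profile():
    """Noise-free ground truth with representative slow loops."""
    return generate_ground_truth_profile(
        seed=3, noise_level=0.0, architecture=representative_slow_architecture()
    )


@pytest.fixture(scope="session")
def clean_bundle(clean_profile):
    free, gel, truth = simulate_rate_tables(clean_profile)
    return free, gel, truth


@pytest.fixture(scope="session")
def clean_mf(clean_bundle, constants):
    free, _, _ = clean_bundle
    return lean_modelfree_profile(free, constants)
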