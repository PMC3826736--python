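import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "adps",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("adps")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_logistic_data():
    """20 subjects x 3 variables, non-separable, both classes present."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(20, 3))
    eta = X @ np.array([1.0, -0.5, 0.0])
    y = (rng.random(20) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    assert 0 < y.mean() < 1
    return X, y


@pytest.fixture(scope="session")
def tiny_cohort():
    """Desk-scale planted cohort small enough for per-test pipelines."""
    from adps.synthetic import EffectBlock, SyntheticCohortSpec, generate_cohort

    spec = SyntheticCohortSpec(
        group_sizes=(12, 12, 12, 12),
        grid_shape=(8, 8, 8),
        effect_regions={
            "GM": (EffectBlock((1, 1, 1), (3, 3, 3), 0.25),),
            "WM": (EffectBlock((4, 4, 4), (3, 3, 3), 0.18),),
            "CSF": (EffectBlock((1, 4, 4), (3, 3, 3), 0.15),),
        },
        seed=5,
    )
    return generate_cohort(spec)
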