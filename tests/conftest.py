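import numpy as np
import pytest

import punishstrat as ps

# The published tick/cross pattern for the nine strategies, frozen as a
# golden fixture in the canonical decision order
# (A,steal), (A,nosteal), ..., (F,nosteal).
TABLE_PATTERN = {
    "deterrent":      [1, 0, 1, 0, 0, 0, 1, 0, 1, 0, 0, 0],
    "norm_enforcing": [1, 0, 1, 0, 0, 0, 1, 0, 1, 0, 1, 0],
    "revenge":        [1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 0, 0],
    "avoid_DI":       [0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0],
    "egalitarian":    [0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 1, 0],
    "seek_AI":        [0, 0, 1, 0, 1, 0, 0, 0, 0, 0, 0, 0],
    "competitive":    [1, 1, 1, 1, 1, 1, 0, 0, 1, 1, 1, 1],
    "antisocial":     [0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1],
    "never_punish":   [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
}


@pytest.fixture(scope="session")
def games():
    return ps.standard_games()


@pytest.fixture(scope="session")
def matrix():
    return ps.base_matrix()


@pytest.fixture(scope="session")
def extended():
    return ps.extended_matrix()


@pytest.fixture(scope="session")
def table(matrix):
    return ps.conditional_probs(matrix, 0.05)


@pytest.fixture(scope="session")
def small_cohort():
    """A reproducible two-country cohort, n=150/country, delta=0.05."""
    spec = ps.GeneratorSpec(
        sample_sizes={"UK": 150, "US": 150},
        frequencies={
            "UK": dict(ps.simulate.DEFAULT_VALIDATION_MIX),
            "US": dict(ps.simulate.DEFAULT_VALIDATION_MIX),
        },
        delta=0.05,
        seed=42,
    )
    data, truth = ps.sample_dataset(spec)
    return spec, data, truth


@pytest.fixture(scope="session")
def quick_config():
    """Short sampler settings for plumbing tests (not calibration claims)."""
    return ps.ModelConfig(samples=800, warmup=400, seed=11,
                          ess_min=100.0, rhat_max=1.05)


def pure_vector(matrix, label):
    return np.asarray(matrix.row(label), dtype=float)
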