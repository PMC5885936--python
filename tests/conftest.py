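import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from covnet.synthetic import PlantedStar, SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_group_star_cohort():
    """n=80/group, p=30, strong star (lambda=3) in group A only."""
    cfg = SyntheticConfig(
        n_per_group=(80, 80),
        p_regions=30,
        covariate_names=("age", "sex"),
        binary_rates={"sex": 0.5},
        planted=(PlantedStar(0, tuple(range(1, 7)), 3.0), None),
        baseline_mu=20.0,
        noise_sd=1.0,
        group_labels=("A", "B"),
        seed=7,
    )
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


def random_correlation_matrix(rng, p=15, n=20):
    """Sample correlation matrix of white-noise data: a generic stand-in for
    an estimated partial-correlation matrix."""
    x = rng.normal(size=(n, p))
    return np.corrcoef(x, rowvar=False)
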