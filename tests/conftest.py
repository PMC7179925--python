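import numpy as np
import pytest

import thyrostage as ts


@pytest.fixture(scope="session")
def worked_example():
    """Tiny fixed cohort: 4 transcripts x 6 samples with known optima."""
    return ts.generate_worked_example()


@pytest.fixture(scope="session")
def small_tumor_dataset():
    """Seed-fixed synthetic tumor cohort (no normals), desk scale."""
    cfg = ts.SimulationConfig(
        n_transcripts=300,
        n_informative=10,
        class_sizes={"normal": 0, "early": 80, "late": 40},
        effect_size_sd=2.0,
        seed=11,
    )
    return ts.generate_dataset(cfg)


@pytest.fixture(scope="session")
def three_class_dataset():
    """Seed-fixed cohort with normals for multiclass tests."""
    cfg = ts.SimulationConfig(
        n_transcripts=200,
        n_informative=12,
        class_sizes={"normal": 30, "early": 80, "late": 40},
        effect_size_sd=3.0,
        normal_effect_sd=3.0,
        seed=21,
    )
    return ts.generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
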