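import numpy as np
import pytest

import indelmark as im


@pytest.fixture(scope="session")
def small_config() -> im.SimulationConfig:
    """A quick dataset: one 120 kb chromosome, 10 diagnostic + 30
    polymorphic InDels, 7+7 samples, no missingness."""
    return im.SimulationConfig(
        seed=11,
        n_chromosomes=1,
        chrom_length=120_000,
        n_diagnostic=10,
        n_shared_polymorphic=15,
        n_private_polymorphic=15,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_dataset")
    reference, matrix, truth, paths = im.simulate_dataset(small_config, out)
    return {
        "config": small_config,
        "reference": reference,
        "matrix": matrix,
        "truth": truth,
        "paths": paths,
    }


@pytest.fixture(scope="session")
def study_scale_dataset(tmp_path_factory):
    """Study-scale conditions: 7+7 diploid samples, 50 planted diagnostic
    and 200 polymorphic InDels, no missingness."""
    cfg = im.SimulationConfig(
        seed=101,
        n_chromosomes=2,
        chrom_length=500_000,
        n_diagnostic=50,
        n_shared_polymorphic=100,
        n_private_polymorphic=100,
    )
    out = tmp_path_factory.mktemp("study_scale")
    reference, matrix, truth, paths = im.simulate_dataset(cfg, out)
    return {
        "config": cfg,
        "reference": reference,
        "matrix": matrix,
        "truth": truth,
        "paths": paths,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
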