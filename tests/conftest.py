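import pytest

from ltelegacy import recovery, synthetic


@pytest.fixture(scope="session")
def study_dataset():
    """The nine-site, 66-record study-like dataset for seed 1."""
    return synthetic.make_study_like_dataset(1)


@pytest.fixture(scope="session")
def study_records(study_dataset):
    return recovery.build_recovery_table(study_dataset)


@pytest.fixture(scope="session")
def noise_free_cfg():
    """Generator config with every stochastic term switched off."""
    return synthetic.SyntheticConfig(
        n_sites=3, sigma_site=0.0, sigma_year=0.0, sigma_obs=0.0
    )
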