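import warnings

import pytest

from vacflux import ModelParams, RunConfig, SyntheticTruth, simulate_experiment


@pytest.fixture()
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def wt_params():
    return ModelParams(k_pd=0.03, mu=0.4, k_ve=2.0, s1=0.01, s2=0.6, s3=0.39)


@pytest.fixture(scope="session")
def noise_free_sim(wt_params):
    """One-replicate noise-free WT experiment, single analyte."""
    truth = SyntheticTruth(
        genotypes={"WT": wt_params},
        response_ratio_per_analyte={"lysine": 1.25},
        noise_cv=0.0,
        n_replicates=1,
        seed=11,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_experiment(truth)


@pytest.fixture(scope="session")
def noisy_sim():
    """Default two-genotype experiment at the standard 5% noise level."""
    truth = SyntheticTruth(seed=42)
    return simulate_experiment(truth)
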