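import numpy as np
import pandas as pd
import pytest

import valgp as vg


@pytest.fixture(scope="session")
def default_b():
    return vg.default_roughness_params()


@pytest.fixture(scope="session")
def irish_table():
    return vg.load_published_table("irish")


@pytest.fixture(scope="session")
def polish_table():
    return vg.load_published_table("polish")


@pytest.fixture(scope="session")
def small_study():
    """A quick 24-respondent synthetic study on the published design."""
    return vg.simulate_study("irish", respondents=24, seed=101)


@pytest.fixture(scope="session")
def toy_dataset():
    """Tiny covariate-free dataset: 3 respondents x 2 states (plus the
    full-health anchor appended automatically)."""
    truth_u = {"22222": 0.6, "44444": 0.1}
    rng = np.random.default_rng(5)
    alpha = np.exp(np.sqrt(0.04) * rng.standard_normal(3))
    rows = []
    for j in range(3):
        for code, u in truth_u.items():
            y = 1.0 - alpha[j] * (1.0 - u) + np.sqrt(0.01) * rng.standard_normal()
            rows.append((f"p{j}", code, y))
    obs = pd.DataFrame(rows, columns=["respondent_id", "state", "y"])
    cov = pd.DataFrame(index=pd.Index([f"p{j}" for j in range(3)], name="respondent_id"))
    return vg.ValuationDataset(observations=obs, covariates=cov)


@pytest.fixture(scope="session")
def small_fit(small_study):
    """A short reference fit reused by prediction and prior tests."""
    return vg.run_mcmc(
        small_study, config=vg.MCMCConfig(n_iter=600, n_burnin=200, seed=11)
    )
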