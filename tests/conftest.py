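import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lifeclocks import (
    compute_age_gaps,
    count_extreme_organs,
    flag_extreme_agers,
    simulate_study,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

MASTER_SEED = 20260926


@pytest.fixture(scope="session")
def study():
    """Full default-condition study: cohort, matrix, clocks, latent truth."""
    cohort, matrix, clocks, latent, truth = simulate_study(seed=MASTER_SEED)
    return {"cohort": cohort, "matrix": matrix, "clocks": clocks, "latent": latent, "truth": truth}


@pytest.fixture(scope="session")
def flagged_profile(study):
    """Age-gap profile built from the latent truth, flagged and counted."""
    profile = compute_age_gaps(study["latent"], study["cohort"])
    profile = flag_extreme_agers(profile)
    count_extreme_organs(profile)
    return profile


@pytest.fixture()
def rng():
    return np.random.default_rng(MASTER_SEED)


def make_survival_cohort(n, seed, lp=None, horizon=15.1, target=0.156):
    """Minimal cohort with exponential survival driven by a linear predictor."""
    rng = np.random.default_rng(seed)
    lp = np.zeros(n) if lp is None else np.asarray(lp, float)
    lam0 = -np.log(1.0 - target) / horizon / np.mean(np.exp(lp))
    t = rng.exponential(1.0, n) / (lam0 * np.exp(lp))
    died = t <= horizon
    return pd.DataFrame(
        {
            "participant_id": [f"S{i:05d}" for i in range(n)],
            "sex": rng.choice(["male", "female"], n),
            "chron_age": 63.2 + 1.1 * rng.standard_normal(n),
            "followup_years": np.where(died, t, horizon),
            "died": died,
            "censored": ~died,
        }
    )
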