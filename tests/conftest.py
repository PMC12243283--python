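import numpy as np
import pandas as pd
import pytest

from idhgan.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A compact labelled cohort reused across module tests."""
    return generate_cohort(CohortConfig(
        n_patients=8, sessions_per_patient=6, measurements_per_session=10,
        seed=11))


def make_two_gaussian_table(n=5000, minority_frac=0.3, seed=0,
                            mu_min=(0.3, -0.3), mu_maj=(-0.3, 0.3),
                            sd=0.15):
    """Two-class, two-feature Gaussian toy in robust-tanh (-1, 1) space."""
    rng = np.random.default_rng(seed)
    n_min = int(n * minority_frac)
    X = np.clip(np.vstack([
        rng.normal(mu_min, sd, size=(n_min, 2)),
        rng.normal(mu_maj, sd, size=(n - n_min, 2)),
    ]), -0.999, 0.999)
    y = np.concatenate([np.ones(n_min), np.zeros(n - n_min)])
    df = pd.DataFrame(X, columns=["f0", "f1"])
    df["idh_next"] = y
    return df
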