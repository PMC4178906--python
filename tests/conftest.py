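import numpy as np
import pandas as pd
import pytest

from pmews import load_band_tables, reference_config, simulate_cohort


@pytest.fixture(scope="session")
def tables():
    return load_band_tables()


@pytest.fixture(scope="session")
def ref_config():
    return reference_config()


@pytest.fixture(scope="session")
def labeled_cohort(ref_config):
    """One medium simulated cohort with labels, reused across tests."""
    return simulate_cohort(ref_config, 500, seed=1234)


def random_cohort_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """A random *valid* patient cohort spanning the admissible input space."""
    consciousness = rng.choice(
        ["alert", "confused_agitated", "voice", "pain_unresponsive"], size=n
    )
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "respiratory_rate": rng.integers(0, 70, n),
            "spo2": rng.integers(50, 101, n),
            "heart_rate": rng.integers(20, 220, n),
            "systolic_bp": rng.integers(40, 260, n),
            "temperature_c": np.round(rng.uniform(28.0, 43.0, n), 1),
            "consciousness": consciousness,
            "age_years": np.round(rng.uniform(12, 100, n), 1),
            "socially_isolated": rng.integers(0, 2, n),
            "chronic_disease": rng.integers(0, 2, n),
            "performance_status": rng.integers(0, 5, n),
            "needs_ems": rng.integers(0, 2, n),
        }
    )
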