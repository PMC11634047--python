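import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fallrisk as fr

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_assessments(rows):
    """Minimal assessment frame from (resident, day, age, frs, falls) tuples."""
    base = pd.Timestamp("2022-01-01")
    return pd.DataFrame(
        {
            "resident_id": [r[0] for r in rows],
            "date": [base + pd.Timedelta(days=r[1]) for r in rows],
            "age": [r[2] for r in rows],
            "frs": [r[3] for r in rows],
            "falls_since_last": [r[4] for r in rows],
        }
    )


def make_pairs(frs_t1, rate_per_week, **covariates):
    """Observation-pair frame straight from arrays (bypasses pairing)."""
    frs_t1 = np.asarray(frs_t1, dtype=float)
    rate = np.asarray(rate_per_week, dtype=float)
    df = pd.DataFrame(
        {
            "resident_id": [f"R{i}" for i in range(len(frs_t1))],
            "frs_t1": frs_t1,
            "frs_t2": frs_t1,
            "interval_days": 100.0,
            "falls": rate * 100.0 / 7.0,
            "rate_per_week": rate,
            "rate_per_day": rate / 7.0,
        }
    )
    for k, v in covariates.items():
        df[k] = v
    return df


@pytest.fixture(scope="session")
def catalog():
    return fr.WeightConfig.default()


@pytest.fixture(scope="session")
def large_cohort_pairs():
    """~200k observation pairs under the default study conditions (seed 0).

    Session-scoped: shared by the parameter-recovery, threshold-recovery and
    rank-correlation checks.
    """
    cfg = fr.simulate.config_with(n_residents=144_000)
    cohort = fr.generate_cohort(cfg, seed=0)
    eligible, _ = fr.filter_eligible(cohort)
    return fr.build_pairs(eligible)


@pytest.fixture(scope="session")
def study_scale_cohort():
    """A cohort at the observed study scale (617 residents), seed 7."""
    return fr.generate_cohort(fr.GeneratorConfig(), seed=7)
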