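import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ropvitals import GeneratorConfig, VitalTrace, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_trace(spo2, hr=None, fio2=None, valid=None, dt=60, infant_id=0):
    """Build a trace from short value lists, repeating the sampling grid."""
    spo2 = np.asarray(spo2, dtype=float)
    n = len(spo2)
    return VitalTrace(
        infant_id=infant_id,
        t=np.arange(n, dtype=np.int64) * dt,
        spo2=spo2,
        hr=np.full(n, 150.0) if hr is None else np.asarray(hr, dtype=float),
        fio2=np.full(n, 0.21) if fio2 is None else np.asarray(fio2, dtype=float),
        valid=np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool),
        nominal_dt=float(dt),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """60-infant cohort with the default group contrasts, coarse sampling."""
    config = GeneratorConfig(n_infants=60, sampling_interval=300, seed=123,
                             missingness_rate=0.0)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with zero group effects (groups identical in law)."""
    config = GeneratorConfig(n_infants=50, sampling_interval=300, seed=321,
                             effect_windows=(), missingness_rate=0.0)
    return generate_cohort(config)
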