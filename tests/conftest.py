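import numpy as np
import pandas as pd
import pytest

import msmcurves as m
from msmcurves.pipeline import arrays_from_cohort
from msmcurves.simulate import BASELINE_COVARIATES, WAVE2_COVARIATES

# a lean confounder set that is still correctly specified for the benchmark
# DGP (it contains every covariate that actually enters the benchmark's
# exposure, censoring and hazard models)
LEAN_BASELINE = ["age", "gender", "smoking", "employment", "sleep_short"]
LEAN_WAVE2 = ["smoking_w2", "employment_w2", "sleep_short_w2", "veg_w2"]


@pytest.fixture(scope="session")
def benchmark_cohort_20k():
    """One moderately large benchmark cohort shared across tests."""
    return m.generate_cohort(m.benchmark_config(20_000, seed=101))


@pytest.fixture(scope="session")
def benchmark_arrays_20k(benchmark_cohort_20k):
    return arrays_from_cohort(benchmark_cohort_20k, BASELINE_COVARIATES,
                              WAVE2_COVARIATES, "region", "all_cause", 14)


@pytest.fixture(scope="session")
def small_cohort():
    """Small benchmark cohort for fast end-to-end tests."""
    return m.generate_cohort(m.benchmark_config(4_000, seed=11))


def tiny_cohort_frame(T, events, causes=None, **extra):
    """Hand-buildable cohort table for worked examples."""
    n = len(T)
    causes = causes if causes is not None else ["X70" if e else "" for e in events]
    df = pd.DataFrame({
        "id": np.arange(n),
        "A1": extra.pop("A1", np.zeros(n, dtype=int)),
        "A2": extra.pop("A2", np.zeros(n, dtype=int)),
        "T": np.asarray(T, dtype=int),
        "event": np.asarray(events, dtype=int),
        "cause_code": causes,
    })
    for key, val in extra.items():
        df[key] = val
    return df
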