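import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from finwhale import detection, synthetic_data
from finwhale.synthetic_data import (
    SyntheticStratum,
    SyntheticTruth,
    generate_survey,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def small_truth(density: float = 0.05, sigma_m: float = 1500.0) -> SyntheticTruth:
    """A one-stratum truth small enough for fast unit tests."""
    return SyntheticTruth(
        strata=(
            SyntheticStratum(
                name="S1",
                area_km2=50_000.0,
                density_individuals_km2=density,
                effort_km=1200.0,
                n_transects=24,
                vessel_shares=(("KPH", 0.5), ("DIS", 0.5)),
            ),
        ),
        sigma_m=sigma_m,
    )


@pytest.fixture(scope="session")
def small_survey():
    dataset, record = generate_survey(small_truth(), seed=11)
    return dataset, record


@pytest.fixture(scope="session")
def paperlike_survey():
    return synthetic_data.scenario_paperlike(7)


@pytest.fixture(scope="session")
def hn_fit():
    """Null half-normal fit on distances simulated from that model."""
    x = synthetic_data.sample_distances(
        1500, detection.HALF_NORMAL, 1500.0, 7000.0, seed=3
    )
    df = synthetic_data.distances_frame(x)
    return detection.fit_detection(df, detection.HALF_NORMAL, (), 7000.0)


def make_fixed_fit(x_m, key, sigma, w_m, b=None):
    """A DetectionFit with *fixed* (not estimated) parameters.

    Used to test goodness-of-fit behaviour against a known model without
    the parameter-estimation step.
    """
    model = detection.DetectionModel(key=key, w_m=w_m)
    params = ([np.log(b)] if key == detection.HAZARD_RATE else []) + [np.log(sigma)]
    params = np.asarray(params, dtype=float)
    x = np.asarray(x_m, dtype=float)
    design = np.ones((len(x), 1))
    mu = detection.effective_strip_width(model, np.full(len(x), sigma), b=b)
    return detection.DetectionFit(
        model=model,
        params=params,
        param_names=["log_shape", "(intercept)"][-len(params):],
        loglik=float("nan"),
        aic=float("nan"),
        n=len(x),
        esw_m=mu,
        p=mu / w_m,
        pa=float(mu[0] / w_m),
        se_pa=0.0,
        vcov=np.zeros((len(params), len(params))),
        distances_m=x,
        design=design,
    )
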