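import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ecometric.communities import CalibrationSet, calibration_from_log
from ecometric.synthetic import LandscapeConfig, generate_landscape, landscape_metrics

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_calibration(means, sds, env_log, richness=None):
    n = len(means)
    records = pd.DataFrame(
        {
            "point_id": [f"p{i}" for i in range(n)],
            "mean": np.asarray(means, float),
            "sd": np.asarray(sds, float),
            "richness": richness if richness is not None else [5] * n,
            "env_log": np.asarray(env_log, float),
        }
    )
    return CalibrationSet(records=records)


@pytest.fixture(scope="session")
def noiseless_landscape():
    return generate_landscape(LandscapeConfig(noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def noiseless_calibration(noiseless_landscape):
    ls = noiseless_landscape
    return calibration_from_log(landscape_metrics(ls), ls.env_log)


@pytest.fixture(scope="session")
def noisy_landscape():
    return generate_landscape(LandscapeConfig(noise_sd=0.3, seed=11))


@pytest.fixture(scope="session")
def noisy_calibration(noisy_landscape):
    ls = noisy_landscape
    return calibration_from_log(landscape_metrics(ls), ls.env_log)
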