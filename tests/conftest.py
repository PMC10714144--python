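import numpy as np
import pytest

from fmrcal import pipeline, synthetic


def short_sim_config(**overrides) -> synthetic.SimConfig:
    """Study-condition config scaled to hour-long blocks for fast tests.

    Amplitudes, rates and noise levels are the defaults; only the block
    structure (colony visits / trips) is shortened so a few-hour record
    still alternates land and sea.
    """
    cfg = synthetic.SimConfig(
        n_birds=overrides.pop("n_birds", 4),
        deployment_h=overrides.pop("deployment_h", 6.0),
        trip_h=overrides.pop("trip_h", 2.0),
    )
    cfg.behaviour_dwell = dict(cfg.behaviour_dwell, rest_land=3600.0)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def short_config():
    return short_sim_config()


@pytest.fixture(scope="session")
def noisy_cohort():
    """Shared small cohort with measurement noise and deliberately
    mismatched published land constants (true land rate is flat 55 kJ/h)."""
    cfg = short_sim_config(n_birds=8, deployment_h=12.0, trip_h=3.0)
    cfg.behaviour_dwell = dict(cfg.behaviour_dwell, rest_land=2 * 3600.0)
    return pipeline.run_cohort(cfg, seed=11, land_constants_kj_h=(150.0, 100.0))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Cohort with all observation noise off: budgets, EE and the DLW chain
    are exact, so recoveries should be exact up to float error."""
    cfg = short_sim_config(n_birds=8, deployment_h=12.0, trip_h=3.0)
    cfg.behaviour_dwell = dict(cfg.behaviour_dwell, rest_land=2 * 3600.0)
    cfg.isotope_noise_sd = 0.0
    return pipeline.run_cohort(cfg, seed=5, land_constants_kj_h=(150.0, 100.0))
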