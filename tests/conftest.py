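import numpy as np
import pytest

import stepnof1 as s


@pytest.fixture(scope="session")
def default_cfg():
    return s.default_config()


@pytest.fixture(scope="session")
def zero_noise_cfg(default_cfg):
    """Fully deterministic generator: no variances, no effects, flat mean."""
    return default_cfg.replace(
        fixed_intercept=5000.0, time_slope=0.0,
        weekday_effects=(0.0,) * 7,
        effect_dmi=0.0, effect_bf=0.0,
        within_se=0.0, between_se=0.0, within_mot=0.0, between_mot=0.0,
        within_barriers=0.0, between_barriers=0.0,
        within_pain=0.0, between_pain=0.0,
        var_intercept=0.0, var_slope=0.0, cov_int_slope=0.0,
        resid_var=0.0, ar1_rho=0.0, driver="none",
        p_day_missing_steps=0.0, p_participant_total_dropout=0.0,
        p_ema_missing=0.0,
    )


@pytest.fixture(scope="session")
def small_study(default_cfg):
    """A 15x40 synthetic study with missingness, shared across tests."""
    return s.simulate_study(default_cfg, seed=20_250_101)


@pytest.fixture(scope="session")
def complete_study(default_cfg):
    """Same cohort without any missingness applied."""
    return s.simulate_study(default_cfg, seed=20_250_101, missingness=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
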