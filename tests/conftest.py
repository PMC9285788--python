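import numpy as np
import pytest

import phytopart as pp
from phytopart.config import BbpFitConfig, ChlFitConfig
from phytopart.environment import OpticalContext

TRUTH_SIGMOID = {"p1": 9.0, "tau1": 4.0}
TRUTH_GAUSS = {"b2m_star": 2.0, "tau2": 5.0, "sigma": 1.0}
TRUTH_BBP = {"omega2": 0.3, "bbpk_star": 0.2}


@pytest.fixture
def tau_grid():
    return np.linspace(0.05, 9.0, 50)


@pytest.fixture
def context():
    """A plain stratified-water optical context (Kd=0.05, Z_m=80 m)."""
    return OpticalContext(
        kd=0.05, kd_source="fitted", b_s=0.3, b_s10=0.3, b_bp_s=1.75e-3,
        z_p=92.0, z_m=80.0, strat_index=1e-5,
    )


@pytest.fixture
def fast_chl_config():
    return ChlFitConfig(bootstrap_n=0)


@pytest.fixture
def fast_bbp_config():
    return BbpFitConfig(bootstrap_n=0)


@pytest.fixture
def noiseless_profile():
    """Noiseless two-community profile with known truth."""
    params = dict(mode="two_community", **TRUTH_SIGMOID, **TRUTH_GAUSS, **TRUTH_BBP)
    return pp.make_profile(
        params, kd=0.05, b_s=0.3, b_bp_s=1.75e-3, time="2016-07-13T07:40",
        zm=20.0, noise_chl=0.0, noise_bbp=0.0, noise_par=0.0,
        rng=np.random.default_rng(0),
    )


@pytest.fixture(scope="session")
def seasonal_records():
    """Small deterministic seasonal scenario shared across tests."""
    spec = pp.ScenarioSpec(cadence_days=10, seed=42)
    return pp.make_seasonal_series(spec)
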