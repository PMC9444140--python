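import pytest
from hypothesis import settings, HealthCheck

import nvusim as nv

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    """Packaged default parameter set (literature tables)."""
    return nv.default_config()


@pytest.fixture(scope="session")
def mesh(config):
    """Default 60x120 mesh of the phantom."""
    return nv.build_mesh(config.geometry, 60, 120)


@pytest.fixture(scope="session")
def coarse_mesh(config):
    return nv.build_mesh(config.geometry, 24, 40)


@pytest.fixture(scope="session")
def coarse_config(config):
    """Desk-scale configuration for fast coupled runs in tests."""
    return config.replace(numerics={"nr": 24, "nz": 40, "dt": 2e-3},
                          scenario={"t_end": 0.5, "t0": 0.25,
                                    "dt_smooth": 0.1})


@pytest.fixture
def newtonian_rheology():
    """Degenerate Carreau parameters that behave as a Newtonian fluid."""
    mu = 3.45e-3
    return nv.RheologyParams(rho_blood=1070.0, mu_0=mu * (1 + 1e-9),
                             mu_inf=mu, lambda_c=0.0, n_idx=1.0)
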