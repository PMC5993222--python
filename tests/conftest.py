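import numpy as np
import pytest

from cocycle import (BoundaryForcing, CoParams, ColumnGrid, EnvForcing,
                     ScenarioConfig, TracerState)


@pytest.fixture(scope="session")
def params():
    return CoParams()


@pytest.fixture()
def box_grid():
    return ColumnGrid.uniform(50.0, 1)


def make_linear_box_env(dust_dep: float = 1.0) -> EnvForcing:
    """Single-layer forcing with no biology: dCo obeys dc/dt = S - Lambda*c.

    Oxygen and bacteria far above their half saturations, no light, no
    phytoplankton, so scavenging runs at a constant near-maximal rate and
    dissolution is inactive.
    """
    one = np.ones(1)
    return EnvForcing(
        t=20.0 * one, o2=1e6 * one, par=0.0 * one, bact=1e6 * one,
        si=0.0 * one, nano_biomass=0.0 * one, diat_biomass=0.0 * one,
        mu_nano=0.0 * one, mu_diat=0.0 * one, graze_rate=0.0 * one,
        mort_rate=0.0 * one, agg_rate=0.0 * one, remin_rate_c=0.0 * one,
        boundary=BoundaryForcing(dust_dep=dust_dep),
    )


@pytest.fixture()
def linear_box_env():
    return make_linear_box_env()


@pytest.fixture()
def closed_box_cfg():
    return ScenarioConfig(scenario_name="closed_box", years=1.0, dt=0.25)


@pytest.fixture()
def small_state():
    st = TracerState.zeros(3)
    st.dco[:] = [50.0, 30.0, 10.0]
    st.scco[:] = [1.0, 2.0, 3.0]
    return st
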