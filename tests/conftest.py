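import numpy as np
import pytest
from hypothesis import settings

from hypoxphys import respirometry as resp
from hypoxphys import synth
from hypoxphys.gas import WaterConditions, mo2_unit_convert

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def seawater_24():
    """Respirometry water: 24 degC, 35 psu, 760 mmHg."""
    return WaterConditions(temperature=24.0, salinity=35.0)


@pytest.fixture(scope="session")
def chamber(seawater_24):
    """2.5 L respirometer holding a 91 g fish."""
    return resp.ChamberSetup(v_chamber=2.5, m_f=0.091, conditions=seawater_24)


@pytest.fixture(scope="session")
def smr_umol():
    """Quiescent uptake matching 151 mgO2 kg-1 h-1."""
    return mo2_unit_convert(151.0, "mgO2/kg/h", "umol/kg/min")


@pytest.fixture(scope="session")
def regulator_fish(smr_umol):
    return synth.FishModel(smr_true=smr_umol, pcrit_true=36.2, mass=0.091)


@pytest.fixture()
def quiet_trace_cfg(seawater_24):
    """Zero-noise, burst-free 2 h intermittent-flow settings."""
    return synth.TraceSimConfig(
        chamber_volume=2.5, duration_h=2.0, noise_sd=0.0, seed=11,
        conditions=seawater_24,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
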