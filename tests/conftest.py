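"""Shared fixtures: simulated Windkessel beats used across the suite.

All fixtures are generated programmatically; there are no stored data
files.  Default conditions are the benchmark half-sine inflow (SV = 70 mL,
T_sys = 0.3 s, T_beat = 1.0 s, dt = 1 ms, 10 beats) driving a Windkessel
with R = 1.2 mmHg·s/mL, C = 1.4 mL/mmHg, P_zf = 20 mmHg, and Z_c = 0.05
mmHg·s/mL for the three-element variant.
"""

import numpy as np
import pytest

from reservoirbp.sim import InflowSpec, WindkesselSpec, windkessel_beat


@pytest.fixture(scope="session")
def inflow_spec() -> InflowSpec:
    return InflowSpec(T_sys=0.3, T_beat=1.0, SV=70.0, n_beats=10, dt=1e-3)


@pytest.fixture(scope="session")
def wk2_spec() -> WindkesselSpec:
    return WindkesselSpec(R=1.2, C=1.4, Z_c=0.0, P_zf=20.0, P0=70.0)


@pytest.fixture(scope="session")
def wk3_spec() -> WindkesselSpec:
    return WindkesselSpec(R=1.2, C=1.4, Z_c=0.05, P_zf=20.0, P0=70.0)


@pytest.fixture(scope="session")
def wk2_beat(inflow_spec, wk2_spec):
    return windkessel_beat(inflow_spec, wk2_spec)


@pytest.fixture(scope="session")
def wk3_beat(inflow_spec, wk3_spec):
    return windkessel_beat(inflow_spec, wk3_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
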