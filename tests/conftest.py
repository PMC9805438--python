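import numpy as np
import pytest

from neovent.bedside import calibrate_characteristics
from neovent.mechanics import SimConfig, VentSettings, make_patient
from neovent.protocol import default_sweep_grid, run_sweep


@pytest.fixture(scope="session")
def cfg():
    return SimConfig()


@pytest.fixture(scope="session")
def p3_symmetric():
    """Homogeneous-lung reference patient: C=1.14 ml/cmH2O, Cw/CL=5.3, Rc=131, R1=R2=88."""
    return make_patient(1.14, 5.3, 1.0, 131.0, 88.0, label="P3-hom")


@pytest.fixture(scope="session")
def settings_rr50():
    return VentSettings(RR=50.0, PIP=25.0, PEEP=5.0, IE=(1, 2), rise_time=0.0)


@pytest.fixture(scope="session")
def p3_sweep12():
    """Default P3 sweep at Cw/CL = 12 (9 T1/T2 values x 5 rates, MV 0.8 l/min)."""
    return run_sweep(default_sweep_grid("P3"))


@pytest.fixture(scope="session")
def p3_sweep_full():
    """P3 sweep extended over Cw/CL in {5, 8, 12}."""
    return run_sweep(default_sweep_grid("P3", cwcl_values=(5.0, 8.0, 12.0)))


@pytest.fixture(scope="session")
def p3_calibration(p3_sweep12):
    return calibrate_characteristics(p3_sweep12)


def single_compartment_vt(dp, C, R, Ti, Te):
    """Closed-form steady-cycle tidal volume of a first-order RC system under
    a square pressure wave (rise time zero): the independent oracle for the
    reduced configurations of the two-compartment circuit."""
    tau = R * C
    T = Ti + Te
    return dp * C * (1 - np.exp(-Ti / tau)) * (1 - np.exp(-Te / tau)) / (1 - np.exp(-T / tau))
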