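import numpy as np
import pytest

from cardioem.fixtures import (reference_fixture_suite, make_geometry,
                               make_sinus_protocol, make_ca_template)
from cardioem.ionic import CellParams, StimulusProtocol
from cardioem.tissue import TissueParams


@pytest.fixture(scope="session")
def suite():
    return reference_fixture_suite()


@pytest.fixture(scope="session")
def cable(suite):
    return make_geometry(suite["cv_cable"]["spec"])


@pytest.fixture(scope="session")
def shell(suite):
    return make_geometry(suite["sweep_shell"]["spec"])


@pytest.fixture(scope="session")
def sinus_protocol(suite, shell):
    return make_sinus_protocol(shell, **suite["sweep_shell"]["protocol"])


@pytest.fixture(scope="session")
def tissue_params():
    return TissueParams()


@pytest.fixture(scope="session")
def epi_params():
    return CellParams(region="epi")


@pytest.fixture(scope="session")
def ca_template_epi():
    return make_ca_template("epi", 600.0)


@pytest.fixture(scope="session")
def reference_beat(epi_params):
    """One stimulated beat from a converged state, integrated both by the
    fixed-step scheme and by the adaptive reference integrator."""
    from cardioem.ionic import (pre_paced_state, run_paced_cell,
                                run_beat_reference)
    proto = StimulusProtocol(n_beats=1)
    start = pre_paced_state(epi_params, n_beats=10)
    stepper = run_paced_cell(epi_params, proto, initial=start, sample_dt=0.5)
    reference = run_beat_reference(epi_params, start, proto, sample_dt=0.5)
    return stepper, reference


def synthetic_hemo_trace(V, P, P_sa=None, cycle_length=None, n_cycles=1):
    """Build a minimal HemoTrace whose final cycle is the given loop."""
    from cardioem.hemodynamics import HemoTrace
    V = np.asarray(V, float)
    P = np.asarray(P, float)
    n = len(V)
    cl = float(cycle_length if cycle_length is not None else n)
    total = cl * n_cycles
    t = np.linspace(total / n, total, n)
    z = np.zeros(n)
    return HemoTrace(
        t=t, P_lv=P, V_lv=V, P_rv=z, V_rv=z + 1,
        P_sa=(np.asarray(P_sa, float) if P_sa is not None else P),
        P_sv=z, P_pa=z, P_pv=z, tension=z, SL=z + 2.0,
        valve_av=z.astype(bool), valve_mv=z.astype(bool),
        cycle_length=cl, n_cycles=n_cycles,
        atp_last=np.ones((n, 1)), tension_last=np.zeros((n, 1)),
        eat_nodes=np.array([20.0]), total_volume=(0.0, 0.0))
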