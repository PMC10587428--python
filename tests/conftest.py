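import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.integrate import solve_ivp

from tackit.aif import FengInput
from tackit.kinetics import KineticParams
from tackit.schedule import fine_time_grid, frame_average, default_frame_schedule

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schedule():
    return default_frame_schedule()


@pytest.fixture(scope="session")
def aif():
    return FengInput()


def ode_tissue_curve(params: KineticParams, cp, t_min: np.ndarray) -> np.ndarray:
    """Independent forward-model oracle: stiff numerical ODE integration.

    Solves dC1/dt = K1*Cp - (k2+k3)*C1, dC2/dt = k3*C1 with LSODA at tight
    tolerance and returns Ct = C1 + C2 on ``t_min``.  Shares no code with the
    analytic-convolution implementation.
    """

    def rhs(t, y):
        c1, c2 = y
        return [params.K1 * float(cp(t)) - (params.k2 + params.k3) * c1, params.k3 * c1]

    sol = solve_ivp(
        rhs,
        (float(t_min[0]), float(t_min[-1])),
        [0.0, 0.0],
        method="LSODA",
        t_eval=t_min,
        rtol=1e-10,
        atol=1e-12,
        max_step=0.05,
    )
    assert sol.success
    return sol.y[0] + sol.y[1]


def ode_oracle_tac(params: KineticParams, cp, cb, schedule, step_s: float = 0.5) -> np.ndarray:
    """Frame-averaged oracle TAC including the blood-volume mixing term."""
    t = fine_time_grid(schedule, step_s)
    ct = ode_tissue_curve(params, cp, t)
    curve = (1.0 - params.Vb) * ct + params.Vb * np.asarray(cb(t))
    return frame_average(t, curve, schedule)
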