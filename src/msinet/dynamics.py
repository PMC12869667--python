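"""Two-timescale firing-rate dynamics of the five-unit network.

Each unit x obeys leaky first-order dynamics

    tau_fast * du_x/dt = -u_x + net_x,      z_x = f(u_x),

with logistic activation f(u) = z_max / (1 + exp(-act_slope*(u - act_center))).
Net inputs follow the wiring described in :mod:`msinet.params`:

    net_A  = i0_a*ext_a + w_av*z_V - l_v*q_v
    net_V  = i0_v*ext_v + w_va*z_A - l_a*q_a
    net_M  = w_ma*z_A + w_mv*z_V
    net_Ia = w_Ia*z_A - l_va*z_Iv
    net_Iv = w_Iv*z_V - l_av*z_Ia

The slow inhibition traces q_a, q_v low-pass filter the interneuron
outputs with time constant tau_slow, so the feedback inhibition produced
by one stimulus persists across the 1-3 s inter-stimulus intervals of
the task and shapes the response to the next stimulus.

Integration is explicit Euler (default dt = 1 ms; the fastest time
constant is 15 ms, and the dt-convergence tests guard accuracy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .params import NetworkParams
from .stimuli import StimulusEvent, events_to_drive

__all__ = [
    "NetworkState",
    "SimulationTrace",
    "activation",
    "step",
    "simulate",
    "rest_state",
]

# Columns of the firing-rate block of a trace, in order.
UNITS = ("a", "v", "m", "Ia", "Iv")


def _logistic(u: float, slope: float, center: float, z_max: float) -> float:
    return z_max / (1.0 + math.exp(-slope * (u - center)))


def activation(u, params: NetworkParams):
    """Logistic activation mapping membrane input to firing rate.

    Monotonically increasing, bounded in (0, z_max), equal to
    ``z_max / 2`` at ``u = act_center``.  Accepts scalars or arrays.
    """
    u = np.asarray(u, dtype=float)
    out = params.z_max / (1.0 + np.exp(-params.act_slope * (u - params.act_center)))
    return float(out) if out.ndim == 0 else out


@dataclass
class NetworkState:
    """Instantaneous state: membrane inputs, firing rates, slow traces."""

    u_a: float = 0.0
    u_v: float = 0.0
    u_m: float = 0.0
    u_Ia: float = 0.0
    u_Iv: float = 0.0
    z_a: float = 0.0
    z_v: float = 0.0
    z_m: float = 0.0
    z_Ia: float = 0.0
    z_Iv: float = 0.0
    q_a: float = 0.0
    q_v: float = 0.0
    t: float = 0.0

    def as_vector(self) -> np.ndarray:
        """State vector [u_a, u_v, u_m, u_Ia, u_Iv, q_a, q_v]."""
        return np.array(
            [self.u_a, self.u_v, self.u_m, self.u_Ia, self.u_Iv, self.q_a, self.q_v]
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray, params: NetworkParams, t: float = 0.0):
        u_a, u_v, u_m, u_Ia, u_Iv, q_a, q_v = (float(x) for x in vec)
        s = params.act_slope
        c = params.act_center
        cI = params.act_center_I
        zm = params.z_max
        return cls(
            u_a=u_a, u_v=u_v, u_m=u_m, u_Ia=u_Ia, u_Iv=u_Iv,
            z_a=_logistic(u_a, s, c, zm),
            z_v=_logistic(u_v, s, c, zm),
            z_m=_logistic(u_m, s, c, zm),
            z_Ia=_logistic(u_Ia, s, cI, zm),
            z_Iv=_logistic(u_Iv, s, cI, zm),
            q_a=q_a, q_v=q_v, t=t,
        )

    def validate(self) -> None:
        vec = self.as_vector()
        if not np.all(np.isfinite(vec)):
            raise FloatingPointError(f"non-finite network state: {self}")


# ---------------------------------------------------------------------------
# Integration kernel.  Pure-Python scalar loop, JIT-compiled with numba
# when available (identical arithmetic either way).
# ---------------------------------------------------------------------------

def _integrate(
    state,            # float64[7], modified in place
    ext_a, ext_v,     # float64[n] external drive per step (0 or 1 scaled)
    jit_Ia, jit_Iv,   # float64[n] one-off additive jitter on interneurons
    dt,
    w_ma, w_mv, w_av, w_va, w_Ia, w_Iv,
    l_av, l_va, l_a, l_v,
    tau_fast, tau_slow, slope, center, center_I, z_max, i0_a, i0_v,
    out_z,            # float64[n+1, 5]
    out_q,            # float64[n+1, 2]
):
    n = ext_a.shape[0]
    kf = dt / tau_fast
    ks = dt / tau_slow
    u_a = state[0]
    u_v = state[1]
    u_m = state[2]
    u_Ia = state[3]
    u_Iv = state[4]
    q_a = state[5]
    q_v = state[6]
    z_a = z_max / (1.0 + math.exp(-slope * (u_a - center)))
    z_v = z_max / (1.0 + math.exp(-slope * (u_v - center)))
    z_m = z_max / (1.0 + math.exp(-slope * (u_m - center)))
    z_Ia = z_max / (1.0 + math.exp(-slope * (u_Ia - center_I)))
    z_Iv = z_max / (1.0 + math.exp(-slope * (u_Iv - center_I)))
    out_z[0, 0] = z_a
    out_z[0, 1] = z_v
    out_z[0, 2] = z_m
    out_z[0, 3] = z_Ia
    out_z[0, 4] = z_Iv
    out_q[0, 0] = q_a
    out_q[0, 1] = q_v
    for i in range(n):
        u_Ia += jit_Ia[i]
        u_Iv += jit_Iv[i]
        net_a = i0_a * ext_a[i] + w_av * z_v - l_v * q_v
        net_v = i0_v * ext_v[i] + w_va * z_a - l_a * q_a
        net_m = w_ma * z_a + w_mv * z_v
        net_Ia = w_Ia * z_a - l_va * z_Iv
        net_Iv = w_Iv * z_v - l_av * z_Ia
        u_a += kf * (net_a - u_a)
        u_v += kf * (net_v - u_v)
        u_m += kf * (net_m - u_m)
        u_Ia += kf * (net_Ia - u_Ia)
        u_Iv += kf * (net_Iv - u_Iv)
        q_a += ks * (z_Ia - q_a)
        q_v += ks * (z_Iv - q_v)
        z_a = z_max / (1.0 + math.exp(-slope * (u_a - center)))
        z_v = z_max / (1.0 + math.exp(-slope * (u_v - center)))
        z_m = z_max / (1.0 + math.exp(-slope * (u_m - center)))
        z_Ia = z_max / (1.0 + math.exp(-slope * (u_Ia - center_I)))
        z_Iv = z_max / (1.0 + math.exp(-slope * (u_Iv - center_I)))
        out_z[i + 1, 0] = z_a
        out_z[i + 1, 1] = z_v
        out_z[i + 1, 2] = z_m
        out_z[i + 1, 3] = z_Ia
        out_z[i + 1, 4] = z_Iv
        out_q[i + 1, 0] = q_a
        out_q[i + 1, 1] = q_v
    state[0] = u_a
    state[1] = u_v
    state[2] = u_m
    state[3] = u_Ia
    state[4] = u_Iv
    state[5] = q_a
    state[6] = q_v


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _integrate = njit(cache=True, fastmath=False)(_integrate)
except ImportError:  # pragma: no cover
    pass


def _params_args(p: NetworkParams) -> tuple:
    return (
        p.w_ma, p.w_mv, p.w_av, p.w_va, p.w_Ia, p.w_Iv,
        p.l_av, p.l_va, p.l_a, p.l_v,
        p.tau_fast, p.tau_slow, p.act_slope, p.act_center, p.act_center_I, p.z_max,
        p.i0_a, p.i0_v,
    )


@dataclass
class SimulationTrace:
    """Uniformly sampled activity time courses produced by :func:`simulate`."""

    dt: float
    t: np.ndarray            # (n+1,) time grid, ms
    z: np.ndarray            # (n+1, 5) firing rates, columns = UNITS
    q: np.ndarray            # (n+1, 2) slow traces (q_a, q_v)
    events: list = field(default_factory=list)
    final_state: NetworkState | None = None

    def series(self, unit: str) -> np.ndarray:
        return self.z[:, UNITS.index(unit)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_ms": self.t,
                "z_a": self.z[:, 0],
                "z_v": self.z[:, 1],
                "z_m": self.z[:, 2],
                "z_Ia": self.z[:, 3],
                "z_Iv": self.z[:, 4],
                "q_a": self.q[:, 0],
                "q_v": self.q[:, 1],
            }
        )


def step(
    state: NetworkState,
    external: tuple[float, float],
    params: NetworkParams,
    dt: float,
) -> NetworkState:
    """One explicit-Euler update.  ``external`` is the (a, v) channel
    drive in [0, 1] multiplying the stimulus efficacies; ``dt = 0``
    returns the state unchanged."""
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    if dt == 0:
        return replace(state)
    state.validate()
    ea, ev = external
    vec = state.as_vector()
    out_z = np.empty((2, 5))
    out_q = np.empty((2, 2))
    _integrate(
        vec,
        np.array([float(ea)]), np.array([float(ev)]),
        np.zeros(1), np.zeros(1),
        float(dt), *_params_args(params), out_z, out_q,
    )
    new = NetworkState.from_vector(vec, params, t=state.t + dt)
    new.validate()
    return new


def simulate(
    events: list[StimulusEvent],
    params: NetworkParams,
    duration: float,
    dt: float = 1.0,
    initial: NetworkState | None = None,
    interneuron_jitter: list[tuple[float, float]] | None = None,
) -> SimulationTrace:
    """Integrate the network over ``duration`` ms of stimulation.

    ``events`` are rectangular input pulses; overlapping events on the
    same channel are rejected.  ``interneuron_jitter`` optionally gives,
    per event, a one-off additive (u_Ia, u_Iv) perturbation applied at
    the event's onset step — the symmetry-breaking mechanism of the
    winner-takes-all circuit (magnitudes should be infinitesimal,
    <= 1e-6).  The result is deterministic given all arguments.
    """
    n = duration / dt
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"dt={dt} must divide duration={duration}")
    n = int(round(n))
    ext_a, ext_v = events_to_drive(events, n, dt)

    jit_Ia = np.zeros(n)
    jit_Iv = np.zeros(n)
    if interneuron_jitter is not None:
        if len(interneuron_jitter) != len(events):
            raise ValueError("one jitter pair per event required")
        for ev, (ja, jv) in zip(events, interneuron_jitter):
            idx = int(round(ev.onset / dt))
            if idx < n:
                jit_Ia[idx] += ja
                jit_Iv[idx] += jv

    if initial is None:
        initial = NetworkState()
    initial.validate()
    vec = initial.as_vector()
    out_z = np.empty((n + 1, 5))
    out_q = np.empty((n + 1, 2))
    _integrate(
        vec, ext_a, ext_v, jit_Ia, jit_Iv, float(dt),
        *_params_args(params), out_z, out_q,
    )
    if not (np.all(np.isfinite(out_z)) and np.all(np.isfinite(vec))):
        raise FloatingPointError("simulation diverged to non-finite values")
    t0 = initial.t
    return SimulationTrace(
        dt=dt,
        t=t0 + dt * np.arange(n + 1),
        z=out_z,
        q=out_q,
        events=list(events),
        final_state=NetworkState.from_vector(vec, params, t=t0 + n * dt),
    )


def rest_state(
    params: NetworkParams, dt: float = 1.0, settle_ms: float = 10000.0
) -> NetworkState:
    """Zero-input fixed point of the network, found by relaxation.

    The settling horizon covers several tau_slow so the tonic values of
    the slow traces are included in the rest point.
    """
    trace = simulate([], params, duration=settle_ms, dt=dt)
    s = trace.final_state
    s.t = 0.0
    return s
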