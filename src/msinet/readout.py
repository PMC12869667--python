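"""Reaction-time readout: threshold detection, trial runner, derived measures.

The simulated reaction time is the interval between stimulus onset and
the first moment the output unit's activity crosses a fixed detection
threshold, phi = 10% of the maximum firing rate.  Crossing times are
linearly interpolated between integration samples so RTs are not
quantized to dt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import NetworkState, SimulationTrace, rest_state, simulate
from .params import NetworkParams
from .stimuli import StimulusEvent, TrialPair

__all__ = [
    "RT_THRESHOLD_FRACTION",
    "RESPONSE_WINDOW_MS",
    "SETTLE_MS",
    "WTA_JITTER",
    "RTRecord",
    "detect_rt",
    "run_condition",
    "trial_winner",
    "switch_cost",
    "multisensory_gain",
]

#: Detection threshold as a fraction of the maximum firing rate.
RT_THRESHOLD_FRACTION = 0.10
#: Crossings later than this after onset are timeouts (the next stimulus
#: could arrive from 1000 ms on, making later crossings unattributable).
RESPONSE_WINDOW_MS = 1000.0
#: Settling period preceding the first stimulus of every trial.
SETTLE_MS = 500.0
#: Magnitude of the symmetry-breaking perturbation applied to one
#: interneuron at each stimulus onset (winner-takes-all tie-break).
WTA_JITTER = 1e-6


@dataclass(frozen=True)
class RTRecord:
    """One simulated response: condition, checkpoint, RT or timeout."""

    condition: str
    checkpoint_epoch: int
    rt_ms: float | None
    timeout: bool
    winner: str | None = None  # "Ia" or "Iv" for AV trials

    def __post_init__(self) -> None:
        if self.rt_ms is not None and self.rt_ms <= 0:
            raise ValueError("rt_ms must be positive when present")
        if self.timeout != (self.rt_ms is None):
            raise ValueError("timeout flag inconsistent with rt_ms")


def detect_rt(
    trace: SimulationTrace,
    stimulus_onset: float,
    phi: float = RT_THRESHOLD_FRACTION,
    window: float = RESPONSE_WINDOW_MS,
) -> float | None:
    """Time from onset to the output unit's first threshold crossing.

    Returns None (timeout) if ``z_m`` never reaches ``phi * z_max``
    within ``window`` ms of onset.  The crossing instant is linearly
    interpolated between samples.
    """
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must lie in (0, 1)")
    t = trace.t
    if stimulus_onset < t[0] or stimulus_onset > t[-1]:
        raise ValueError(
            f"onset {stimulus_onset} outside trace [{t[0]}, {t[-1]}]"
        )
    # threshold on the absolute rate scale; z_max is normalized to the
    # activation bound used by the simulation that produced the trace
    z_m = trace.series("m")
    zmax = 1.0
    thr = phi * zmax
    end = min(stimulus_onset + window, t[-1])
    i0 = int(np.searchsorted(t, stimulus_onset, side="left"))
    i1 = int(np.searchsorted(t, end, side="right"))
    seg = z_m[i0:i1]
    above = np.nonzero(seg >= thr)[0]
    if above.size == 0:
        return None
    k = int(above[0])
    if k == 0:
        # already at/above threshold at onset sample
        t_cross = t[i0]
    else:
        z0, z1 = seg[k - 1], seg[k]
        frac = (thr - z0) / (z1 - z0)
        t_cross = t[i0 + k - 1] + frac * trace.dt
    rt = t_cross - stimulus_onset
    if rt > window:
        return None
    return float(rt)


def _event_jitter(modality: str, rng: np.random.Generator | None, scale: float):
    """Tie-break perturbation for one stimulus onset.

    Only audiovisual pulses drive both interneurons symmetrically and
    need a tie-break; the perturbed side is drawn from ``rng`` (auditory
    side if no generator is supplied, keeping everything deterministic).
    """
    if modality != "AV" or scale == 0.0:
        return (0.0, 0.0)
    if rng is None or bool(rng.integers(2)):
        return (scale, 0.0)
    return (0.0, scale)


def run_condition(
    params: NetworkParams,
    pair: TrialPair,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
    rest: NetworkState | None = None,
    jitter_scale: float = WTA_JITTER,
    jitter: list[tuple[float, float]] | None = None,
) -> tuple[float | None, float | None, SimulationTrace]:
    """Simulate one two-stimulus trial and read out both RTs.

    The trial is a single continuous run — 500 ms settling, stimulus 1,
    the ISI, stimulus 2, then a full response window — so the slow
    inhibition traces raised by the first stimulus shape the second
    response.  Returns (rt_first, rt_second, trace); a None RT flags a
    timeout.  ``jitter`` overrides the per-event tie-break pairs
    explicitly (used by the symmetry tests).
    """
    onset1 = SETTLE_MS
    onset2 = SETTLE_MS + pair.isi
    duration = onset2 + RESPONSE_WINDOW_MS + 200.0
    events = [
        StimulusEvent(pair.first_modality, onset1),
        StimulusEvent(pair.second_modality, onset2),
    ]
    if jitter is None:
        jitter = [
            _event_jitter(ev.modality, rng, jitter_scale) for ev in events
        ]
    if rest is None:
        rest = rest_state(params, dt=dt)
    trace = simulate(
        events, params, duration, dt=dt, initial=rest,
        interneuron_jitter=jitter,
    )
    rt1 = detect_rt(trace, onset1)
    rt2 = detect_rt(trace, onset2)
    return rt1, rt2, trace


def trial_winner(trace: SimulationTrace, onset: float, span: float = 300.0):
    """Identity of the interneuron dominating after a stimulus onset."""
    t = trace.t
    i0 = int(np.searchsorted(t, onset))
    i1 = int(np.searchsorted(t, onset + span))
    peak_Ia = float(trace.z[i0:i1, 3].max())
    peak_Iv = float(trace.z[i0:i1, 4].max())
    return "Ia" if peak_Ia >= peak_Iv else "Iv"


def switch_cost(rt_switch: float, rt_repeat: float) -> float:
    """Modality switch cost in ms; positive when switching is slower."""
    if rt_switch is None or rt_repeat is None:
        raise ValueError("switch cost undefined for timed-out responses")
    if not (math.isfinite(rt_switch) and math.isfinite(rt_repeat)):
        raise ValueError("switch cost requires finite RTs")
    return rt_switch - rt_repeat


def multisensory_gain(rt_av: float, rt_a: float, rt_v: float) -> float:
    """RT advantage of the audiovisual stimulus over the best unisensory
    one, in ms; negative values indicate cross-modal competition."""
    for rt in (rt_av, rt_a, rt_v):
        if rt is None or not math.isfinite(rt):
            raise ValueError("multisensory gain requires finite RTs")
    return min(rt_a, rt_v) - rt_av
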