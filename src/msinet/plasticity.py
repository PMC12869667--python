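"""Hebbian / anti-Hebbian training of the network across development.

Development is simulated as one continuous session of single-stimulus
exposures (one epoch = one exposure; 500 epochs correspond to roughly
three years of age).  After each exposure the trained synapses are
updated from the time-averaged pre- and postsynaptic firing rates over
the 500 ms response window:

* excitatory synapses (feedforward w_ma, w_mv and the signed
  cross-modal w_av, w_va) follow long-term potentiation,
  ``w += gamma * pre * post``, clipped to their class bounds — repeated
  audiovisual co-activation therefore drives the cross-modal weights
  from negative (competition) through zero to positive (facilitation);
* inhibitory feedback magnitudes (l_a, l_v) follow an anti-Hebbian
  rule, ``l += gamma * pre * (z_max - post)``: the synapse strengthens
  when the presynaptic interneuron fires while the postsynaptic input
  unit is suppressed.

The input->interneuron weights and the interneuron mutual inhibition
are not plastic.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import NetworkState, rest_state, simulate
from .params import LearningRates, NetworkParams
from .readout import SETTLE_MS, WTA_JITTER, _event_jitter
from .stimuli import (
    DEFAULT_ISI_HI,
    DEFAULT_ISI_LO,
    MixSpec,
    StimulusEvent,
    make_training_stream,
)

__all__ = [
    "CHECKPOINT_EPOCHS",
    "AGE_GROUP_CHECKPOINTS",
    "ADULT_CHECKPOINTS",
    "TrainingSchedule",
    "hebb_ltp",
    "anti_hebb",
    "train",
    "train_logged",
]

#: Default epochs at which parameter snapshots are taken.
CHECKPOINT_EPOCHS = (0, 500, 1000, 1500, 2000, 2500, 3000)

#: Epoch -> age-group mapping for the three child/adolescent groups; the
#: adult group averages the checkpoints in ADULT_CHECKPOINTS.
AGE_GROUP_CHECKPOINTS = {"6-9": 0, "10-12": 500, "13-17": 1000}
ADULT_CHECKPOINTS = (1500, 2000, 2500, 3000)
AGE_GROUPS = ("6-9", "10-12", "13-17", "adult")

#: Length of the post-onset window over which pre/post activity is
#: averaged for the learning rules (ms).  It covers the stimulus pulse
#: and the decay of the evoked response; keeping it short makes the
#: Hebbian product selective for genuine co-activation (during a
#: unisensory pulse the other modality is suppressed below its
#: spontaneous rate, so cross-modal updates come almost entirely from
#: audiovisual exposures).
LEARNING_WINDOW_MS = 150.0


@dataclass(frozen=True)
class TrainingSchedule:
    """Exposure count, stimulus-mix phases and learning rates."""

    mix_schedule: list = field(
        default_factory=lambda: [(0, MixSpec(0.30, 0.20, 0.50))]
    )
    n_epochs: int = 3000
    rates: LearningRates = field(default_factory=LearningRates)
    checkpoints: tuple = CHECKPOINT_EPOCHS
    isi_lo: float = DEFAULT_ISI_LO
    isi_hi: float = DEFAULT_ISI_HI

    def __post_init__(self) -> None:
        if self.n_epochs < 0:
            raise ValueError("n_epochs must be nonnegative")
        bad = [c for c in self.checkpoints if not 0 <= c <= self.n_epochs]
        if bad:
            raise ValueError(f"checkpoints outside [0, n_epochs]: {bad}")


def hebb_ltp(
    w: float, pre: float, post: float, gamma: float, bounds: tuple[float, float]
) -> float:
    """Long-term potentiation: ``w + gamma*pre*post`` clipped to bounds."""
    lo, hi = bounds
    return min(hi, max(lo, w + gamma * pre * post))


def anti_hebb(
    l: float, pre: float, post: float, gamma: float,
    l_max: float, z_max: float = 1.0,
) -> float:
    """Inhibitory strengthening proportional to presynaptic activity and
    postsynaptic suppression: ``l + gamma*pre*(z_max - post)``, clipped
    to [0, l_max]."""
    return min(l_max, max(0.0, l + gamma * pre * (z_max - post)))


def _apply_updates(p: NetworkParams, rates: LearningRates, zbar) -> NetworkParams:
    """One per-exposure update of all trained synapses.

    ``zbar`` holds the window-averaged rates (za, zv, zm, zIa, zIv).
    """
    za, zv, zm, zIa, zIv = zbar
    ff = (0.0, rates.w_max_ff)
    cm = (rates.w_cm_min, rates.w_cm_max)
    return p.replace(
        w_ma=hebb_ltp(p.w_ma, za, zm, rates.gamma_ff, ff),
        w_mv=hebb_ltp(p.w_mv, zv, zm, rates.gamma_ff, ff),
        w_av=hebb_ltp(p.w_av, zv, za, rates.gamma_cm, cm),
        w_va=hebb_ltp(p.w_va, za, zv, rates.gamma_cm, cm),
        l_a=anti_hebb(p.l_a, zIa, zv, rates.gamma_fb, rates.l_max_fb, p.z_max),
        l_v=anti_hebb(p.l_v, zIv, za, rates.gamma_fb, rates.l_max_fb, p.z_max),
    )


def exposure_response(
    params: NetworkParams,
    modality: str,
    state: NetworkState,
    segment_ms: float,
    dt: float,
    jitter: tuple[float, float],
):
    """Simulate one exposure segment; return (zbar, final_state).

    The stimulus starts at the beginning of the segment, whose length is
    the ISI to the next exposure, so slow traces carry over naturally.
    Used both by the training loop and by the single-exposure replay
    oracle in the tests.
    """
    n = max(1, int(round(segment_ms / dt)))
    trace = simulate(
        [StimulusEvent(modality, 0.0)],
        params,
        duration=n * dt,
        dt=dt,
        initial=state,
        interneuron_jitter=[jitter],
    )
    w = min(n, int(round(LEARNING_WINDOW_MS / dt)))
    zbar = trace.z[: w + 1].mean(axis=0)
    return zbar, trace.final_state


def train_logged(
    params0: NetworkParams,
    schedule: TrainingSchedule,
    rng: np.random.Generator,
    dt: float = 1.0,
):
    """Run the developmental training loop.

    Returns (checkpoints, log) where ``checkpoints`` is a list of
    (epoch, NetworkParams) snapshots and ``log`` a per-epoch dict of
    arrays tracking the trained weights.  Deterministic per rng state.
    """
    params0.validate()
    stream = make_training_stream(
        schedule.mix_schedule, schedule.n_epochs, rng,
        isi_lo=schedule.isi_lo, isi_hi=schedule.isi_hi,
    )
    tracked = ("w_ma", "w_mv", "w_av", "w_va", "l_a", "l_v")
    log = {k: np.empty(schedule.n_epochs) for k in tracked}
    log["epoch"] = np.arange(schedule.n_epochs)
    log["modality"] = np.empty(schedule.n_epochs, dtype="U2")

    params = params0
    state = rest_state(params, dt=dt)
    # settle before the first exposure
    if schedule.n_epochs:
        state = simulate([], params, SETTLE_MS, dt=dt, initial=state).final_state
    checkpoints: list[tuple[int, NetworkParams]] = []
    ckpt_set = set(schedule.checkpoints)
    for epoch, modality, isi in stream:
        if epoch in ckpt_set:
            checkpoints.append((epoch, copy.deepcopy(params)))
        jit = _event_jitter(modality, rng, WTA_JITTER)
        segment = max(LEARNING_WINDOW_MS, round(isi / dt) * dt)
        zbar, state = exposure_response(params, modality, state, segment, dt, jit)
        params = _apply_updates(params, schedule.rates, zbar)
        for k in tracked:
            log[k][epoch] = getattr(params, k)
        log["modality"][epoch] = modality
        if not all(
            math.isfinite(getattr(params, k)) for k in tracked
        ):  # pragma: no cover - guarded by bounded rules
            raise FloatingPointError(f"non-finite weight at epoch {epoch}")
    if schedule.n_epochs in ckpt_set:
        checkpoints.append((schedule.n_epochs, copy.deepcopy(params)))
    return checkpoints, log


def train(
    params0: NetworkParams,
    schedule: TrainingSchedule,
    rng: np.random.Generator,
    dt: float = 1.0,
) -> list[tuple[int, NetworkParams]]:
    """Developmental training; returns parameter snapshots per checkpoint."""
    checkpoints, _ = train_logged(params0, schedule, rng, dt=dt)
    return checkpoints
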