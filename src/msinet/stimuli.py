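"""Stimulus events, trial pairs and seeded training streams.

The task protocol follows a bisensory reaction-time paradigm: brief
(60 ms) auditory, visual or combined audiovisual pulses separated by
inter-stimulus intervals drawn uniformly from 1-3 s (mean 2 s).  Trial
pairs realize the six repeat/switch conditions used to quantify the
modality switch cost; training streams are long randomized sequences of
single exposures with configurable modality mixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MODALITIES",
    "CONDITIONS",
    "StimulusEvent",
    "TrialPair",
    "MixSpec",
    "sample_isi",
    "make_condition_pair",
    "make_training_stream",
    "events_to_drive",
]

MODALITIES = ("A", "V", "AV")

#: The six repeat/switch conditions.  Switch trials present the second
#: stimulus after a different-modality first stimulus (A-switch = V->A).
CONDITIONS = (
    "A-repeat",
    "A-switch",
    "V-repeat",
    "V-switch",
    "AV-repeat",
    "AV-switch",
)

DEFAULT_PULSE_MS = 60.0
DEFAULT_ISI_LO = 1000.0
DEFAULT_ISI_HI = 3000.0
TEST_ISI_MS = 2000.0


@dataclass(frozen=True)
class StimulusEvent:
    """One rectangular external pulse.

    ``efficacy`` scales both active channels equally: auditory and
    visual components of an AV pulse always share the same efficacy.
    """

    modality: str
    onset: float
    pulse_duration: float = DEFAULT_PULSE_MS
    efficacy: float = 1.0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.onset < 0:
            raise ValueError("onset must be nonnegative")

    @property
    def drives_a(self) -> bool:
        return self.modality in ("A", "AV")

    @property
    def drives_v(self) -> bool:
        return self.modality in ("V", "AV")


@dataclass(frozen=True)
class TrialPair:
    """An ordered two-stimulus trial defining one repeat/switch condition."""

    first_modality: str
    second_modality: str
    isi: float
    condition: str = field(default="")

    def __post_init__(self) -> None:
        for m in (self.first_modality, self.second_modality):
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}")
        if self.isi <= 0:
            raise ValueError("isi must be positive")
        if self.condition and self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition label {self.condition!r}")


@dataclass(frozen=True)
class MixSpec:
    """Probabilities of AV / A-only / V-only exposures in a training phase."""

    p_av: float
    p_a: float
    p_v: float

    def __post_init__(self) -> None:
        for p in (self.p_av, self.p_a, self.p_v):
            if not 0.0 <= p <= 1.0:
                raise ValueError("mix probabilities must lie in [0, 1]")
        if abs(self.p_av + self.p_a + self.p_v - 1.0) > 1e-9:
            raise ValueError(
                f"mix probabilities must sum to 1, got "
                f"{self.p_av + self.p_a + self.p_v}"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_av, self.p_a, self.p_v)


def sample_isi(
    rng: np.random.Generator,
    lo: float = DEFAULT_ISI_LO,
    hi: float = DEFAULT_ISI_HI,
) -> float:
    """Uniform inter-stimulus interval draw in [lo, hi] ms."""
    if not 0 < lo <= hi:
        raise ValueError(f"require 0 < lo <= hi, got lo={lo}, hi={hi}")
    return float(rng.uniform(lo, hi))


_PAIRS = {
    "A-repeat": ("A", "A"),
    "A-switch": ("V", "A"),
    "V-repeat": ("V", "V"),
    "V-switch": ("A", "V"),
    "AV-repeat": ("AV", "AV"),
    # default multisensory switch variant: V -> AV (A -> AV is also
    # supported by constructing the pair directly; batteries average both)
    "AV-switch": ("V", "AV"),
}


def make_condition_pair(condition: str, isi: float = TEST_ISI_MS) -> TrialPair:
    """Trial pair for a named condition at the given ISI."""
    try:
        first, second = _PAIRS[condition]
    except KeyError:
        raise ValueError(
            f"unknown condition {condition!r}; valid: {list(_PAIRS)}"
        ) from None
    return TrialPair(first, second, isi, condition)


def make_training_stream(
    mix_schedule: list[tuple[int, MixSpec]],
    n_epochs: int,
    rng: np.random.Generator,
    isi_lo: float = DEFAULT_ISI_LO,
    isi_hi: float = DEFAULT_ISI_HI,
) -> list[tuple[int, str, float]]:
    """Randomized exposure sequence for developmental training.

    ``mix_schedule`` is a sorted list of (start_epoch, MixSpec) phases
    starting at epoch 0; the modality of epoch e is drawn from the phase
    covering e, and each exposure gets a uniform ISI.  One epoch = one
    stimulus exposure.  Returns [(epoch, modality, isi_ms), ...],
    deterministic per rng state.
    """
    if not mix_schedule:
        raise ValueError("mix schedule must contain at least one phase")
    starts = [s for s, _ in mix_schedule]
    if starts[0] != 0:
        raise ValueError("mix schedule must start at epoch 0")
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise ValueError("mix schedule phases must be sorted and non-overlapping")
    if n_epochs < 0:
        raise ValueError("n_epochs must be nonnegative")

    stream = []
    phase_idx = 0
    for epoch in range(n_epochs):
        while phase_idx + 1 < len(mix_schedule) and mix_schedule[phase_idx + 1][0] <= epoch:
            phase_idx += 1
        mix = mix_schedule[phase_idx][1]
        r = rng.random()
        if r < mix.p_av:
            modality = "AV"
        elif r < mix.p_av + mix.p_a:
            modality = "A"
        else:
            modality = "V"
        stream.append((epoch, modality, sample_isi(rng, isi_lo, isi_hi)))
    return stream


def events_to_drive(
    events: list[StimulusEvent], n_steps: int, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-step external drive on each channel; rejects same-channel overlap.

    The drive equals the event's efficacy during [onset, onset+duration)
    and 0 elsewhere.
    """
    ext_a = np.zeros(n_steps)
    ext_v = np.zeros(n_steps)
    for ev in events:
        i0 = int(round(ev.onset / dt))
        i1 = int(round((ev.onset + ev.pulse_duration) / dt))
        if i0 < 0 or i1 > n_steps:
            raise ValueError(
                f"event {ev} extends outside the simulated window "
                f"({n_steps * dt} ms)"
            )
        for drives, ext in ((ev.drives_a, ext_a), (ev.drives_v, ext_v)):
            if drives:
                if np.any(ext[i0:i1] != 0.0):
                    raise ValueError(f"overlapping events on one channel at {ev}")
                ext[i0:i1] = ev.efficacy
    return ext_a, ext_v
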