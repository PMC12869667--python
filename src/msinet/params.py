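"""Network parameters and shipped presets.

The model is a five-unit firing-rate network: auditory (A) and visual (V)
input units, a multisensory output unit (M), and two modality-specific
inhibitory interneurons (Ia, Iv).  Connectivity:

* feedforward excitation  A -> M (``w_ma``), V -> M (``w_mv``);
* direct cross-modal coupling V -> A (``w_av``) and A -> V (``w_va``),
  signed: negative (competition) in the immature network, positive
  (facilitation) after development;
* input -> interneuron excitation (``w_Ia``, ``w_Iv``);
* interneuron mutual inhibition implementing winner-takes-all
  (``l_av``, ``l_va``);
* slow feedback inhibition from each interneuron onto the *opposite*
  input unit (``l_a`` for Ia -> V, ``l_v`` for Iv -> A), acting through a
  low-pass synaptic trace with time constant ``tau_slow`` so that one
  stimulus suppresses processing of a subsequent opposite-modality
  stimulus seconds later.

Weights are dimensionless synaptic efficacies; time constants are in ms;
firing rates are normalized to ``z_max`` = 1.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

__all__ = [
    "NetworkParams",
    "LearningRates",
    "PRESETS",
    "LEARNING_PRESETS",
    "get_preset",
    "get_learning_preset",
]


@dataclass(frozen=True)
class NetworkParams:
    """All synaptic efficacies, time constants and activation parameters."""

    # feedforward input -> output
    w_ma: float = 11.0
    w_mv: float = 11.0
    # signed cross-modal coupling (w_av: V -> A, w_va: A -> V)
    w_av: float = -24.0
    w_va: float = -24.0
    # input -> same-modality interneuron
    w_Ia: float = 240.0
    w_Iv: float = 240.0
    # interneuron <-> interneuron mutual inhibition (winner-takes-all)
    l_av: float = 150.0
    l_va: float = 150.0
    # slow feedback inhibition magnitude (Ia -> V is l_a, Iv -> A is l_v)
    l_a: float = 5.0
    l_v: float = 5.0
    # time constants (ms)
    tau_fast: float = 15.0
    tau_slow: float = 1800.0
    # logistic activation (interneurons have a higher threshold and
    # are silent at rest; principal units keep a small spontaneous rate)
    act_slope: float = 0.35
    act_center: float = 9.5
    act_center_I: float = 20.0
    z_max: float = 1.0
    # external stimulus efficacies
    i0_a: float = 11.0
    i0_v: float = 11.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("w_ma", "w_mv", "w_Ia", "w_Iv", "l_av", "l_va", "l_a", "l_v"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0.0:
                raise ValueError(f"{name} must be finite and nonnegative, got {v!r}")
        for name in ("w_av", "w_va", "i0_a", "i0_v", "act_slope", "act_center", "act_center_I"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.tau_fast <= 0.0 or self.tau_slow <= 0.0:
            raise ValueError("time constants must be positive")
        if self.tau_slow <= self.tau_fast:
            raise ValueError("tau_slow must exceed tau_fast (two-timescale model)")
        if self.z_max <= 0.0:
            raise ValueError("z_max must be positive")
        if self.act_slope <= 0.0:
            raise ValueError("act_slope must be positive")

    def replace(self, **kwargs) -> "NetworkParams":
        return dataclasses.replace(self, **kwargs)

    def swap_modalities(self) -> "NetworkParams":
        """Mirror image of the network: every A-labeled quantity becomes
        the V-labeled one and vice versa."""
        return self.replace(
            w_ma=self.w_mv, w_mv=self.w_ma,
            w_av=self.w_va, w_va=self.w_av,
            w_Ia=self.w_Iv, w_Iv=self.w_Ia,
            l_av=self.l_va, l_va=self.l_av,
            l_a=self.l_v, l_v=self.l_a,
            i0_a=self.i0_v, i0_v=self.i0_a,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown NetworkParams keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "NetworkParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class LearningRates:
    """Per-synapse-class learning rates and saturation bounds.

    ``gamma_ff`` drives Hebbian LTP of the feedforward weights (w_ma,
    w_mv), ``gamma_cm`` the signed cross-modal weights (w_av, w_va) and
    ``gamma_fb`` the anti-Hebbian growth of the feedback-inhibition
    magnitudes (l_a, l_v).  Bounds cap each class: feedforward weights in
    [0, w_max_ff], cross-modal weights in [w_cm_min, w_cm_max] and
    feedback magnitudes in [0, l_max_fb].  The cross-modal range is
    asymmetric: its floor only has to contain the most inhibitory
    initial configuration (LTP never drives the weight downward), while
    its ceiling is the mature facilitatory efficacy, kept low enough
    that the excitatory A<->V loop remains stable.
    """

    gamma_ff: float = 0.045
    gamma_cm: float = 2.9
    gamma_fb: float = 0.03
    w_max_ff: float = 14.0
    w_cm_min: float = -40.0
    w_cm_max: float = 8.0
    l_max_fb: float = 80.0

    def __post_init__(self) -> None:
        for name in ("gamma_ff", "gamma_cm", "gamma_fb"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("w_max_ff", "w_cm_max", "l_max_fb"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if self.w_cm_min >= self.w_cm_max:
            raise ValueError("w_cm_min must lie below w_cm_max")

    def scaled(self, factor: float) -> "LearningRates":
        """Uniformly rescaled learning rates (same bounds)."""
        return dataclasses.replace(
            self,
            gamma_ff=self.gamma_ff * factor,
            gamma_cm=self.gamma_cm * factor,
            gamma_fb=self.gamma_fb * factor,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LearningRates":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown LearningRates keys: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# Shipped presets.  The child/adult values are calibrated (see
# docs/methods.md): the child networks show no multisensory facilitation
# and a small positive unisensory switch cost, the adult network shows
# facilitation and a larger switch cost.  The ASD child differs from the
# TD child only in strictly more inhibitory cross-modal coupling.
# ---------------------------------------------------------------------------

PRESETS: dict[str, NetworkParams] = {
    "td_child": NetworkParams(),
    "asd_child": NetworkParams(w_av=-29.0, w_va=-29.0),
    # Endpoint of typical development: trained feedforward / feedback
    # weights near their bounds, excitatory cross-modal coupling.
    "adult": NetworkParams(
        w_ma=14.0, w_mv=14.0, w_av=8.0, w_va=8.0, l_a=32.0, l_v=32.0
    ),
}

#: Reduced-plasticity factor used for the ASD learning-rate preset.
ASD_PLASTICITY_FACTOR = 0.8

LEARNING_PRESETS: dict[str, LearningRates] = {
    "td": LearningRates(),
    "asd_reduced": LearningRates().scaled(ASD_PLASTICITY_FACTOR),
}


def get_preset(name: str) -> NetworkParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown parameter preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def get_learning_preset(name: str) -> LearningRates:
    try:
        return LEARNING_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown learning preset {name!r}; available: {sorted(LEARNING_PRESETS)}"
        ) from None
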