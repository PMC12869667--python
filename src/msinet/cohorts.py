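"""Developmental cohort experiments: TD, ASD hypotheses, interventions.

A cohort specifies an initial network (TD-child or ASD-child), a
learning-rate preset (normal or reduced plasticity) and a stimulus-mix
schedule (typical experience, reduced multisensory exposure, or an
intensive multisensory intervention starting early or late).  Running a
cohort trains the network, then freezes the weights at each checkpoint
and runs the six-condition reaction-time battery, assembling an
age-group x condition trajectory table that can be compared across
cohorts or against an empirical reference table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .params import (
    ASD_PLASTICITY_FACTOR,
    LearningRates,
    NetworkParams,
    get_preset,
)
from .plasticity import (
    ADULT_CHECKPOINTS,
    AGE_GROUP_CHECKPOINTS,
    AGE_GROUPS,
    CHECKPOINT_EPOCHS,
    TrainingSchedule,
    train,
)
from .readout import multisensory_gain, run_condition, switch_cost
from .dynamics import rest_state
from .stimuli import CONDITIONS, MixSpec, TrialPair, make_condition_pair

__all__ = [
    "COHORT_NAMES",
    "TD_MIX",
    "ASD_EXPOSURE_START_MIX",
    "INTERVENTION_MIX",
    "CohortSpec",
    "RTTrajectory",
    "build_mix_schedule",
    "run_battery",
    "run_cohort",
    "trajectory_distance",
    "anova_oneway",
    "compare_to_reference",
]

#: Typical developmental stimulus mix (AV, A-only, V-only).
TD_MIX = MixSpec(0.30, 0.20, 0.50)
#: Starting mix under the reduced-multisensory-exposure hypothesis.
ASD_EXPOSURE_START_MIX = MixSpec(0.20, 0.40, 0.40)
#: Intensive multisensory intervention mix.
INTERVENTION_MIX = MixSpec(0.60, 0.10, 0.30)
#: AV increment per 500-epoch phase under the exposure hypothesis.
EXPOSURE_AV_INCREMENT = 0.10
#: Epoch at which the "late" intervention begins (second age group).
LATE_INTERVENTION_EPOCH = 500

COHORT_NAMES = (
    "TD",
    "ASD_plasticity",
    "ASD_exposure",
    "ASD_plasticity_intervention_early",
    "ASD_plasticity_intervention_late",
    "ASD_exposure_intervention_early",
    "ASD_exposure_intervention_late",
)


@dataclass(frozen=True)
class CohortSpec:
    """Named experimental cohort: initial preset, rates and mix schedule."""

    name: str
    initial_preset: str = "td_child"
    plasticity_factor: float = 1.0
    intervention_start: int | None = None  # epoch, where applicable
    n_epochs: int = 3000
    #: cap the exposure-hypothesis AV ramp at the TD level instead of
    #: applying literal +10-point increments through the end
    cap_exposure_at_td: bool = False

    @classmethod
    def named(cls, name: str, **overrides) -> "CohortSpec":
        if name not in COHORT_NAMES:
            raise ValueError(f"unknown cohort {name!r}; valid: {COHORT_NAMES}")
        kw: dict = {"name": name}
        if name != "TD":
            kw["initial_preset"] = "asd_child"
        if name.startswith("ASD_plasticity"):
            kw["plasticity_factor"] = ASD_PLASTICITY_FACTOR
        if name.endswith("intervention_early"):
            kw["intervention_start"] = 0
        elif name.endswith("intervention_late"):
            kw["intervention_start"] = LATE_INTERVENTION_EPOCH
        kw.update(overrides)
        return cls(**kw)

    @property
    def hypothesis(self) -> str:
        """Which ASD hypothesis the mix schedule follows before any
        intervention: 'plasticity' keeps the TD mix, 'exposure' uses the
        ramped reduced-AV mix."""
        if self.name.startswith("ASD_exposure"):
            return "exposure"
        if self.name.startswith("ASD_plasticity"):
            return "plasticity"
        return "td"


def _exposure_phases(n_epochs: int, cap_at_td: bool) -> list[tuple[int, MixSpec]]:
    """Reduced-exposure schedule: AV starts at 20% and gains 10 points
    every 500 epochs, the non-AV remainder split equally between A and V."""
    phases = []
    for start in range(0, n_epochs, 500):
        p_av = ASD_EXPOSURE_START_MIX.p_av + EXPOSURE_AV_INCREMENT * (start // 500)
        if cap_at_td:
            p_av = min(p_av, TD_MIX.p_av)
        p_av = min(p_av, 1.0)
        rest = (1.0 - p_av) / 2.0
        phases.append((start, MixSpec(round(p_av, 9), rest, rest)))
    return phases


def build_mix_schedule(spec: CohortSpec) -> list[tuple[int, MixSpec]]:
    """Phase list (start_epoch, MixSpec) realizing the cohort's stimulus
    experience, including any intervention switch."""
    if spec.hypothesis == "exposure":
        base = _exposure_phases(spec.n_epochs, spec.cap_exposure_at_td)
    else:
        base = [(0, TD_MIX)]
    if spec.intervention_start is None:
        return base
    start = spec.intervention_start
    kept = [(s, m) for s, m in base if s < start]
    if not kept:
        return [(0, INTERVENTION_MIX)]
    return kept + [(start, INTERVENTION_MIX)]


@dataclass
class RTTrajectory:
    """Age-group x condition table of median RTs for one cohort.

    ``cells`` maps (age_group, condition) -> RT in ms (NaN flags a
    timeout).  Derived switch costs and multisensory gains are computed
    on demand.
    """

    cohort: str
    cells: dict = field(default_factory=dict)

    def rt(self, age_group: str, condition: str) -> float:
        return self.cells[(age_group, condition)]

    def complete(self) -> bool:
        return all(
            (g, c) in self.cells for g in AGE_GROUPS for c in CONDITIONS
        )

    def check_complete(self) -> None:
        missing = [
            (g, c)
            for g in AGE_GROUPS
            for c in CONDITIONS
            if (g, c) not in self.cells
        ]
        if missing:
            raise ValueError(f"trajectory missing cells: {missing}")

    def values(self) -> np.ndarray:
        """The 24 cells in canonical (age group, condition) order."""
        self.check_complete()
        return np.array(
            [self.cells[(g, c)] for g in AGE_GROUPS for c in CONDITIONS]
        )

    def switch_cost(self, age_group: str, modality: str) -> float:
        return switch_cost(
            self.rt(age_group, f"{modality}-switch"),
            self.rt(age_group, f"{modality}-repeat"),
        )

    def multisensory_gain(self, age_group: str) -> float:
        return multisensory_gain(
            self.rt(age_group, "AV-repeat"),
            self.rt(age_group, "A-repeat"),
            self.rt(age_group, "V-repeat"),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cohort": self.cohort,
                "age_group": g,
                "condition": c,
                "median_rt_ms": self.cells[(g, c)],
            }
            for g in AGE_GROUPS
            for c in CONDITIONS
            if (g, c) in self.cells
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cohort: str) -> "RTTrajectory":
        traj = cls(cohort=cohort)
        for _, row in df.iterrows():
            g, c = str(row["age_group"]), str(row["condition"])
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition label {c!r}")
            if g not in AGE_GROUPS:
                raise ValueError(f"unknown age group {g!r}")
            rt = float(row["median_rt_ms"])
            if not math.isnan(rt) and rt <= 0:
                raise ValueError(f"non-positive RT for {(g, c)}: {rt}")
            traj.cells[(g, c)] = rt
        traj.check_complete()
        return traj


def run_battery(
    params: NetworkParams,
    dt: float = 1.0,
    isi: float = 2000.0,
) -> dict[str, float]:
    """Six-condition test battery with frozen weights.

    Each condition runs once (the frozen network is deterministic); the
    multisensory switch RT averages the V->AV and A->AV variants.  The
    tie-break perturbation of audiovisual onsets is fixed to the
    auditory interneuron, a convention that leaves RTs unchanged under
    the A/V mirror symmetry of the battery.  Timeouts surface as NaN.
    """
    rest = rest_state(params, dt=dt)
    out: dict[str, float] = {}

    def second_rt(pair: TrialPair) -> float:
        _, rt2, _ = run_condition(params, pair, dt=dt, rest=rest)
        return math.nan if rt2 is None else rt2

    for cond in CONDITIONS:
        if cond == "AV-switch":
            variants = [
                TrialPair("V", "AV", isi, "AV-switch"),
                TrialPair("A", "AV", isi, "AV-switch"),
            ]
            out[cond] = float(np.mean([second_rt(p) for p in variants]))
        else:
            out[cond] = second_rt(make_condition_pair(cond, isi))
    return out


def run_cohort(
    spec: CohortSpec,
    seed: int | np.random.Generator = 0,
    dt: float = 1.0,
    return_checkpoints: bool = False,
):
    """Train a cohort and assemble its RT trajectory.

    The network trains over the cohort's exposure schedule; at each
    checkpoint plasticity is frozen and the test battery runs.  The
    adult row averages the batteries at epochs 1500-3000.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence(seed))
    )
    rates = LearningRates().scaled(spec.plasticity_factor)
    schedule = TrainingSchedule(
        mix_schedule=build_mix_schedule(spec),
        n_epochs=spec.n_epochs,
        rates=rates,
        checkpoints=tuple(c for c in CHECKPOINT_EPOCHS if c <= spec.n_epochs),
    )
    checkpoints = train(get_preset(spec.initial_preset), schedule, rng, dt=dt)
    batteries = {epoch: run_battery(p, dt=dt) for epoch, p in checkpoints}

    traj = RTTrajectory(cohort=spec.name)
    for group, epoch in AGE_GROUP_CHECKPOINTS.items():
        for cond, rt in batteries[epoch].items():
            traj.cells[(group, cond)] = rt
    adult_epochs = [e for e in ADULT_CHECKPOINTS if e in batteries]
    for cond in CONDITIONS:
        traj.cells[("adult", cond)] = float(
            np.mean([batteries[e][cond] for e in adult_epochs])
        )
    if return_checkpoints:
        return traj, checkpoints
    return traj


def trajectory_distance(a: RTTrajectory, b: RTTrajectory) -> float:
    """Root-mean-square RT difference over the 24 matched cells."""
    va, vb = a.values(), b.values()
    if np.isnan(va).any() or np.isnan(vb).any():
        raise ValueError("trajectory distance undefined with timeout cells")
    return float(np.sqrt(np.mean((va - vb) ** 2)))


def anova_oneway(groups: list) -> tuple[float, float, int, int]:
    """Classical fixed-effects one-way ANOVA.

    Returns (F, p, df_between, df_within).
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    n = sum(a.size for a in arrays)
    df_b, df_w = k - 1, n - k
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0.0 and ssb == 0.0:
        raise ZeroDivisionError("undefined F: no variance within or between")
    if ssw == 0.0:
        return math.inf, 0.0, df_b, df_w
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p, df_b, df_w


def compare_to_reference(
    model: RTTrajectory, reference: RTTrajectory
) -> dict:
    """Goodness-of-fit report between a simulated and a reference
    trajectory: one-way ANOVA with factor data source over the 24 cells,
    the RMS distance, and per-cell deltas."""
    F, p, df_b, df_w = anova_oneway([model.values(), reference.values()])
    deltas = {
        f"{g}|{c}": model.rt(g, c) - reference.rt(g, c)
        for g in AGE_GROUPS
        for c in CONDITIONS
    }
    return {
        "F": F,
        "p": p,
        "df_between": df_b,
        "df_within": df_w,
        "rms_distance_ms": trajectory_distance(model, reference),
        "deltas_ms": deltas,
    }
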