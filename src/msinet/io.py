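"""Run configuration, trajectory tables and synthetic reference fixtures.

The empirical developmental RT data this model is built around are
published as figures, not tables, so the package ships a generator for
*synthetic* reference tables that obey the qualitative orderings of the
behavioral findings (RTs fall with age, the unisensory switch cost grows,
multisensory gain emerges only in adults, the ASD-like table lags in the
middle age groups and converges by adulthood).  Real reference tables
can be supplied as CSV with columns (cohort, age_group, condition,
median_rt_ms).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohorts import RTTrajectory
from .plasticity import AGE_GROUPS
from .stimuli import CONDITIONS

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_trajectory",
    "read_trajectory",
    "read_reference_table",
    "make_fixture_reference",
    "check_qualitative_orderings",
    "write_trace",
]

FIXTURE_STYLES = ("TD-like", "ASD-like")


@dataclass
class RunConfig:
    """Validated configuration for a cohort run."""

    seed: int
    preset: str | None = "td_child"
    params: dict | None = None
    cohorts: list[str] = field(default_factory=lambda: ["TD"])
    dt: float = 1.0
    n_epochs: int = 3000
    out_dir: str = "results"
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for any stochastic run")
        self.seed = int(self.seed)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_epochs < 0:
            raise ValueError("n_epochs must be nonnegative")
        if self.preset is None and self.params is None:
            raise ValueError("either a preset name or inline params required")
        if self.params is not None:
            from .params import NetworkParams

            NetworkParams.from_dict(self.params)  # validates

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Short stable hash of the full configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Read and validate a YAML/JSON run configuration.

    Unknown keys are rejected by name; defaults are filled in for
    everything else.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Trajectory tables
# ---------------------------------------------------------------------------

def write_trajectory(traj: RTTrajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_trajectory(path, cohort: str | None = None) -> RTTrajectory:
    df = pd.read_csv(path)
    required = {"cohort", "age_group", "condition", "median_rt_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    if cohort is None:
        names = df["cohort"].unique()
        if len(names) != 1:
            raise ValueError(
                f"table holds cohorts {list(names)}; specify which to read"
            )
        cohort = str(names[0])
    sub = df[df["cohort"] == cohort]
    if sub.empty:
        raise ValueError(f"no rows for cohort {cohort!r}")
    return RTTrajectory.from_frame(sub, cohort)


def read_reference_table(path, cohort: str | None = None) -> RTTrajectory:
    """Load an empirical reference table (all 24 cells required)."""
    return read_trajectory(path, cohort=cohort)


# ---------------------------------------------------------------------------
# Synthetic reference fixtures
# ---------------------------------------------------------------------------

# Plausible median RTs (ms) for a simple audiovisual detection task.
_BASE_REPEAT = {
    "A": (450.0, 400.0, 350.0, 300.0),
    "V": (470.0, 420.0, 365.0, 310.0),
}
_UNI_SWITCH_COST = (12.0, 18.0, 24.0, 30.0)
_AV_GAIN = (1.0, 6.0, 15.0, 30.0)       # vs best unisensory repeat
_AV_SWITCH_DELTA = (1.0, 1.0, 2.0, 2.0)
#: ASD-like lag per age group (applied to every condition).
_ASD_LAG = (12.0, 35.0, 25.0, 2.0)


def make_fixture_reference(style: str, seed: int) -> RTTrajectory:
    """Synthetic 24-cell reference table obeying the qualitative
    developmental orderings; deterministic per seed.

    The jitter is kept small relative to the constructed effects so the
    orderings survive it.
    """
    if style not in FIXTURE_STYLES:
        raise ValueError(f"unknown fixture style {style!r}; valid: {FIXTURE_STYLES}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 91]))
    lag = _ASD_LAG if style == "ASD-like" else (0.0, 0.0, 0.0, 0.0)
    traj = RTTrajectory(cohort=style)
    jit = lambda: float(rng.uniform(-1.5, 1.5))  # noqa: E731
    for i, g in enumerate(AGE_GROUPS):
        rep = {m: _BASE_REPEAT[m][i] + lag[i] + jit() for m in ("A", "V")}
        for m in ("A", "V"):
            traj.cells[(g, f"{m}-repeat")] = rep[m]
            traj.cells[(g, f"{m}-switch")] = rep[m] + _UNI_SWITCH_COST[i] + jit()
        av = min(rep.values()) - _AV_GAIN[i] + jit() * 0.5
        traj.cells[(g, "AV-repeat")] = av
        traj.cells[(g, "AV-switch")] = av + _AV_SWITCH_DELTA[i] + jit() * 0.5
    traj.check_complete()
    return traj


def check_qualitative_orderings(
    traj: RTTrajectory, gain_tol: float = 5.0, av_cost_tol: float = 5.0
) -> list[str]:
    """Validate the developmental orderings on any 24-cell trajectory.

    Returns a list of violation messages (empty = all orderings hold):
    RTs non-increasing with age per condition; pooled unisensory switch
    cost positive and non-decreasing; no child multisensory gain beyond
    ``gain_tol`` but positive adult gain; multisensory switch cost within
    ``av_cost_tol`` at every age.
    """
    traj.check_complete()
    bad: list[str] = []
    for c in CONDITIONS:
        rts = [traj.rt(g, c) for g in AGE_GROUPS]
        if any(b > a + 1e-9 for a, b in zip(rts, rts[1:])):
            bad.append(f"{c}: RT not non-increasing with age {rts}")
    pooled = [
        0.5 * (traj.switch_cost(g, "A") + traj.switch_cost(g, "V"))
        for g in AGE_GROUPS
    ]
    if min(pooled) <= 0:
        bad.append(f"pooled unisensory switch cost not positive: {pooled}")
    if any(b < a - 1e-9 for a, b in zip(pooled, pooled[1:])):
        bad.append(f"pooled unisensory switch cost not non-decreasing: {pooled}")
    if traj.multisensory_gain(AGE_GROUPS[0]) > gain_tol:
        bad.append("youngest group shows multisensory facilitation")
    if traj.multisensory_gain("adult") <= 0:
        bad.append("adult group lacks multisensory facilitation")
    for g in AGE_GROUPS:
        av_cost = traj.switch_cost(g, "AV")
        if abs(av_cost) > av_cost_tol:
            bad.append(f"multisensory switch cost at {g} too large: {av_cost:.2f}")
    return bad


def write_trace(trace, path) -> None:
    """Export an activity trace as CSV (t_ms, firing rates, slow traces)."""
    trace.to_frame().to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
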