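"""Configuration objects for the two-step task pipeline.

The task configuration captures the experimental constants of the two-stage
sequential decision task: a fixed 70/30 transition structure, 201 trials per
session, exponentially distributed intertrial intervals with a 2-s mean, and
second-stage reward probabilities that drift as reflecting Gaussian random
walks. Group specifications describe cohorts of synthetic subjects whose
hybrid-model parameters are drawn from truncated normal distributions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

__all__ = [
    "TaskConfig",
    "GroupSpec",
    "FitConfig",
    "BmsConfig",
    "RegressorConfig",
    "PipelineConfig",
    "PARAM_NAMES",
    "PARAM_BOUNDS",
    "HIGH_IMPULSIVE",
    "LOW_IMPULSIVE",
    "practice_config",
    "load_pipeline_config",
]

#: Subject-level model parameters, in canonical order.
PARAM_NAMES = ("omega", "alpha1", "alpha2", "lam", "beta1", "beta2", "rho")

#: Legal range of each parameter on the native scale. The unit-interval
#: parameters (mixture weight and learning rates) live in [0, 1]; inverse
#: temperatures are non-negative (capped for cohort sampling only); the
#: perseveration weight is an unbounded real.
PARAM_BOUNDS: Mapping[str, tuple[float, float]] = {
    "omega": (0.0, 1.0),
    "alpha1": (0.0, 1.0),
    "alpha2": (0.0, 1.0),
    "lam": (0.0, 1.0),
    "beta1": (0.0, 20.0),
    "beta2": (0.0, 20.0),
    "rho": (-float("inf"), float("inf")),
}

#: Number of trials in the practice version of the task.
PRACTICE_N_TRIALS = 55


@dataclass(frozen=True)
class TaskConfig:
    """Constants of the two-stage task environment.

    Parameters
    ----------
    p_common
        Probability that a first-stage action leads to its common
        second-stage state. Fixed at 0.7 in the study task.
    n_trials
        Trials per session (201 in the main task).
    walk_sd
        Standard deviation of the per-trial Gaussian innovation of each
        reward-probability random walk.
    walk_bounds
        Reflecting boundaries ``(lo, hi)`` of the walks.
    walk_init
        Either ``"uniform"`` (draw the four initial reward probabilities
        uniformly within the bounds) or an explicit 4-sequence ordered as
        ``(s0a0, s0a1, s1a0, s1a1)``.
    iti_mean
        Mean of the exponential intertrial interval, seconds.
    decision_window
        Duration of each decision phase, seconds.
    stage1_display
        Time the chosen first-stage stimulus stays on screen before the
        second stage begins, seconds.
    feedback_duration
        Feedback display time, seconds.
    q_init
        Initial action value for every stage and action (midpoint of the
        reward-probability bounds by default).
    """

    p_common: float = 0.7
    n_trials: int = 201
    walk_sd: float = 0.025
    walk_bounds: tuple[float, float] = (0.25, 0.75)
    walk_init: str | tuple[float, float, float, float] = "uniform"
    iti_mean: float = 2.0
    decision_window: float = 2.0
    stage1_display: float = 1.5
    feedback_duration: float = 1.0
    q_init: float = 0.5

    def __post_init__(self) -> None:
        if not (0.5 < self.p_common <= 1.0):
            raise ValueError(f"p_common must be in (0.5, 1], got {self.p_common}")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        lo, hi = self.walk_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"walk_bounds must satisfy 0 <= lo < hi <= 1, got {self.walk_bounds}")
        if self.walk_sd < 0:
            raise ValueError("walk_sd must be non-negative")
        if self.iti_mean <= 0:
            raise ValueError("iti_mean must be positive")
        if isinstance(self.walk_init, str):
            if self.walk_init != "uniform":
                raise ValueError("walk_init must be 'uniform' or a 4-sequence")
        else:
            init = tuple(float(p) for p in self.walk_init)
            if len(init) != 4:
                raise ValueError("walk_init needs exactly 4 probabilities")
            if any(not (lo <= p <= hi) for p in init):
                raise ValueError("walk_init probabilities must lie within walk_bounds")
            object.__setattr__(self, "walk_init", init)

    @property
    def p_rare(self) -> float:
        return 1.0 - self.p_common


def practice_config(config: TaskConfig | None = None) -> TaskConfig:
    """Practice-session variant: same generator, 55 trials, fresh walks."""
    base = config or TaskConfig()
    return dataclasses.replace(base, n_trials=PRACTICE_N_TRIALS, walk_init="uniform")


@dataclass(frozen=True)
class GroupSpec:
    """Sampling distribution of subject parameters for one cohort.

    ``means`` and ``sds`` map parameter names to the mean and SD of a normal
    distribution on the native scale, truncated to the parameter's legal
    range (redrawn, not clipped, so stated means stay approximately intact).
    """

    name: str
    n_subjects: int
    means: Mapping[str, float]
    sds: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        for p in PARAM_NAMES:
            if p not in self.means or p not in self.sds:
                raise ValueError(f"GroupSpec missing parameter {p!r}")
            if self.sds[p] < 0:
                raise ValueError(f"SD for {p!r} must be >= 0")
            lo, hi = PARAM_BOUNDS[p]
            if not (lo <= self.means[p] <= hi):
                raise ValueError(f"mean for {p!r} outside legal range")


# Softmax temperatures and perseveration are set to magnitudes typical of
# fitted values on this task family; the four hybrid learning parameters
# follow the study's group-level estimates.
_SHARED_MEANS = {"beta1": 5.0, "beta2": 4.0, "rho": 0.2}
_SHARED_SDS = {"beta1": 1.5, "beta2": 1.5, "rho": 0.2}

#: High-impulsivity cohort (n=24).
HIGH_IMPULSIVE = GroupSpec(
    name="high",
    n_subjects=24,
    means={"omega": 0.6076, "alpha1": 0.5272, "alpha2": 0.5803, "lam": 0.6854, **_SHARED_MEANS},
    sds={"omega": 0.1114, "alpha1": 0.2077, "alpha2": 0.1706, "lam": 0.0756, **_SHARED_SDS},
)

#: Low-impulsivity cohort (n=26).
LOW_IMPULSIVE = GroupSpec(
    name="low",
    n_subjects=26,
    means={"omega": 0.5943, "alpha1": 0.4330, "alpha2": 0.6006, "lam": 0.6202, **_SHARED_MEANS},
    sds={"omega": 0.1080, "alpha1": 0.1928, "alpha2": 0.1328, "lam": 0.0965, **_SHARED_SDS},
)


@dataclass(frozen=True)
class FitConfig:
    """Settings for subject-level MAP fitting and evidence estimation."""

    n_restarts: int = 10
    evidence_samples: int = 2000
    em_max_iter: int = 40
    em_tol: float = 2e-3

    def __post_init__(self) -> None:
        if self.n_restarts < 1 or self.evidence_samples < 100:
            raise ValueError("n_restarts >= 1 and evidence_samples >= 100 required")


@dataclass(frozen=True)
class BmsConfig:
    """Settings for random-effects Bayesian model selection."""

    alpha0: float = 1.0
    n_mc: int = 1_000_000

    def __post_init__(self) -> None:
        if self.alpha0 <= 0 or self.n_mc < 1000:
            raise ValueError("alpha0 > 0 and n_mc >= 1000 required")


@dataclass(frozen=True)
class RegressorConfig:
    """Settings for fMRI regressor construction."""

    tr: float = 2.0
    n_scans: int = 900
    hrf: str = "spm"
    dt: float = 0.1
    time_derivative: bool = False

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.n_scans <= 0 or self.dt <= 0:
            raise ValueError("tr, n_scans and dt must be positive")
        if self.hrf not in ("spm", "glover"):
            raise ValueError("hrf must be 'spm' or 'glover'")


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level configuration tying the pipeline stages together."""

    task: TaskConfig = field(default_factory=TaskConfig)
    groups: tuple[GroupSpec, ...] = (HIGH_IMPULSIVE, LOW_IMPULSIVE)
    fit: FitConfig = field(default_factory=FitConfig)
    bms: BmsConfig = field(default_factory=BmsConfig)
    regressors: RegressorConfig = field(default_factory=RegressorConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")


def _build_section(cls, data: Mapping, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {name!r} section: {sorted(unknown)}")
    return cls(**data)


def load_pipeline_config(path: str) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file.

    Unknown keys anywhere in the file are rejected. Missing sections fall
    back to the study defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {"task", "groups", "fit", "bms", "regressors", "seed"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs: dict = {}
    if "task" in raw:
        task = dict(raw["task"])
        if "walk_bounds" in task:
            task["walk_bounds"] = tuple(task["walk_bounds"])
        if "walk_init" in task and not isinstance(task["walk_init"], str):
            task["walk_init"] = tuple(task["walk_init"])
        kwargs["task"] = _build_section(TaskConfig, task, "task")
    if "groups" in raw:
        groups = []
        for g in raw["groups"]:
            g = dict(g)
            unknown = set(g) - {"name", "n_subjects", "means", "sds"}
            if unknown:
                raise ValueError(f"unknown keys in group: {sorted(unknown)}")
            defaults = HIGH_IMPULSIVE if g.get("name") == "high" else LOW_IMPULSIVE
            means = {**dict(defaults.means), **g.get("means", {})}
            sds = {**dict(defaults.sds), **g.get("sds", {})}
            groups.append(GroupSpec(g["name"], int(g["n_subjects"]), means, sds))
        kwargs["groups"] = tuple(groups)
    for key, cls in (("fit", FitConfig), ("bms", BmsConfig), ("regressors", RegressorConfig)):
        if key in raw:
            kwargs[key] = _build_section(cls, raw[key], key)
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return PipelineConfig(**kwargs)
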