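"""Generative models of choice behavior on the two-stage task.

Three controllers are defined over a shared second-stage value table Q2:

* **model-free** — SARSA(lambda): first-stage values are updated
  retrospectively by the state prediction error at second-stage onset
  (delta1) and, scaled by the stage-skipping rate lambda, by the reward
  prediction error at feedback (delta2);
* **model-based** — first-stage values are computed prospectively each trial
  by combining the maximum second-stage values with the instructed 70/30
  transition probabilities;
* **hybrid** — a convex mixture of the two first-stage value vectors with
  weight omega on the model-based component.

Choices follow a softmax with separate inverse temperatures per stage
(beta1, beta2) and a first-stage perseveration bonus rho for repeating the
previous trial's first-stage choice.

This module is also the synthetic-cohort generator: subject parameters are
drawn from truncated normals whose means/SDs default to the study's
group-level estimates for the two impulsivity groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .config import PARAM_BOUNDS, PARAM_NAMES, GroupSpec, TaskConfig
from .task import (
    RewardWalks,
    common_state,
    init_walks,
    sample_iti,
    sample_reward,
    sample_transition,
    step_walks,
)

__all__ = [
    "ParameterSet",
    "QState",
    "PredictionErrors",
    "Session",
    "mb_values",
    "hybrid_values",
    "softmax_policy",
    "mf_update",
    "simulate_session",
    "simulate_cohort",
    "sample_parameters",
    "replay_session",
]


@dataclass(frozen=True)
class ParameterSet:
    """The seven subject-level parameters of the hybrid model.

    omega: model-based weight in [0, 1]; alpha1/alpha2: first-/second-stage
    learning rates in [0, 1]; lam: stage-skipping update rate in [0, 1];
    beta1/beta2: non-negative inverse temperatures; rho: perseveration
    weight (any real).
    """

    omega: float
    alpha1: float
    alpha2: float
    lam: float
    beta1: float
    beta2: float
    rho: float

    def __post_init__(self) -> None:
        for name in ("omega", "alpha1", "alpha2", "lam"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("inverse temperatures must be non-negative")
        if not all(np.isfinite(self.to_array())):
            raise ValueError("parameters must be finite")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ParameterSet":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))


@dataclass
class QState:
    """Learner state: first-stage model-free values, shared second-stage
    values, and the previous first-stage choice (None on the first trial)."""

    q1_mf: np.ndarray
    q2: np.ndarray
    prev_choice: int | None = None

    @classmethod
    def initial(cls, q_init: float = 0.5) -> "QState":
        return cls(q1_mf=np.full(2, q_init), q2=np.full((2, 2), q_init))

    def copy(self) -> "QState":
        return QState(self.q1_mf.copy(), self.q2.copy(), self.prev_choice)


@dataclass(frozen=True)
class PredictionErrors:
    """delta1: state PE at second-stage onset; delta2: reward PE at feedback."""

    delta1: float
    delta2: float


@dataclass
class Session:
    """One subject's trial records and event onsets.

    Trial arrays are aligned; invalid trials (no response inside the
    decision window) carry ``-1`` in the choice/state/reward slots and 0 in
    ``valid``. ``is_common[t]`` flags a common transition. Onsets are in
    seconds from scan start and strictly increase within and across trials.
    """

    a1: np.ndarray
    is_common: np.ndarray
    s2: np.ndarray
    a2: np.ndarray
    reward: np.ndarray
    valid: np.ndarray
    onset1: np.ndarray
    onset2: np.ndarray
    onset_fb: np.ndarray
    delta1: np.ndarray | None = None
    delta2: np.ndarray | None = None
    params_true: ParameterSet | None = None
    group: str | None = None
    subject: str | None = None

    def __post_init__(self) -> None:
        n = len(self.a1)
        for name in ("is_common", "s2", "a2", "reward", "valid", "onset1", "onset2", "onset_fb"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"trial array {name!r} has mismatched length")
        times = np.column_stack([self.onset1, self.onset2, self.onset_fb]).ravel()
        if np.any(np.diff(times) <= 0):
            raise ValueError("onsets must strictly increase within and across trials")

    @property
    def n_trials(self) -> int:
        return len(self.a1)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def mb_values(q2: np.ndarray, p_common: float) -> np.ndarray:
    """Prospective first-stage values from the instructed transition model.

    value(a) = p_common * max_a' Q2[common(a), a']
             + (1 - p_common) * max_a' Q2[rare(a), a'].
    """
    q2 = np.asarray(q2, dtype=float)
    if not np.all(np.isfinite(q2)):
        raise ValueError("q2 must be finite")
    best = q2.max(axis=1)
    out = np.empty(2)
    for a in (0, 1):
        c = common_state(a)
        out[a] = p_common * best[c] + (1.0 - p_common) * best[1 - c]
    return out


def hybrid_values(q1_mf: np.ndarray, q_mb: np.ndarray, omega: float) -> np.ndarray:
    """Convex mixture omega * q_mb + (1 - omega) * q1_mf, elementwise."""
    if not (0.0 <= omega <= 1.0):
        raise ValueError("omega must be in [0, 1]")
    return omega * np.asarray(q_mb, float) + (1.0 - omega) * np.asarray(q1_mf, float)


def softmax_policy(
    values: np.ndarray,
    beta: float,
    rho: float = 0.0,
    prev_choice: int | None = None,
) -> np.ndarray:
    """Two-action softmax: P(a) ∝ exp(beta * values[a] + rho * 1[a == prev]).

    The perseveration bonus applies only when ``prev_choice`` is given
    (first-stage use); on a first trial the indicator is zero for both
    actions. Overflow is guarded by max-subtraction.
    """
    values = np.asarray(values, dtype=float)
    if np.any(np.isnan(values)) or np.isnan(beta) or np.isnan(rho):
        raise ValueError("NaN input to softmax_policy")
    logits = beta * values
    if prev_choice is not None:
        bonus = np.zeros(2)
        bonus[prev_choice] = rho
        logits = logits + bonus
    logits = logits - logits.max()
    expd = np.exp(logits)
    return expd / expd.sum()


def mf_update(
    q: QState, a1: int, s2: int, a2: int, r: float, params: ParameterSet
) -> tuple[QState, PredictionErrors]:
    """SARSA(lambda) update after one complete trial.

    delta1 = Q2[s2, a2] - Q1[a1] (state PE at second-stage onset);
    delta2 = r - Q2[s2, a2] (reward PE at feedback).
    Q2[s2, a2] += alpha2 * delta2;
    Q1[a1]     += alpha1 * delta1 + alpha1 * lam * delta2.
    Unchosen entries are untouched. Returns a new state plus the PEs.
    """
    new = q.copy()
    d1 = float(q.q2[s2, a2] - q.q1_mf[a1])
    d2 = float(r - q.q2[s2, a2])
    new.q2[s2, a2] += params.alpha2 * d2
    new.q1_mf[a1] += params.alpha1 * d1 + params.alpha1 * params.lam * d2
    new.prev_choice = a1
    return new, PredictionErrors(delta1=d1, delta2=d2)


def simulate_session(
    params: ParameterSet,
    config: TaskConfig | None = None,
    seed: int | np.random.Generator = 0,
    return_walks: bool = False,
):
    """Simulate one session of a hybrid agent on the two-stage task.

    Every trial: the agent picks a first-stage action from the hybrid
    softmax policy, transitions per the 70/30 structure, picks a
    second-stage action from the Q2 softmax, collects a Bernoulli reward
    from the drifting walks, and updates its values. Prediction errors and
    event onsets are recorded. Identical seeds reproduce identical sessions.
    """
    config = config or TaskConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    walks = init_walks(config, rng)
    q = QState.initial(config.q_init)

    n = config.n_trials
    a1 = np.empty(n, dtype=np.int64)
    is_common = np.empty(n, dtype=np.int64)
    s2 = np.empty(n, dtype=np.int64)
    a2 = np.empty(n, dtype=np.int64)
    reward = np.empty(n, dtype=np.int64)
    valid = np.ones(n, dtype=np.int64)
    onset1 = np.empty(n)
    onset2 = np.empty(n)
    onset_fb = np.empty(n)
    d1s = np.empty(n)
    d2s = np.empty(n)

    t = float(sample_iti(config, rng))
    for i in range(n):
        onset1[i] = t
        p1 = softmax_policy(
            hybrid_values(q.q1_mf, mb_values(q.q2, config.p_common), params.omega),
            params.beta1,
            params.rho,
            q.prev_choice,
        )
        a = int(rng.random() < p1[1])
        state, kind = sample_transition(a, config, rng)
        onset2[i] = t = t + config.decision_window + config.stage1_display
        p2 = softmax_policy(q.q2[state], params.beta2)
        b = int(rng.random() < p2[1])
        onset_fb[i] = t = t + config.decision_window
        r = sample_reward(state, b, walks, rng)
        q, pes = mf_update(q, a, state, b, r, params)
        step_walks(walks, config, rng)
        a1[i], s2[i], a2[i], reward[i] = a, state, b, r
        is_common[i] = int(kind == "common")
        d1s[i], d2s[i] = pes.delta1, pes.delta2
        t = t + config.feedback_duration + sample_iti(config, rng)

    session = Session(
        a1=a1, is_common=is_common, s2=s2, a2=a2, reward=reward, valid=valid,
        onset1=onset1, onset2=onset2, onset_fb=onset_fb,
        delta1=d1s, delta2=d2s, params_true=params,
    )
    if return_walks:
        return session, walks
    return session


def sample_parameters(spec: GroupSpec, rng: np.random.Generator) -> ParameterSet:
    """Draw one subject's parameters from the group's truncated normals.

    Out-of-range draws are redrawn (never clipped), so the stated group
    means remain approximately intact. SD = 0 yields the mean exactly.
    """
    values = {}
    for name in PARAM_NAMES:
        mu, sd = spec.means[name], spec.sds[name]
        lo, hi = PARAM_BOUNDS[name]
        if sd == 0.0:
            values[name] = mu
            continue
        for _ in range(10_000):
            draw = rng.normal(mu, sd)
            if lo <= draw <= hi:
                values[name] = draw
                break
        else:  # pragma: no cover - pathological spec
            raise RuntimeError(f"truncated-normal sampling failed for {name!r}")
    return ParameterSet(**values)


def simulate_cohort(
    spec: GroupSpec, config: TaskConfig | None = None, seed: int = 0
) -> list[Session]:
    """Simulate a cohort: one session per subject, parameters drawn per spec.

    Subject ``i`` uses the generator seeded with ``seed + i``, so cohorts
    are reproducible under subsetting.
    """
    config = config or TaskConfig()
    sessions = []
    for i in range(spec.n_subjects):
        rng = np.random.default_rng(seed + i)
        params = sample_parameters(spec, rng)
        session = simulate_session(params, config, rng)
        session.group = spec.name
        session.subject = f"{spec.name}{i + 1:02d}"
        sessions.append(session)
    return sessions


def replay_session(
    session: Session,
    params: ParameterSet,
    config: TaskConfig | None = None,
    model: str = "hybrid",
) -> dict[str, np.ndarray]:
    """Replay observed choices under given parameters; return the latent trace.

    For each trial the *pre-update* quantities are recorded: model-free and
    model-based first-stage values, the stage-1 choice probabilities, the
    prediction errors, and the omega-derivative of the chosen-action
    probability (chain rule through the hybrid value mixture). Values update
    only on valid trials; invalid trials contribute NaNs.

    ``model`` pins the controller: "mf" fixes omega = 0; "mb" fixes
    omega = 1 with alpha1 and lam inert.
    """
    config = config or TaskConfig()
    if model == "mf":
        params = replace(params, omega=0.0)
    elif model == "mb":
        params = replace(params, omega=1.0, alpha1=0.0, lam=0.0)
    elif model != "hybrid":
        raise ValueError(f"unknown model {model!r}")

    n = session.n_trials
    out = {
        k: np.full(n, np.nan)
        for k in ("p1_chosen", "p2_chosen", "delta1", "delta2", "dp_domega")
    }
    out["q1_mf"] = np.full((n, 2), np.nan)
    out["q_mb"] = np.full((n, 2), np.nan)
    out["q2"] = np.full((n, 2, 2), np.nan)

    q = QState.initial(config.q_init)
    for t in range(n):
        if not session.valid[t]:
            continue
        a, s, b, r = (int(session.a1[t]), int(session.s2[t]),
                      int(session.a2[t]), float(session.reward[t]))
        qmb = mb_values(q.q2, config.p_common)
        out["q1_mf"][t] = q.q1_mf
        out["q_mb"][t] = qmb
        out["q2"][t] = q.q2
        p1 = softmax_policy(
            hybrid_values(q.q1_mf, qmb, params.omega), params.beta1, params.rho, q.prev_choice
        )
        p2 = softmax_policy(q.q2[s], params.beta2)
        out["p1_chosen"][t] = p1[a]
        out["p2_chosen"][t] = p2[b]
        diff = qmb - q.q1_mf
        out["dp_domega"][t] = p1[a] * (1.0 - p1[a]) * params.beta1 * (diff[a] - diff[1 - a])
        q, pes = mf_update(q, a, s, b, r, params)
        out["delta1"][t] = pes.delta1
        out["delta2"][t] = pes.delta2
    return out
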