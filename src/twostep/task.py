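"""Generative environment for the two-stage task.

Two first-stage actions lead probabilistically to one of two second-stage
states: action ``a`` reaches state ``a`` with probability ``p_common`` (its
*common* state) and the other state otherwise (*rare*). Each of the four
second-stage options pays a unit reward with a probability that drifts from
trial to trial as an independent Gaussian random walk reflecting at fixed
bounds, so reward contingencies must be tracked continuously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TaskConfig

__all__ = [
    "RewardWalks",
    "init_walks",
    "step_walks",
    "sample_transition",
    "sample_reward",
    "sample_iti",
    "common_state",
    "walk_history_frame",
]


def common_state(a1: int) -> int:
    """Second-stage state commonly reached by first-stage action ``a1``.

    The mapping is the identity bijection: action 0 -> state 0, action
    1 -> state 1 (which physical pair is 'state 0' is a labeling choice).
    """
    if a1 not in (0, 1):
        raise ValueError(f"first-stage action must be 0 or 1, got {a1}")
    return a1


@dataclass
class RewardWalks:
    """Reward probabilities of the four second-stage options.

    ``probs[s, a]`` is the current probability that choosing action ``a`` in
    second-stage state ``s`` is rewarded. ``history`` accumulates one 2x2
    snapshot per completed update.
    """

    probs: np.ndarray
    bounds: tuple[float, float]
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (2, 2):
            raise ValueError("probs must be a 2x2 matrix")
        self._check()

    def _check(self) -> None:
        if not np.all(np.isfinite(self.probs)):
            raise FloatingPointError("non-finite reward probability")
        lo, hi = self.bounds
        if np.any(self.probs < lo) or np.any(self.probs > hi):
            raise ValueError("reward probability outside walk bounds")


def init_walks(config: TaskConfig, rng: np.random.Generator) -> RewardWalks:
    """Create walks at their initial probabilities (explicit or uniform)."""
    lo, hi = config.walk_bounds
    if config.walk_init == "uniform":
        probs = rng.uniform(lo, hi, size=(2, 2))
    else:
        probs = np.asarray(config.walk_init, dtype=float).reshape(2, 2)
    return RewardWalks(probs=probs, bounds=config.walk_bounds)


def _reflect(x: float, lo: float, hi: float) -> float:
    # Fold back into [lo, hi]; a loop handles (unlikely) multi-bounces.
    while x < lo or x > hi:
        if x > hi:
            x = 2.0 * hi - x
        if x < lo:
            x = 2.0 * lo - x
    return x


def step_walks(walks: RewardWalks, config: TaskConfig, rng: np.random.Generator) -> RewardWalks:
    """Advance every walk by one Gaussian innovation, reflecting at bounds.

    Each of the four probabilities receives an independent N(0, walk_sd^2)
    perturbation; excursions beyond a bound are reflected back (a value at
    the upper bound ``hi`` pushed up by ``d`` lands at ``hi - d``), which
    keeps the stationary distribution from piling up at the bounds. The
    updated snapshot is appended to the history. Mutates and returns
    ``walks``.
    """
    lo, hi = walks.bounds
    noise = rng.normal(0.0, config.walk_sd, size=(2, 2))
    if not np.all(np.isfinite(noise)):
        raise FloatingPointError("non-finite walk innovation")
    for s in range(2):
        for a in range(2):
            walks.probs[s, a] = _reflect(walks.probs[s, a] + noise[s, a], lo, hi)
    walks._check()
    walks.history.append(walks.probs.copy())
    return walks


def sample_transition(
    a1: int, config: TaskConfig, rng: np.random.Generator
) -> tuple[int, str]:
    """Draw the second-stage state for first-stage action ``a1``.

    Returns ``(state2, kind)`` where ``kind`` is ``"common"`` with
    probability ``p_common`` and ``"rare"`` otherwise.
    """
    c = common_state(a1)
    if rng.random() < config.p_common:
        return c, "common"
    return 1 - c, "rare"


def sample_reward(state2: int, a2: int, walks: RewardWalks, rng: np.random.Generator) -> int:
    """Bernoulli reward with probability ``walks.probs[state2, a2]``."""
    if state2 not in (0, 1) or a2 not in (0, 1):
        raise ValueError("state2 and a2 must be 0 or 1")
    return int(rng.random() < walks.probs[state2, a2])


def sample_iti(config: TaskConfig, rng: np.random.Generator) -> float:
    """Exponential intertrial interval with mean ``iti_mean`` seconds."""
    return float(rng.exponential(config.iti_mean))


def walk_history_frame(walks: RewardWalks) -> pd.DataFrame:
    """Walk history as a table: trial (1-based), p_s0a0 ... p_s1a1."""
    hist = np.asarray(walks.history, dtype=float).reshape(-1, 4)
    frame = pd.DataFrame(hist, columns=["p_s0a0", "p_s0a1", "p_s1a0", "p_s1a1"])
    frame.insert(0, "trial", np.arange(1, len(frame) + 1))
    return frame
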