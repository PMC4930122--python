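"""Behavioral raw-data analysis: stay probabilities and group statistics.

First-stage stay/switch behavior is summarized per subject as a 2x2 table
of stay probabilities conditioned on the previous trial's reward
(rewarded/unrewarded) and transition (common/rare). A main effect of reward
indexes model-free control; the reward x transition interaction indexes
model-based control. Group-level inference uses a 2x2 mixed-design ANOVA
implemented through subject-level contrasts (exact for two-level factors),
between-group t-tests, and a one-way MANOVA (Roy's largest root) over the
four hybrid-model learning parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .agents import Session

__all__ = [
    "StayTable",
    "GroupStats",
    "stay_table",
    "reward_main_effect",
    "mb_interaction",
    "mixed_anova_2x2",
    "manova_roy",
    "group_ttest",
]


@dataclass(frozen=True)
class StayTable:
    """Per-subject stay probabilities by previous reward x transition.

    ``probs[r, s]`` is the probability of repeating the previous first-stage
    choice when the previous trial had reward ``r`` (0 = unrewarded,
    1 = rewarded) and transition ``s`` (0 = common, 1 = rare); ``counts``
    holds the number of consecutive valid trial pairs per cell. Cells with
    no observations are NaN and flagged by :attr:`complete`.
    """

    probs: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))
        if self.probs.shape != (2, 2) or self.counts.shape != (2, 2):
            raise ValueError("probs and counts must be 2x2")

    @property
    def complete(self) -> bool:
        return bool(np.all(self.counts > 0))

    def cell(self, rewarded: bool, common: bool) -> float:
        return float(self.probs[int(rewarded), 0 if common else 1])


@dataclass(frozen=True)
class GroupStats:
    """One test statistic: F (with df) and p, plus the underlying t or
    Roy's root where applicable."""

    effect: str
    F: float
    df1: int
    df2: int
    p: float
    t: float | None = None
    roy_root: float | None = None


def stay_table(session: Session) -> StayTable:
    """Tabulate first-stage stays by the previous trial's reward x transition.

    For every consecutive pair of valid trials (t-1, t), a stay is recorded
    when the first-stage choice repeats, binned by reward and transition of
    trial t-1. The first trial contributes nothing (no predecessor).
    """
    stays = np.zeros((2, 2))
    counts = np.zeros((2, 2), dtype=int)
    for t in range(1, session.n_trials):
        if not (session.valid[t - 1] and session.valid[t]):
            continue
        r = int(session.reward[t - 1])
        s = 0 if session.is_common[t - 1] else 1
        counts[r, s] += 1
        stays[r, s] += int(session.a1[t] == session.a1[t - 1])
    if counts.sum() == 0:
        raise ValueError("need at least two consecutive valid trials")
    with np.errstate(invalid="ignore"):
        probs = np.where(counts > 0, stays / np.maximum(counts, 1), np.nan)
    return StayTable(probs=probs, counts=counts)


def _require_complete(table: StayTable) -> None:
    if not table.complete:
        raise ValueError("stay table has an empty cell; effect undefined")


def reward_main_effect(table: StayTable) -> float:
    """Mean stay probability after rewards minus after non-rewards."""
    _require_complete(table)
    return float(table.probs[1].mean() - table.probs[0].mean())


def mb_interaction(table: StayTable) -> float:
    """Reward x transition interaction of stay probabilities:
    (rewarded common - rewarded rare) - (unrewarded common - unrewarded rare)."""
    _require_complete(table)
    p = table.probs
    return float((p[1, 0] - p[1, 1]) - (p[0, 0] - p[0, 1]))


def _subject_contrasts(tables: list[StayTable]) -> np.ndarray:
    """Rows: overall mean, reward contrast, state contrast, interaction."""
    out = np.empty((len(tables), 4))
    for i, tb in enumerate(tables):
        p = tb.probs
        out[i] = (
            p.mean(),
            p[1].mean() - p[0].mean(),
            p[:, 0].mean() - p[:, 1].mean(),
            (p[1, 0] - p[1, 1]) - (p[0, 0] - p[0, 1]),
        )
    return out


def _two_group_indices(group: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    labels = tuple(sorted(set(group)))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    g1 = np.asarray(group) == labels[0]
    g2 = np.asarray(group) == labels[1]
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("each group needs at least two subjects")
    return g1, g2, labels


def mixed_anova_2x2(
    tables: list[StayTable], group: list[str] | np.ndarray
) -> list[GroupStats]:
    """2 (reward) x 2 (transition) x group mixed-design ANOVA on stay tables.

    Because every within-subject factor has exactly two levels, each effect
    reduces exactly to a t-test on a subject-level contrast (so no
    sphericity machinery is needed): within effects test the unweighted
    grand mean of the contrast against zero with the pooled within-group
    error; effect x group terms are two-sample t-tests on the contrast; the
    group main effect is a two-sample t-test on subjects' overall mean stay
    probability. Each F is the square of its t with df (1, N - 2).

    Subjects with an empty stay-table cell are dropped with a warning.
    """
    group = np.asarray(group)
    if len(tables) != len(group):
        raise ValueError("tables and group labels must align")
    keep = np.array([tb.complete for tb in tables])
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} subject(s) with empty stay-table cells",
            RuntimeWarning,
        )
    tables = [tb for tb, k in zip(tables, keep) if k]
    group = group[keep]
    C = _subject_contrasts(tables)
    g1, g2, labels = _two_group_indices(group)
    n1, n2 = int(g1.sum()), int(g2.sum())
    df2 = n1 + n2 - 2

    def pooled_var(values: np.ndarray) -> float:
        v1 = values[g1].var(ddof=1)
        v2 = values[g2].var(ddof=1)
        return ((n1 - 1) * v1 + (n2 - 1) * v2) / df2

    results = []
    within_names = {1: "reward", 2: "state", 3: "reward_x_state"}
    for col, name in within_names.items():
        c = C[:, col]
        s2p = pooled_var(c)
        # within main effect: unweighted grand mean vs 0, pooled error
        grand = 0.5 * (c[g1].mean() + c[g2].mean())
        se = np.sqrt(s2p * (1.0 / n1 + 1.0 / n2)) / 2.0
        t = grand / se if se > 0 else 0.0
        results.append(_t_to_stats(name, t, df2))
        # effect x group
        diff = c[g1].mean() - c[g2].mean()
        se_b = np.sqrt(s2p * (1.0 / n1 + 1.0 / n2))
        tb = diff / se_b if se_b > 0 else 0.0
        results.append(_t_to_stats(f"{name}_x_group", tb, df2))
    # group main effect on overall stay level
    m = C[:, 0]
    s2p = pooled_var(m)
    se_g = np.sqrt(s2p * (1.0 / n1 + 1.0 / n2))
    tg = (m[g1].mean() - m[g2].mean()) / se_g if se_g > 0 else 0.0
    results.append(_t_to_stats("group", tg, df2))
    return results


def _t_to_stats(effect: str, t: float, df2: int) -> GroupStats:
    F = float(t) ** 2
    p = float(stats.f.sf(F, 1, df2))
    return GroupStats(effect=effect, F=F, df1=1, df2=df2, p=p, t=float(t))


def manova_roy(
    param_matrix: np.ndarray, group: list[str] | np.ndarray
) -> GroupStats:
    """One-way two-group MANOVA summarized by Roy's largest root.

    Roy's root is the largest eigenvalue of ``W^{-1} B`` (within- and
    between-group scatter). With two groups this is equivalent to
    Hotelling's T^2, so the F transform ``F = root * (N - p - 1) / p`` with
    df (p, N - p - 1) is exact.
    """
    X = np.asarray(param_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("param_matrix must be 2-D (subjects x variables)")
    group = np.asarray(group)
    g1, g2, labels = _two_group_indices(group)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("need more subjects than variables + groups")
    grand = X.mean(axis=0)
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    for mask in (g1, g2):
        Xi = X[mask]
        mi = Xi.mean(axis=0)
        d = (mi - grand)[:, None]
        B += mask.sum() * (d @ d.T)
        R = Xi - mi
        W += R.T @ R
    try:
        eigvals = np.linalg.eigvals(np.linalg.solve(W, B))
    except np.linalg.LinAlgError as err:
        raise ValueError("within-group scatter matrix is singular") from err
    root = float(np.max(eigvals.real))
    df1 = p
    df2 = n - p - 1  # two groups: N - g - p + 1 with g = 2
    F = root * df2 / df1
    return GroupStats(
        effect="group_manova",
        F=float(F),
        df1=df1,
        df2=df2,
        p=float(stats.f.sf(F, df1, df2)),
        roy_root=root,
    )


def group_ttest(
    values: np.ndarray,
    group: list[str] | np.ndarray,
    tail: str = "two-sided",
    order: tuple[str, str] | None = None,
    pooled: bool = True,
) -> GroupStats:
    """Two-sample t-test between groups (pooled variance by default).

    ``tail`` is ``"two-sided"``, ``"greater"`` or ``"less"``, with the sign
    convention mean(order[0]) - mean(order[1]); ``order`` defaults to the
    sorted group labels. If both groups have zero variance and equal means
    the test is degenerate and returns t = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    g1, g2, labels = _two_group_indices(group)
    if order is not None:
        if set(order) != set(labels):
            raise ValueError("order must name the two group labels")
        if order[0] != labels[0]:
            g1, g2 = g2, g1
    x, y = values[g1], values[g2]
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        df = len(x) + len(y) - 2
        return GroupStats("group_ttest", 0.0, 1, df, 1.0, t=0.0)
    res = stats.ttest_ind(x, y, equal_var=pooled, alternative=tail)
    df = len(x) + len(y) - 2 if pooled else int(np.floor(res.df))
    return GroupStats(
        effect="group_ttest",
        F=float(res.statistic) ** 2,
        df1=1,
        df2=df,
        p=float(res.pvalue),
        t=float(res.statistic),
    )
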