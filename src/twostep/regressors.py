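"""Model-derived fMRI parametric regressors (no voxel data involved).

The analysis focuses on the two within-trial time points at which
prediction errors arise: second-stage onset (state prediction error
delta1 = Q2[s2, a2] - Q1_MF[a1]) and feedback (reward prediction error
delta2 = r - Q2[s2, a2]). Those events carry two parametric modulators:
the model-free prediction error and the model-based-minus-model-free value
difference (the partial derivative of the hybrid value with respect to the
weight omega), which is exactly zero at feedback because the two algorithms
share second-stage values. First-stage onsets carry the softmax probability
of the chosen action and its partial derivative with respect to omega. All
modulators use the trial's *pre-update* values; the difference regressor is
mean-centered within subject; streams are convolved with a canonical
double-gamma HRF and sampled at the scan times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from nilearn.glm.first_level import hemodynamic_models as _hrf

from .agents import ParameterSet, Session, replay_session
from .config import RegressorConfig, TaskConfig

__all__ = [
    "RegressorSet",
    "build_pe_modulators",
    "build_choice_modulators",
    "mean_center",
    "build_events",
    "convolve_design",
    "build_regressor_set",
    "hrf_kernel",
]


@dataclass
class RegressorSet:
    """Events table plus the convolved design matrix sampled at scan times."""

    events: pd.DataFrame
    design: pd.DataFrame
    tr: float

    @property
    def n_scans(self) -> int:
        return len(self.design)


def mean_center(values: np.ndarray) -> np.ndarray:
    """Subtract the within-subject mean."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot mean-center an empty sequence")
    return values - values.mean()


def build_pe_modulators(
    session: Session,
    params: ParameterSet,
    config: TaskConfig | None = None,
) -> pd.DataFrame:
    """Prediction-error events at second-stage and feedback onsets.

    Per valid trial, two rows: at ``onset2`` the model-free PE is delta1 and
    the difference modulator is ``Q_MB[a1] - Q_MF[a1]`` (pre-update values);
    at ``onset_fb`` the model-free PE is delta2 and the difference modulator
    is exactly 0. Invalid trials emit no modulated events here (they are
    modeled separately).
    """
    config = config or TaskConfig()
    trace = replay_session(session, params, config)
    rows = []
    for t in range(session.n_trials):
        if not session.valid[t]:
            continue
        a = int(session.a1[t])
        diff = float(trace["q_mb"][t, a] - trace["q1_mf"][t, a])
        rows.append((float(session.onset2[t]), float(trace["delta1"][t]), diff))
        rows.append((float(session.onset_fb[t]), float(trace["delta2"][t]), 0.0))
    return pd.DataFrame(rows, columns=["onset", "mf_pe", "mbmf_diff"])


def build_choice_modulators(
    session: Session,
    params: ParameterSet,
    config: TaskConfig | None = None,
) -> pd.DataFrame:
    """Choice-probability modulators at first-stage onsets.

    ``p_choice`` is the softmax probability of the chosen first-stage
    action; ``dp_domega`` its partial derivative with respect to omega via
    the chain rule, p(1-p) * beta1 * [(Q_MB - Q_MF) chosen - unchosen].
    """
    config = config or TaskConfig()
    trace = replay_session(session, params, config)
    keep = session.valid.astype(bool)
    return pd.DataFrame(
        {
            "onset": session.onset1[keep].astype(float),
            "p_choice": trace["p1_chosen"][keep],
            "dp_domega": trace["dp_domega"][keep],
        }
    )


def build_events(
    session: Session,
    params: ParameterSet,
    config: TaskConfig | None = None,
) -> pd.DataFrame:
    """BIDS-style events table for one subject.

    ``trial_type`` values: ``stage1`` (modulators p_choice, dp_domega),
    ``pe`` (the combined second-stage + feedback prediction-error events,
    modulators mf_pe and mbmf_diff), ``feedback`` (unmodulated separate
    event, absorbing mean activity at reward delivery) and ``invalid`` for
    trials without a response. The difference modulator is mean-centered
    within the subject; the zero value it takes at feedback events is part
    of the stream being centered.
    """
    config = config or TaskConfig()
    pe = build_pe_modulators(session, params, config)
    choice = build_choice_modulators(session, params, config)
    frames = []
    frames.append(
        pd.DataFrame(
            {
                "onset": choice["onset"],
                "duration": 0.0,
                "trial_type": "stage1",
                "p_choice": choice["p_choice"],
                "dp_domega": choice["dp_domega"],
            }
        )
    )
    frames.append(
        pd.DataFrame(
            {
                "onset": pe["onset"],
                "duration": 0.0,
                "trial_type": "pe",
                "mf_pe": pe["mf_pe"],
                "mbmf_diff": mean_center(pe["mbmf_diff"].to_numpy()),
            }
        )
    )
    valid = session.valid.astype(bool)
    frames.append(
        pd.DataFrame(
            {
                "onset": session.onset_fb[valid].astype(float),
                "duration": 0.0,
                "trial_type": "feedback",
            }
        )
    )
    if (~valid).any():
        frames.append(
            pd.DataFrame(
                {
                    "onset": session.onset1[~valid].astype(float),
                    "duration": 0.0,
                    "trial_type": "invalid",
                }
            )
        )
    events = pd.concat(frames, ignore_index=True).sort_values("onset", kind="stable")
    return events.reset_index(drop=True)


def hrf_kernel(kind: str = "spm", dt: float = 0.1, derivative: bool = False) -> np.ndarray:
    """Canonical double-gamma HRF (and optionally its temporal derivative)
    sampled every ``dt`` seconds."""
    if kind == "spm":
        k = _hrf.spm_hrf(dt, oversampling=1)
        d = _hrf.spm_time_derivative(dt, oversampling=1)
    elif kind == "glover":
        k = _hrf.glover_hrf(dt, oversampling=1)
        d = _hrf.glover_time_derivative(dt, oversampling=1)
    else:
        raise ValueError(f"unknown hrf kind {kind!r}")
    return np.column_stack([k, d]) if derivative else np.asarray(k)


_MODULATOR_COLS = ("p_choice", "dp_domega", "mf_pe", "mbmf_diff")


def convolve_design(
    events: pd.DataFrame,
    config: RegressorConfig,
) -> pd.DataFrame:
    """Convolve event streams with the HRF and sample at scan times.

    Each ``trial_type`` contributes one unit-impulse regressor plus one
    regressor per available modulator column (impulse heights equal the
    modulator values; no orthogonalization beyond the mean-centering applied
    when events were built). Events at or beyond the scan window are dropped
    with a warning. Columns follow ``<trial_type>`` and
    ``<trial_type>_x_<modulator>`` naming, with ``_dt`` suffixes for the
    optional temporal-derivative regressors.
    """
    total = config.n_scans * config.tr
    dt = config.dt
    n_fine = int(np.ceil(total / dt)) + 1
    kernel = hrf_kernel(config.hrf, dt, derivative=config.time_derivative)
    if kernel.ndim == 1:
        kernel = kernel[:, None]

    late = events["onset"] >= total
    if late.any():
        warnings.warn(
            f"dropping {int(late.sum())} event(s) beyond the scan window",
            RuntimeWarning,
        )
        events = events[~late]

    scan_idx = np.round(np.arange(config.n_scans) * config.tr / dt).astype(int)
    columns: dict[str, np.ndarray] = {}
    for ttype, sub in events.groupby("trial_type", sort=True):
        idx = np.round(sub["onset"].to_numpy() / dt).astype(int)
        streams = {ttype: np.ones(len(sub))}
        for col in _MODULATOR_COLS:
            if col in sub.columns and sub[col].notna().all():
                streams[f"{ttype}_x_{col}"] = sub[col].to_numpy(dtype=float)
        for name, heights in streams.items():
            fine = np.zeros(n_fine)
            np.add.at(fine, idx, heights)
            for k in range(kernel.shape[1]):
                conv = np.convolve(fine, kernel[:, k])[:n_fine]
                cname = name if k == 0 else f"{name}_dt"
                columns[cname] = conv[scan_idx]
    design = pd.DataFrame(columns)
    design.insert(0, "time_s", np.arange(config.n_scans) * config.tr)
    return design


def build_regressor_set(
    session: Session,
    params: ParameterSet,
    reg_config: RegressorConfig | None = None,
    task_config: TaskConfig | None = None,
) -> RegressorSet:
    """Events plus convolved design for one fitted session.

    Pure function of its inputs: identical (session, params, config) yield
    bit-identical outputs.
    """
    reg_config = reg_config or RegressorConfig()
    events = build_events(session, params, task_config)
    design = convolve_design(events, reg_config)
    return RegressorSet(events=events, design=design, tr=reg_config.tr)
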