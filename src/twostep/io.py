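"""Tab-separated interchange formats for the pipeline stages.

Sessions, walk histories, fit results and evidence matrices travel as TSV
(UTF-8, header row); reports are JSON. Trial indices are 1-based in files,
0-based in memory. Session round-trips are lossless.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import ParameterSet, Session
from .bms import BMSResult, EvidenceMatrix
from .config import PARAM_NAMES
from .fit import FitResult

__all__ = [
    "session_to_frame",
    "frame_to_session",
    "write_session_tsv",
    "read_session_tsv",
    "write_fit_results_tsv",
    "read_evidence_tsv",
    "write_evidence_tsv",
    "bms_report",
    "write_manifest",
]

_SESSION_COLS = [
    "trial", "choice1", "transition", "state2", "choice2", "reward",
    "valid", "onset1_s", "onset2_s", "onset_fb_s",
]


def session_to_frame(session: Session) -> pd.DataFrame:
    """Session as a tidy table (trial 1-based, transition common/rare).

    Invalid trials carry empty choice/state/reward fields.
    """
    n = session.n_trials
    valid = session.valid.astype(bool)

    def masked(values) -> list:
        return [int(v) if ok else "" for v, ok in zip(values, valid)]

    return pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "choice1": masked(session.a1),
            "transition": [
                ("common" if c else "rare") if ok else ""
                for c, ok in zip(session.is_common, valid)
            ],
            "state2": masked(session.s2),
            "choice2": masked(session.a2),
            "reward": masked(session.reward),
            "valid": session.valid.astype(int),
            "onset1_s": session.onset1,
            "onset2_s": session.onset2,
            "onset_fb_s": session.onset_fb,
        }
    )


def frame_to_session(frame: pd.DataFrame, **meta) -> Session:
    """Rebuild a Session from its tidy table."""
    missing = [c for c in _SESSION_COLS if c not in frame.columns]
    if missing:
        raise ValueError(f"session table missing columns {missing}")
    n = len(frame)
    valid = frame["valid"].to_numpy(dtype=np.int64)

    def col(name: str) -> np.ndarray:
        raw = frame[name].to_numpy()
        out = np.full(n, -1, dtype=np.int64)
        for i, (v, ok) in enumerate(zip(raw, valid)):
            if ok:
                out[i] = int(v)
        return out

    trans_raw = frame["transition"].to_numpy()
    is_common = np.array(
        [1 if (ok and str(v) == "common") else 0 for v, ok in zip(trans_raw, valid)],
        dtype=np.int64,
    )
    return Session(
        a1=col("choice1"),
        is_common=is_common,
        s2=col("state2"),
        a2=col("choice2"),
        reward=col("reward"),
        valid=valid,
        onset1=frame["onset1_s"].to_numpy(dtype=float),
        onset2=frame["onset2_s"].to_numpy(dtype=float),
        onset_fb=frame["onset_fb_s"].to_numpy(dtype=float),
        **meta,
    )


def write_session_tsv(session: Session, path: str | Path) -> None:
    session_to_frame(session).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_session_tsv(path: str | Path, **meta) -> Session:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    return frame_to_session(frame, **meta)


def write_fit_results_tsv(
    fits: dict[str, list[FitResult]],
    subjects: list[str],
    evidences: dict[str, list[tuple[float, float]]],
    path: str | Path,
) -> pd.DataFrame:
    """Long table: one row per subject x model with MAP parameters,
    negative log-likelihood and sampled log evidence."""
    rows = []
    for model, model_fits in fits.items():
        for subject, fit, (lev, se) in zip(subjects, model_fits, evidences[model]):
            row = {"subject": subject, "model": model}
            row.update({n: getattr(fit.map_params, n) for n in PARAM_NAMES})
            row.update({"nll": fit.nll, "log_evidence": lev, "evidence_se": se})
            rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return frame


def write_evidence_tsv(ev: EvidenceMatrix, subjects: list[str], path: str | Path) -> None:
    frame = pd.DataFrame(ev.log_evidence, columns=list(ev.models))
    frame.insert(0, "subject", subjects)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_evidence_tsv(path: str | Path) -> tuple[EvidenceMatrix, list[str]]:
    frame = pd.read_csv(path, sep="\t")
    subjects = frame["subject"].astype(str).tolist()
    models = tuple(c for c in frame.columns if c != "subject")
    return EvidenceMatrix(frame[list(models)].to_numpy(dtype=float), models), subjects


def bms_report(result: BMSResult) -> dict:
    return {
        "models": list(result.models),
        "alpha": [float(a) for a in result.alpha],
        "expected_freq": [float(f) for f in result.expected_freq],
        "exceedance": [float(x) for x in result.exceedance],
        "best": result.best,
        "n_iter": result.n_iter,
    }


def write_manifest(path: str | Path, config_repr: str, seed: int) -> dict:
    """Record what is needed to reproduce a run bit-for-bit."""
    from . import __version__

    manifest = {
        "config_sha256": hashlib.sha256(config_repr.encode()).hexdigest(),
        "seed": int(seed),
        "package_version": __version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return manifest
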