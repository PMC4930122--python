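"""Stage drivers tying the modules into a reproducible pipeline.

Each ``cmd_*`` function implements one pipeline verb (simulate, fit,
select, stats, regressors, recover) over a :class:`PipelineConfig`; the
command-line interface and the numbered analysis scripts are thin wrappers
around these. Every run writes a manifest (config hash, seed, package
version) sufficient to reproduce its outputs bit-for-bit. Per-subject seeds
derive deterministically from the global seed (seed + global subject
index), so cohorts are reproducible under subsetting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .agents import ParameterSet, Session, simulate_cohort
from .bms import EvidenceMatrix, rfx_bms
from .config import PARAM_NAMES, PipelineConfig
from .fit import FitResult, fit_empirical_prior, model_evidence
from .io import (
    bms_report,
    read_session_tsv,
    write_evidence_tsv,
    write_fit_results_tsv,
    write_manifest,
    write_session_tsv,
)
from .regressors import build_regressor_set
from .stay_stats import group_ttest, mixed_anova_2x2, reward_main_effect, stay_table

logger = logging.getLogger("twostep")

__all__ = [
    "cmd_simulate",
    "cmd_fit",
    "cmd_select",
    "cmd_stats",
    "cmd_regressors",
    "cmd_recover",
    "load_sessions",
]

# Seed offsets decorrelating pipeline stages that share the global seed.
_EVIDENCE_OFFSET = 104_729
_REPLICATE_STRIDE = 50_021


def _config_repr(config: PipelineConfig) -> str:
    return json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)


def simulate_groups(config: PipelineConfig, seed: int | None = None) -> list[Session]:
    """All groups' sessions, subject seeds = seed + global subject index."""
    seed = config.seed if seed is None else seed
    sessions: list[Session] = []
    offset = 0
    for spec in config.groups:
        sessions.extend(simulate_cohort(spec, config.task, seed + offset))
        offset += spec.n_subjects
    return sessions


def cmd_simulate(config: PipelineConfig, outdir: str | Path) -> list[Path]:
    """Write one session TSV per synthetic subject plus the ground-truth
    parameter manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sessions = simulate_groups(config)
    paths = []
    truth_rows = []
    for session in sessions:
        path = outdir / f"sub-{session.subject}_task-twostep_beh.tsv"
        write_session_tsv(session, path)
        paths.append(path)
        row = {"subject": session.subject, "group": session.group}
        row.update({n: getattr(session.params_true, n) for n in PARAM_NAMES})
        truth_rows.append(row)
    pd.DataFrame(truth_rows).to_csv(
        outdir / "params_true.tsv", sep="\t", index=False, float_format="%.6f"
    )
    write_manifest(outdir / "manifest.json", _config_repr(config), config.seed)
    logger.info("simulated %d subjects into %s (seed %d)", len(paths), outdir, config.seed)
    return paths


def load_sessions(indir: str | Path) -> list[Session]:
    """Read every session TSV in a simulate output directory."""
    indir = Path(indir)
    paths = sorted(indir.glob("sub-*_task-twostep_beh.tsv"))
    if not paths:
        raise FileNotFoundError(f"no session TSVs found in {indir}")
    truth_path = indir / "params_true.tsv"
    groups: dict = {}
    truths: dict = {}
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        groups = dict(zip(truth["subject"], truth["group"]))
        for _, row in truth.iterrows():
            truths[row["subject"]] = ParameterSet(
                **{n: float(row[n]) for n in PARAM_NAMES}
            )
    sessions = []
    for path in paths:
        subject = path.name.split("_")[0].removeprefix("sub-")
        sessions.append(
            read_session_tsv(
                path,
                subject=subject,
                group=groups.get(subject),
                params_true=truths.get(subject),
            )
        )
    return sessions


def fit_all_models(
    config: PipelineConfig,
    sessions: list[Session],
    models: tuple[str, ...] = ("mf", "mb", "hybrid"),
    seed: int | None = None,
):
    """Hierarchical fit + evidence for each model over all sessions.

    Returns ``(fits, evidences, priors)`` keyed by model; evidence for
    subject j uses its own fixed derived seed, so results do not depend on
    the order in which models are fitted.
    """
    seed = config.seed if seed is None else seed
    fits: dict[str, list[FitResult]] = {}
    evidences: dict[str, list[tuple[float, float]]] = {}
    priors = {}
    for m, model in enumerate(models):
        prior, model_fits, converged = fit_empirical_prior(
            sessions,
            model,
            max_iter=config.fit.em_max_iter,
            tol=config.fit.em_tol,
            n_restarts=config.fit.n_restarts,
            seed=seed + m,
            config=config.task,
        )
        if not converged:
            logger.warning("empirical-prior EM flagged non-convergence for %s", model)
        fits[model] = model_fits
        priors[model] = prior
        evidences[model] = [
            model_evidence(
                session,
                prior,
                model,
                n_samples=config.fit.evidence_samples,
                seed=seed + _EVIDENCE_OFFSET + 7 * j + m,
                config=config.task,
            )
            for j, session in enumerate(sessions)
        ]
    return fits, evidences, priors


def cmd_fit(
    config: PipelineConfig,
    indir: str | Path,
    outdir: str | Path,
    models: tuple[str, ...] = ("mf", "mb", "hybrid"),
) -> pd.DataFrame:
    """Fit every model to every subject; write fit and evidence tables."""
    sessions = load_sessions(indir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects = [s.subject for s in sessions]
    fits, evidences, priors = fit_all_models(config, sessions, models)
    frame = write_fit_results_tsv(fits, subjects, evidences, outdir / "fits.tsv")
    lev = np.column_stack([[e[0] for e in evidences[m]] for m in models])
    write_evidence_tsv(EvidenceMatrix(lev, tuple(models)), subjects, outdir / "evidence.tsv")
    prior_dump = {
        m: {"mean": priors[m].mean.tolist(), "var": priors[m].var.tolist()}
        for m in models
    }
    (outdir / "priors.json").write_text(json.dumps(prior_dump, indent=2) + "\n")
    write_manifest(outdir / "manifest.json", _config_repr(config), config.seed)
    return frame


def cmd_select(
    config: PipelineConfig,
    ev: EvidenceMatrix,
    subjects: list[str] | None = None,
    groups: list[str] | None = None,
    out: str | Path | None = None,
) -> dict:
    """Random-effects model selection, overall and per group if labeled."""
    report = {
        "all": bms_report(
            rfx_bms(ev, config.bms.alpha0, config.bms.n_mc, seed=config.seed)
        )
    }
    if groups is not None:
        for label in sorted(set(groups)):
            mask = np.asarray(groups) == label
            sub_ev = EvidenceMatrix(ev.log_evidence[mask], ev.models)
            report[label] = bms_report(
                rfx_bms(sub_ev, config.bms.alpha0, config.bms.n_mc, seed=config.seed)
            )
    if out is not None:
        Path(out).write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")
    return report


def cmd_stats(
    config: PipelineConfig,
    sessions: list[Session],
    out: str | Path | None = None,
) -> dict:
    """Stay-probability tables and group statistics.

    Emits the 2x2x group mixed ANOVA (reward, state, reward x state, each
    x group, group) and the one-tailed between-group t-test on the reward
    main effect (first group label > second), mirroring the behavioral
    analysis of the study design.
    """
    tables = [stay_table(s) for s in sessions]
    groups = [s.group or "all" for s in sessions]
    rows = []
    for session, table in zip(sessions, tables):
        rows.append(
            {
                "subject": session.subject,
                "group": session.group,
                "stay_rew_common": table.probs[1, 0],
                "stay_rew_rare": table.probs[1, 1],
                "stay_unrew_common": table.probs[0, 0],
                "stay_unrew_rare": table.probs[0, 1],
                "n_pairs": int(table.counts.sum()),
            }
        )
    stay_frame = pd.DataFrame(rows)
    report: dict = {"n_subjects": len(sessions)}
    if len(set(groups)) == 2:
        anova = mixed_anova_2x2(tables, groups)
        report["anova"] = [dataclasses.asdict(a) for a in anova]
        complete = [i for i, tb in enumerate(tables) if tb.complete]
        effects = np.array([reward_main_effect(tables[i]) for i in complete])
        labels = [groups[i] for i in complete]
        uniq = set(labels)
        # the directional hypothesis is high-impulsive > low-impulsive
        order = ("high", "low") if uniq == {"high", "low"} else tuple(sorted(uniq))
        ttest = group_ttest(effects, labels, tail="greater", order=order)
        report["reward_effect_ttest"] = {
            **dataclasses.asdict(ttest),
            "order": list(order),
        }
    if out is not None:
        out = Path(out)
        out.parent.mkdir(parents=True, exist_ok=True)
        stay_frame.to_csv(
            out.with_suffix(".tsv"), sep="\t", index=False, float_format="%.6f"
        )
        out.write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")
    report["stay_tables"] = stay_frame
    return report


def cmd_regressors(
    config: PipelineConfig,
    sessions: list[Session],
    params_by_subject: dict | None,
    outdir: str | Path,
) -> list[Path]:
    """Events and convolved design matrices, one pair of TSVs per subject.

    ``params_by_subject`` maps subject id to a fitted ParameterSet; when
    None, each session's generating parameters are used.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for session in sessions:
        params = (
            params_by_subject[session.subject]
            if params_by_subject is not None
            else session.params_true
        )
        if params is None:
            raise ValueError(f"no parameters available for subject {session.subject}")
        rs = build_regressor_set(session, params, config.regressors, config.task)
        ev_path = outdir / f"sub-{session.subject}_events.tsv"
        dm_path = outdir / f"sub-{session.subject}_design.tsv"
        rs.events.to_csv(ev_path, sep="\t", index=False, float_format="%.6f")
        rs.design.to_csv(dm_path, sep="\t", index=False, float_format="%.6f")
        paths.extend([ev_path, dm_path])
    write_manifest(outdir / "manifest.json", _config_repr(config), config.seed)
    return paths


def cmd_recover(
    config: PipelineConfig,
    n_replicates: int = 1,
    models: tuple[str, ...] = ("mf", "mb", "hybrid"),
    run_bms: bool = True,
    out: str | Path | None = None,
) -> dict:
    """Parameter- and model-recovery experiment.

    Per replicate: simulate the configured cohorts, fit the models
    hierarchically, and report Spearman rank correlations between true and
    MAP hybrid parameters, native-scale MAP means per group, and (when
    ``run_bms``) the exceedance probabilities of a random-effects model
    selection over the sampled evidences.
    """
    replicates = []
    for k in range(n_replicates):
        rep_seed = config.seed + _REPLICATE_STRIDE * k
        sessions = simulate_groups(config, seed=rep_seed)
        fits, evidences, _ = fit_all_models(config, sessions, models, seed=rep_seed)
        entry: dict = {"replicate": k, "seed": rep_seed, "n_subjects": len(sessions)}
        if "hybrid" in models:
            true = np.array(
                [s.params_true.to_array() for s in sessions]
            )
            mapv = np.array(
                [f.map_params.to_array() for f in fits["hybrid"]]
            )
            entry["rank_corr"] = {
                name: float(sp_stats.spearmanr(true[:, i], mapv[:, i]).statistic)
                for i, name in enumerate(PARAM_NAMES)
            }
            entry["map_group_means"] = {}
            for spec in config.groups:
                mask = np.array([s.group == spec.name for s in sessions])
                entry["map_group_means"][spec.name] = {
                    name: float(mapv[mask, i].mean())
                    for i, name in enumerate(PARAM_NAMES)
                }
        if run_bms and len(models) >= 2:
            lev = np.column_stack([[e[0] for e in evidences[m]] for m in models])
            res = rfx_bms(
                EvidenceMatrix(lev, tuple(models)),
                config.bms.alpha0,
                config.bms.n_mc,
                seed=rep_seed,
            )
            entry["bms"] = bms_report(res)
        replicates.append(entry)
    report = {"n_replicates": n_replicates, "models": list(models), "replicates": replicates}
    if out is not None:
        Path(out).write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")
    return report
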