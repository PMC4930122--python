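#!/usr/bin/env python
"""Construct model-derived fMRI regressors from the fitted sessions.

For every subject, replays the session under the fitted hybrid parameters
and writes a BIDS-style events table (first-stage onsets with choice
probability and its omega-derivative; prediction-error events at
second-stage and feedback onsets with the model-free PE and the
mean-centered model-based-minus-model-free difference) plus the
HRF-convolved design matrix sampled at TR = 2 s.
"""

import argparse
from pathlib import Path

import pandas as pd

from twostep.agents import ParameterSet
from twostep.config import PARAM_NAMES, PipelineConfig
from twostep.pipeline import cmd_regressors, load_sessions

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    import dataclasses

    config = dataclasses.replace(PipelineConfig(), seed=args.seed)
    sessions = load_sessions(args.results / "sessions")
    fits = pd.read_csv(args.results / "fits" / "fits.tsv", sep="\t")
    hybrid = fits[fits["model"] == "hybrid"].set_index("subject")
    params = {
        subj: ParameterSet(**{n: float(row[n]) for n in PARAM_NAMES})
        for subj, row in hybrid.iterrows()
    }
    paths = cmd_regressors(config, sessions, params, args.results / "regressors")
    print(f"wrote {len(paths)} regressor files for {len(sessions)} subjects")
    design = pd.read_csv(paths[1], sep="\t")
    print(f"design matrix: {design.shape[0]} scans x {design.shape[1] - 1} regressors; "
          f"columns: {', '.join(c for c in design.columns if c != 'time_s')}")
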