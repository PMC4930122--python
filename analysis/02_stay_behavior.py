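#!/usr/bin/env python
"""Behavioral raw-data analysis of the simulated cohorts.

Computes per-subject stay probabilities by previous reward x transition,
runs the 2 x 2 x group mixed ANOVA (reward and transition within, group
between), and the one-tailed between-group t-test (high > low) on the
reward main effect. A positive reward main effect indexes model-free
control; the reward x transition interaction indexes model-based control.
"""

import argparse
from pathlib import Path

from twostep.config import PipelineConfig
from twostep.pipeline import cmd_stats, load_sessions

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    import dataclasses

    config = dataclasses.replace(PipelineConfig(), seed=args.seed)
    sessions = load_sessions(args.results / "sessions")
    report = cmd_stats(config, sessions, out=args.results / "stay_stats.json")

    print(f"n = {report['n_subjects']} subjects")
    for eff in report["anova"]:
        print(f"  {eff['effect']:<24} F(1,{eff['df2']}) = {eff['F']:7.2f}  p = {eff['p']:.2g}")
    tt = report["reward_effect_ttest"]
    print(f"reward effect {tt['order'][0]} > {tt['order'][1]}: "
          f"T({tt['df2']}) = {tt['t']:.2f}, one-tailed p = {tt['p']:.3f}")
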