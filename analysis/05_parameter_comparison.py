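#!/usr/bin/env python
"""Group comparison of the fitted hybrid-model parameters.

Subjects the four hybrid learning parameters (omega, alpha1, alpha2,
lambda) to a one-way MANOVA (Roy's largest root) with impulsivity group as
the between-subject factor, followed by post-hoc univariate F tests per
parameter.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from twostep.stay_stats import group_ttest, manova_roy

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    fits = pd.read_csv(args.results / "fits" / "fits.tsv", sep="\t")
    hybrid = fits[fits["model"] == "hybrid"].set_index("subject")
    truth = pd.read_csv(args.results / "sessions" / "params_true.tsv", sep="\t")
    groups = truth.set_index("subject").loc[hybrid.index, "group"].tolist()

    names = ["omega", "alpha1", "alpha2", "lam"]
    res = manova_roy(hybrid[names].to_numpy(), groups)
    print(f"MANOVA (impulsivity): Roy's root = {res.roy_root:.3f}, "
          f"F({res.df1},{res.df2}) = {res.F:.2f}, p = {res.p:.3f}")

    report = {"manova": {"roy_root": res.roy_root, "F": res.F,
                         "df1": res.df1, "df2": res.df2, "p": res.p},
              "univariate": {}}
    for name in names:
        t = group_ttest(hybrid[name].to_numpy(), groups, order=("high", "low"))
        report["univariate"][name] = {"F": t.F, "df2": t.df2, "p": t.p}
        print(f"  {name:<7} F(1,{t.df2}) = {t.F:5.2f}, p = {t.p:.3f} "
              f"(high mean {hybrid[name][pd.Series(groups, index=hybrid.index) == 'high'].mean():.3f}, "
              f"low mean {hybrid[name][pd.Series(groups, index=hybrid.index) == 'low'].mean():.3f})")
    (args.results / "parameter_comparison.json").write_text(
        json.dumps(report, indent=2) + "\n"
    )
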