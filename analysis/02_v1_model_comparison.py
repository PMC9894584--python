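#!/usr/bin/env python
"""V1 pathway on a synthetic SR cohort: GLM activity profiles from partial
trials, successor/predecessor contrast, exponential-decay fit of the lag
profile, and the SR / CO / H0 model comparison.

With the default ground truth (SR, gamma = 0.3) the script reports a clearly
positive successor-minus-predecessor contrast, per-subject fitted gamma close
to 0.3, and the SR model winning the group BIC comparison.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from srmap import io
from srmap.pipeline import analyze_v1_cohort
from srmap.synth import GroundTruth, make_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--subjects", type=int, default=12)
parser.add_argument("--gamma", type=float, default=0.3)
parser.add_argument("--out", default="results")
args = parser.parse_args()

out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)

truth = GroundTruth(generative_model="SR", gamma=args.gamma)
cohort = make_cohort(args.subjects, truth, args.seed, rois=("V1",))
res = analyze_v1_cohort(cohort.subjects)

res["model_comparison"]["fits"].to_csv(out / "v1_model_fits.tsv", sep="\t",
                                       index=False)
t = res["successor_vs_predecessor"]
summary = {
    "n_subjects": args.subjects,
    "true_gamma": args.gamma,
    "successor_vs_predecessor": {"t": round(t.statistic, 3), "df": t.df,
                                 "p": t.p_value},
    "gamma_decay_mean": round(res["gamma_decay_mean"], 4),
    "gamma_decay_sem": round(res["gamma_decay_sem"], 4),
    "sr_gamma_median": round(float(np.median(res["sr_gamma_fits"])), 4),
    "mean_bic": {k: round(v, 2)
                 for k, v in res["model_comparison"]["mean_bic"].items()},
    "winner": res["model_comparison"]["winner"],
}
io.write_report(summary, out / "v1_summary.json")
print(json.dumps(summary, indent=2))
print(f"\nwrote {out / 'v1_summary.json'} and {out / 'v1_model_fits.tsv'}")
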