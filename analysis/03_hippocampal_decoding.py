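#!/usr/bin/env python
"""Hippocampal pathway on a synthetic cohort: localizer decoding accuracy,
control-subtracted successor/predecessor classifier-evidence contrast on
partial trials, and the time-resolved evidence difference with its fitted
hemodynamic peak.

With a forward-skewed (SR) ground truth the successor evidence exceeds the
predecessor evidence at the group level, and the evidence difference
time-course shows a transient peaking a few seconds after trial onset.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from srmap import decoding, io
from srmap.pipeline import decode_subject
from srmap.stats import paired_t
from srmap.synth import GroundTruth, make_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--subjects", type=int, default=8)
parser.add_argument("--out", default="results")
args = parser.parse_args()

out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)

truth = GroundTruth(generative_model="SR", gamma=0.5, pattern_amplitude=0.2)
cohort = make_cohort(args.subjects, truth, args.seed, rois=("hippocampus",))

rows, curves = [], []
for i, sub in enumerate(cohort.subjects):
    r = decode_subject(sub)
    offsets, diff = decoding.time_resolved_evidence(
        r["model"], r["preprocessed_main"], sub.design, sub.spec)
    curves.append(diff)
    rows.append({"subject": i, "loo_accuracy": r["accuracy"],
                 "successor_evidence": r["successor"],
                 "predecessor_evidence": r["predecessor"]})

table = pd.DataFrame(rows)
table.to_csv(out / "decoding_per_subject.tsv", sep="\t", index=False)
mean_curve = np.mean(curves, axis=0)
pd.DataFrame({"offset_s": offsets, "diff_evidence": mean_curve}).to_csv(
    out / "evidence_timecourse.tsv", sep="\t", index=False)

contrast = paired_t(table["successor_evidence"],
                    table["predecessor_evidence"])
peak = decoding.fit_hrf_peak(offsets, mean_curve)
summary = {
    "n_subjects": args.subjects,
    "loo_accuracy_mean": round(float(table["loo_accuracy"].mean()), 4),
    "chance_level": 0.125,
    "successor_vs_predecessor": {"t": round(contrast.statistic, 3),
                                 "df": contrast.df, "p": contrast.p_value},
    "evidence_peak_s": None if peak is None else round(peak, 2),
}
io.write_report(summary, out / "decoding_summary.json")
print(json.dumps(summary, indent=2))
print(f"\nwrote {out / 'decoding_summary.json'}")
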