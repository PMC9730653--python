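#!/usr/bin/env python
"""MyD88-dependent TLR-signaling gene-set score over time in the CP.

Scores GO:0002755 per spot against expression-matched controls,
collects the per-time distributions in the CP cluster, and summarizes
them with bootstrap CIs, a loess curve and the recovered peak time
(planted program peaks at 24 h).
"""

from pathlib import Path

from ichmap.config import RunConfig
from ichmap.pipeline import (
    annotate_cohort,
    run_score_timecourse,
    simulate_spot_cohort,
)
from ichmap.report import build_report

OUT = Path("results")

cfg = RunConfig(seed=1)
cohort = simulate_spot_cohort(cfg)
expr, _, assignment = annotate_cohort(cohort.samples, cfg)
tidy, tc = run_score_timecourse(expr, assignment, cfg)

tidy.to_csv(OUT / "tlr_score_by_spot.csv", index=False)
build_report({"timecourses": [tc]}, OUT)
print(tc.table[["time_h", "n", "estimate", "ci_lo", "ci_hi"]]
      .round(3).to_string(index=False))
print(f"recovered peak time: {tc.peak_time_h} h "
      f"(local maxima: {tc.local_maxima_h})")
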