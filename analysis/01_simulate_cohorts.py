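#!/usr/bin/env python
"""Generate the synthetic spot-transcriptomics cohort.

Writes a 10x-style fixture bundle (one sample per time point: untouched
control plus 2, 12, 24, 48 and 96 h after whole-blood injection) with
the anatomical gene-set GMT and the planted-truth table to
``results/spot_bundle/``.
"""

from pathlib import Path

from ichmap.config import RunConfig
from ichmap.pipeline import simulate_spot_cohort
from ichmap.synthetic import default_gene_sets, write_fixture_bundle

OUT = Path("results/spot_bundle")

cfg = RunConfig(seed=1)
cohort = simulate_spot_cohort(cfg)
write_fixture_bundle(cohort, default_gene_sets(), OUT, force=True)

n_spots = sum(s.n_spots for s in cohort.samples)
print(f"wrote {len(cohort.samples)} samples, {n_spots} spots total -> {OUT}")
print(cohort.truth.groupby("region5").size().to_string())
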