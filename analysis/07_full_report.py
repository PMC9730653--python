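#!/usr/bin/env python
"""Run the whole pipeline end to end and assemble the report.

Equivalent to ``ichmap run-all --seed 1 --outdir results/report``:
spot cohort -> annotation -> DGE/enrichment -> score time course ->
imaging series -> knockout comparison -> figures + tables + manifest.
"""

import sys

from ichmap.cli import main

sys.exit(main(["run-all", "--seed", "1",
               "--outdir", "results/report", "--maps"]))
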