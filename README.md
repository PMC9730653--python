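# ichmap

Spatiotemporal mapping of brain inflammation after intracerebral
hemorrhage (ICH), as a tested, reusable Python pipeline.

After whole blood is injected into the mouse striatum, two brain
compartments react on very different clocks: the **choroid plexus
(CP)** mounts an acute inflammatory response (cytokines, interferon
response, leukocyte adhesion molecules) peaking within 12–24 h, while
the **perilesional striatum** responds with a delayed macrophage wave
around 96 h, accompanied by biphasic blood–brain-barrier leakage
(peaks near 12 h and 48 h).  `ichmap` implements the full quantitative
workflow used to establish that picture, for two data modalities:

* **Spatial transcriptomics** (10x-style spot bundles): per-sample
  normalization; anatomical gene-set scoring against
  expression-matched binned control genes; Leiden clustering with the
  community count constrained by a resolution bisection search;
  cluster→region assignment with a dominance rule that yields
  composite labels (the deep-brain cluster spanning
  pallidum/hypothalamus/midbrain/pons); region-stratified Wilcoxon
  rank-sum differential expression against the untouched control with
  BH correction, top-k marker tables, hypergeometric gene-set
  enrichment, and gene-set-score time courses
  (e.g. GO:0002755, MyD88-dependent TLR signaling).
* **Quantitative immunofluorescence** (multichannel TIFF sections with
  label-mask compartments): standardized eight-section selection,
  moment-based similarity registration to a common template,
  cross-animal average-intensity maps, dextran leakage area/intensity
  quantification, per-compartment mean intensities, bootstrap/loess
  temporal summaries, and knockout-series (TLR4⁻/⁻, MyD88⁻/⁻) group
  comparisons.

Since no raw study data ship with the package, a first-class
**synthetic-data generator** (`ichmap.synthetic`) produces spot and
image cohorts with the planted spatiotemporal structure above and full
ground truth, which is what the test suite and the analysis scripts
run on.  See `docs/methods.md` for the models and every default.

## Worked example

```python
from ichmap.config import RunConfig
from ichmap.pipeline import (
    annotate_cohort, run_dge, simulate_spot_cohort,
)

cfg = RunConfig(seed=1)
cohort = simulate_spot_cohort(cfg)            # 6 samples, ~3100 spots
expr, scores, assignment = annotate_cohort(cohort.samples, cfg)
print(assignment.cluster_to_region)
dge, top = run_dge(expr, assignment, cfg, regions=["CP"])
print(top[top.time_h == 12.0].gene.tolist())
```

prints

```
{0: 'CTX', 1: 'TH', 2: 'STR', 3: 'PAL+HY+MB+P', 4: 'CP'}
['Cxcl10', 'Ccl5', 'Icam1', 'Serpina3n', 'Ifi27l2a']
```

— the five main clusters map one-to-one onto anatomy (with the
composite deep-brain label), and the 12 h CP top-5 consists of the
acute inflammatory wave genes (chemokines, adhesion molecules,
acute-phase markers), exactly the planted program.  On this cohort the
adjusted Rand index between recovered region labels and the planted
truth is 1.0.

The numbered scripts under `analysis/` run the complete study
narrative and write their tables and figures under `results/`:

```sh
python analysis/01_simulate_cohorts.py      # spot cohort fixture
python analysis/02_annotate_regions.py      # clusters -> regions, ARI
python analysis/03_temporal_dge.py          # DE tables + enrichment
python analysis/04_score_timecourse.py      # TLR/MyD88 score in CP
python analysis/05_histology_timecourses.py # leakage, CD45, ICAM1 maps
python analysis/06_knockout_series.py       # sham ~ KO < wildtype
python analysis/07_full_report.py           # everything, one report
```

The same stages are exposed as a CLI (`ichmap simulate|annotate|dge|
enrich|score|register|maps|leakage|timecourse|compare|report|run-all`).

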