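# Methods

`ichmap` re-creates, as a tested pipeline over synthetic data, the
quantitative analysis of a mouse intracerebral-hemorrhage (ICH)
experiment: whole blood is injected into the right striatum, and the
inflammatory response is read out over hours to days in two
compartments — the choroid plexus (CP), which reacts acutely, and the
perilesional striatum, which reacts with a delay — using spot-based
spatial transcriptomics and quantitative immunofluorescence.

Because the raw study data are not bundled here, every analysis runs on
cohorts from the synthetic-data generator, which plants the study's
qualitative structure with known ground truth.  What the tests
demonstrate is therefore that the *procedures* recover *planted*
structure at realistic noise levels — not that they would reach the
same numbers on the original tissue.

## Synthetic cohorts

**Section template.** A coronal-section cartoon: an anisotropic
elliptical outline (semi-axes 0.36/0.43 of the field, so the principal
axis is well defined for registration, with enough border margin that
a 10 % scale-up plus a 10 px shift never clips the section), a cortical
band (CTX), two striatal blobs (STR) with the lesion carved out of the
ipsilateral one, central thalamus (TH), a ventral deep-brain band
(DEEP, standing in for pallidum/hypothalamus/midbrain/pons), and three
ventricular cavities each enclosing a choroid-plexus blob.  Masks are
mutually disjoint; every spot and pixel carries a recoverable truth
label.  The histology template is rendered at 512×512 px, 20 µm/px;
the transcriptomics layout at 165×165 px, 20 µm/px, which puts the
default six-sample cohort at ≈3,100 spots — the scale at which the
annotation stage is exercised.  The test suite runs the imaging
cohorts on a half-resolution raster of the same physical field
(256 px at 40 µm/px) to keep the default `pytest` run fast; the planted
structure is identical in micrometers.

**Spot counts.** Spots sit on a square 100 µm grid (55 µm nominal spot
diameter recorded in metadata; true spot-array hex geometry adds
nothing to the statistics tested here).  Counts are negative binomial
with dispersion 0.2; library sizes are log-normal (µ = 9.2, σ = 0.3 on
the log scale, ≈10⁴ counts per spot).  The per-spot mean is
`library_size × relative_expression / Z` with a *fixed* normalizer `Z`
(the baseline table total), so a planted fold-change of 4 shifts the
mean count by exactly 4 — this makes the generator's examples
analytically checkable.  Baseline abundances are spread over a
log-spaced range: the control-gene matching of the scoring step bins
genes by mean expression, and a flat baseline would put all markers
into the same bins, making markers of one region serve as controls for
another.

**Temporal programs** are multiplicative Gaussian bumps in log-time
(biphasic = sum of two bumps), acting only inside their compartment:

| program | genes (examples) | compartment | peak | amplitude |
|---|---|---|---|---|
| erythrocyte pulse | Hba-a1, Hbb-bs, Alas2 | STR + lesion + CP | 2 h | 8 |
| CP inflammatory wave | Icam1, Vcam1, Ccl20, Cxcl10, Ccl5, Irf7, Lcn2 … | CP | 12 h | 6 |
| CP TLR/MyD88 program | Myd88, Tlr4, Irak4, Traf6 … | CP | 24 h | 4 |
| perilesional wave | Cd68, Lyz2, Hmox1, Ftl1 … | STR + lesion | 96 h | 6 |
| leukocyte (Ptprc) | Ptprc | CP | 24 h + 96 h | 4 / 5 |

Amplitudes are fold-changes chosen once to be clearly detectable at
the cohort's group sizes without dwarfing the anatomical signal
(marker fold 10 in a region's own spots; deep-brain markers fold 5 in
DEEP).  Knockout genotypes (TLR4ko, MyD88ko) zero the amplitudes of
*CP-restricted* programs only — the erythrocyte pulse, which merely
reaches the CP with the injected blood, is not suppressed.  Sham
animals keep the lesion geometry with all injection-driven programs
off.  The no-injection control reuses the template with lesion spots
relabeled as striatum.

**Section images.** Channel intensity = background + compartment
signal(time, genotype), then Poisson shot noise and Gaussian read
noise (σ = 8).  Planted dynamics: dextran leakage is a perilesional
disc whose area and plateau intensity are biphasic with peaks at 12 h
and 48 h (plus a small acute mechanical component at 2 h); CP dextran
peaks at 2 h with side weights CP_ipsi > CP_third > CP_contra
(1.0/0.7/0.4); CD45 peaks in the CP at 24 h while perilesional CD45
rises only from 48 h; ICAM1 peaks in the CP at 36 h.  Each animal
contributes a stack of sixteen 60-µm-spaced sections whose lesion
cross-section follows a spherical profile along the
anterior–posterior axis; one similarity jitter per animal (rotation
≤10°, shift ≤8 px, scale 0.95–1.05) is applied to images and masks
alike.  Knockouts and shams suppress the inflammatory CP signals to
5 % of wildtype.

What the generator does *not* emulate: real anatomical geometry,
segmentation error (masks are exact up to the jitter), per-section
staining variability beyond the global intensity normalization,
autofluorescence structure, spatial transcript diffusion between
spots, and batch effects between samples.  Passing tests therefore say
nothing about robustness to those factors.

## Anatomical annotation

Per-sample normalization scales each spot to the median total count,
then `log1p`; samples are concatenated without batch correction.
Gene-set scores follow the binned-control scheme: genes are ranked by
mean expression into 25 equal-size bins, and for each set gene 50
control genes are drawn from its bin (set genes excluded, with
replacement if the bin is small); score = mean(set) − mean(pooled
controls).  Scores are shift-invariant and deterministic given the
seed.

Clustering: PCA to 30 components (full SVD, deterministic), a
symmetrized 15-nearest-neighbor graph, and Leiden community detection
whose resolution is found by bisection so that the community count
equals the target (5).  The search brackets [0.001, 2.0]: at the lower
end the partition converges to the graph's connected components,
which gives a reliable bracket even when an acute signature (the 2 h
erythrocyte pulse) makes one region/time stratum very distinct.  On a
plateau of resolutions hitting the target, the search keeps moving
toward the smallest one; the count trace is checked for monotonicity
and a violated bracket is re-evaluated with a perturbed partition
seed.  Labels are returned ordered by decreasing cluster size.

Cluster→region assignment: per cluster, the mean score and
positive-score fraction are computed per region; every region whose
mean score is ≥ 0.75 of the best positive mean is kept.  One region →
its label; several → a composite label (this is how the deep-brain
cluster acquires `PAL+HY+MB+P`); none positive → `unassigned`.  The
positive fraction is reported for QC but does not enter the rule.

## Temporal differential expression

Each post-injection time point is compared with the control within one
region by a two-sided Wilcoxon rank-sum test per gene on the
log-normalized expression: exact enumeration of the rank-sum
distribution when both groups have ≤ 8 spots (the two-sided p is
P(|W − E W| ≥ |w_obs − E W|) under permutation), otherwise the
tie-corrected normal approximation.  log2 fold-changes use
`expm1`-means with a 1e−9 pseudocount.  BH controls the FDR.  Top-k
tables keep the k smallest adjusted p among *up-regulated* genes; ties
break by |log2FC| descending, then gene symbol.  Enrichment is the
hypergeometric upper tail against the universe of genes detected in
≥ 3 spots, BH-corrected across the catalog.

## Histology quantification

Standardized section selection: first section at/after 300 µm
posterior to the anterior commissure, then every second section, eight
in total.  Registration is moment-based on the section outline
(centroid → translation, principal axis → rotation with the
180°-ambiguity resolved by the side of the midline-ventricle centroid,
√area ratio → scale); the mean boundary distance after warping is
reported as a residual and flags low confidence above 5 px.  Warping
is bilinear with out-of-field pixels marked missing, never zero-filled;
averaging is the per-pixel mean over contributing sections only, with
a coverage mask.  Sections are intensity-normalized by the median of
the contralateral hemisphere before any cross-section statistics, so
reported intensities are contralateral-median folds.

Leakage: threshold = background mean + 3 SD over the contralateral
striatum; 8-connected supra-threshold components intersecting a 200 µm
disc around the injection site (the lesion-mask centroid) form the
leakage; area in mm², mean intensity over the component; no component
→ area 0 with missing intensity.

## Temporal summaries and group comparisons

Per time point: mean with a seeded percentile bootstrap CI
(B = 10,000 by default; percentile rather than BCa, matching the
plainest reading of a "bootstrap confidence interval").  The summary
curve is a tricube-weighted local *linear* regression (loess, span
0.75) with a pointwise t-band; σ² uses the smoother-trace df
δ₁ = n − 2 tr L + tr L Lᵀ.  The window widens until at least two
points carry positive weight, so tied neighbor distances cannot
degenerate the fit.

Peak time = observed time closest to the argmax of the loess curve,
ties to the earlier time; *peak localization uses span 0.5* while the
display curve keeps 0.75 — with six exponentially spaced time points a
0.75-span window holds five of six points everywhere and biases the
argmax toward the widely sampled side (a planted 36 h bump reads as
48 h).  Secondary peaks of biphasic courses are identified as interior
local maxima of the per-time estimate sequence, since any wide
smoother merges two humps into one.

Knockout series: animal-level means (sections averaged within animal
first), type-7 quartile boxes with 1.5 IQR whiskers, and exact
two-sided rank-sum comparisons (wildtype-blood vs knockout-blood,
wildtype-blood vs sham, knockout-blood vs sham) BH-corrected as a
family.  The hypothesis test is this package's addition on top of the
descriptive boxplots and is labeled as such in the output tables.

## Numerical and design notes

- All randomness flows from explicit `numpy` Generators seeded from a
  single run seed; no global RNG state.  Same seed → bit-identical
  cohorts, scores and intervals.
- Counts are stored as integer MatrixMarket; expression matrices are
  never serialized and are recomputed from counts.
- A percentile bootstrap of n = 3 observations is checked against the
  exhaustive 27-resample enumeration; the correct limiting interval is
  the quantile function (inverted CDF) of the discrete resample-mean
  distribution, which for {1,2,3} at the 95 % level is the full data
  range.
- The per-time CI "flatness" check on zero-amplitude cohorts is
  formulated as an effect-size bound (estimate spread within a few CI
  half-widths) rather than strict coverage of the grand median —
  a 95 % interval excludes any fixed point for ~5 % of draws, so a
  strict version would fail on one seed in twenty by construction.
- Degenerate inputs: zero-total spots are dropped with a warning;
  genes detected in < 3 spots are flagged but kept; empty compartments
  yield missing values; a leakage search with no supra-threshold
  component near the site reports area 0.

## Limitations

- The anatomical template is a cartoon; region adjacency and shape do
  not match a real atlas, and segmentation is exact by construction.
- Five-cluster recovery is clean on this generator because anatomical
  folds dominate temporal folds, mirroring the studied tissue; data
  where a temporal state rivals anatomy would need the target-count
  constraint revisited.
- The exact rank-sum path enumerates combinations and is only used for
  group sizes ≤ 8; larger groups rely on the tie-corrected normal
  approximation.
- The loess band uses a single-smoother trace df approximation, not a
  full two-delta correction; bands at the time-axis boundaries are
  wider and less calibrated.
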