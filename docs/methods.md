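# Methods

## The sampling problem being modelled

A formalin-fixed tumor block is step-sectioned (one stained level every
~25 μm, eight levels per block unless tissue runs out), each level is
scored for percent CD8+ cells within a pathologist-drawn region of
interest (tumor plus immediately adjacent stroma), and the block-level
truth is taken to be the mean over levels.  The package asks two nested
sampling questions: is one level representative of its block, and is a
small number of ~2 mm² core-biopsy fragments representative of a level (or
of the block, pooling fragments across levels)?  Everything runs on
synthetic data whose structure mirrors such a study; no real slides are
required.

## Synthetic cohort generator

Section values follow a two-level Gaussian hierarchy on the raw percent
scale: patient truth `N(mean, between_sd)`, section value = truth +
`N(0, within_sd)`, clipped to [0, 100].  The raw-percent scale (rather
than logit) is used because the downstream models operate on raw percent;
clip events are counted and reported in the table's metadata.  Clipping is
negligible except in the lowest-staining (colorectal) arm, where truths
near 0 put a few percent of sections at the floor — those cohorts are
exactly the ones where a floor is also physically real.

Default cohort: 6 ductal breast (mean 8.8%, within-SD 1.2), 6 medullary
breast (mean 24.0%, within-SD 1.7) and 13 colorectal carcinomas (mean
3.8%, within-SD 0.4), eight sections each.  Group means and within-patient
SDs follow published group summaries for cohorts of this kind; the
between-patient SDs (7, 13 and 3 percent respectively) are calibrated
once from the published medians and observed ranges, since only pooled
intrapatient SDs are reported — they are a package choice, not quoted
values.  Tissue loss affects each section independently with probability
0.02 (a handful of levels per ~200, as observed in practice) and reduces
the expected cell count to 30% of normal while leaving the expected
percent unchanged, so analyses with and without flagged sections are
comparable.  Section cell counts are Poisson (default mean 20,000) so
count-level noise varies realistically.

Slides are marked spatial point patterns: a Poisson(density × ROI area)
number of cells uniform over the ROI polygon, each CD8+ with probability
`p(x, y)`.  Two patterns are provided — uniform, and margin-enriched,
where `p` is multiplied by an enrichment factor within a band of the ROI
boundary (erosion by the band width splits interior from margin) and
rescaled so the area-weighted mean equals the slide target exactly.  When
a high target and strong enrichment would push the margin probability past
1 it saturates at 1 and the interior rate compensates, preserving the mean
(the effective enrichment is then smaller than requested).  A band wider
than the ROI inradius degenerates to uniform.  Coordinates are μm (origin
at the bounding-box corner, y downward); areas are mm².

What the generator deliberately does not emulate: nucleus morphology and
segmentation error, staining chemistry and scanner artefacts, non-Poisson
cell clustering (glands, follicles), irregular hand-drawn ROI shapes, and
correlated section-to-section spatial drift through the block.  Passing
tests therefore demonstrate the statistical machinery under the stated
hierarchy and spatial patterns, not robustness to every pathology of real
slides.

## Variance components

The fixed-effects ANOVA is sequential (type-I) with patient entered before
section; "percent of variability explained" is each factor's share of the
total sum of squares.  Patient-first ordering is a declared convention —
the quantity is order-dependent and no standard definition exists for it.
The model treats section index (step depth 1..8) as a crossed factor with
common levels.  An exactly constant response returns all-zero sums of
squares with undefined (NaN) variance fractions rather than 0/0.

The random-intercept model is estimated by the ANOVA method of moments:
`σ̂²_patient = max(0, (MSB − MSW)/n₀)` with the harmonic correction
`n₀ = (N − Σn_i²/N)/(k − 1)` for unbalanced data, `σ̂²_residual = MSW`.
For balanced one-way layouts this equals REML while remaining closed-form
and deterministic; the zero-truncation keeps the ICC in [0, 1].  Both the
ANOVA SS fractions and the mixed-model ICC are reported side by side,
since "fraction of variability attributable to patients" is quoted in
both senses in practice.

## Section resampling

Truth per patient = mean over all its sections; cut-off = cohort median of
truths (midpoint convention for even cohorts); value ≥ cut-off ⇒ high (a
declared tie rule; ties have measure zero for continuous staining).
Scheme (i) fixes the patient set and draws k sections with replacement per
patient; scheme (ii) draws patients with replacement first, then sections.
In both, truth and cut-off stay those of the original cohort — the median
is a candidate cut-off determined by the full sample, so bootstrap cohorts
are judged against it rather than re-deriving their own.  Agreement is
overall concordance; the 95% CI is the 2.5/97.5 percentile interval over
replicates (the natural choice for a resampling distribution); replicates
missing a class are skipped for sensitivity or specificity and counted.
The mean-or-max summary choice (`summary_stat`) matters only for k ≥ 2.

## Virtual cores and subsampling

The grid tiles the ROI bounding box with axis-aligned rectangles of area
2 mm² (square by default, side √2 mm ≈ 1414 μm; aspect configurable),
anchored at the bounding-box min corner (a configurable anchor offset
exists as a robustness knob, since anchoring is otherwise arbitrary).
Retention requires ROI overlap ≥ 0.7 mm² — computed by exact polygon
intersection — and tumor fraction ≥ 33%; with the defaults 0.7/2.0 = 35%,
so the overlap filter is the binding one.  Cells are dimensionless points;
membership is boundary-inclusive, with a half-open tie rule on shared tile
edges (the tile with the smaller row-major index wins) so a partition of
the slide conserves counts exactly.  Retained cores with zero cells have
undefined percent and are dropped with a warning.

Subsampling draws k distinct cores per replicate (1000 replicates by
default).  The slide/block reference is the mean and sample SD (n−1) of
its retained core percents.  Reported per unit × k × summary: the
within-1-SD rate `P(|estimate − core mean| ≤ core SD)`, and out-of-bag
differences summary(selected) − summary(unselected), whose SD is the
headline variability measure (their mean is 0 for the mean summary by
finite-population symmetry).  Mirroring the published design, units need
≥ 15 retained cores in restricted mode; an unrestricted mode exists for
exhaustive small-n checks.  Blocks pool retained cores across a block's
slides unweighted (each core counts once — the simplest reading of
"pooled over all slides"); a cell-count-weighted block mean is available
behind a flag.  ROC analysis classifies each replicate's estimate against
cut-offs 1/2/5/10% with the unit's core mean as truth (≥ rule), averaging
per-replicate sensitivity/specificity/accuracy over replicates; cut-offs
leaving a single class yield NaN for the undefined metric rather than 0.

Loess curves of out-of-bag SD versus unit mean staining use tricube
weights and a local quadratic with span 0.75 (classic defaults, both
configurable); the log2 display scale is `log2(x + 0.1)`, the offset
keeping zero-percent units finite.  The smoother is implemented in-package
as a direct weighted least-squares solve on the centred predictor because
the available lowess routine is local-linear only and cannot evaluate on
a new grid; it reproduces polynomials up to degree 2 exactly.

## Pipeline and reproducibility

One master seed is expanded per stage as
`SeedSequence([master, crc32(stage_name)])`, truncated below 2³¹, so any
stage reruns independently yet reproducibly; no global RNG state is used.
The demo pipeline runs 25 patients × 8 sections, 2 slides per block
(targets taken from the patient's simulated section values, so the spatial
stage inherits the cohort hierarchy), ~9–12 mm square ROIs at 600
cells/mm² giving roughly 50–70 retained cores per slide, and 1000
replicates per resampling stage — sizes chosen to exercise every stage of
the design at desk scale, and the whole run completes in a few seconds.
Reruns with the same config produce byte-identical tables; the output
bundle records the seed, a config hash, clip counts and warnings.

## Known limitations

- Gaussian-with-clipping section values slightly distort the lowest
  staining group near the floor; a censored or logit model would trade
  that for a scale the downstream ANOVA no longer matches.
- The ROI is also the tumor mask, so "tumor fraction" means ROI fraction;
  a separate epithelium-only mask is out of scope.
- Cores are grid tiles, not randomly placed or needle-shaped fragments;
  anchor sensitivity can be probed via the offset knob but is not swept
  automatically.
- The mixed model is strictly one-way (no covariates, no crossed random
  effects); the fixed-effects model is strictly additive.
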