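# tilsampling

How much of a tumor do you have to look at before an immunohistochemistry
(IHC) readout of CD8+ T-cell infiltration is representative?  Pathology
cohorts score percent CD8+ cells (CD8+ cells / all nucleated cells × 100)
on a single stained section — or on a couple of needle-biopsy cores — and
use it to call a patient "CD8-high" or "CD8-low" against a cut-off.
`tilsampling` is a simulation and analysis toolkit for quantifying the
sampling error of that practice: it generates synthetic step-sectioned
cohorts and whole-slide cell maps with controlled patient, section and
spatial variability, and measures how well small subsamples (single
sections, 1–5 virtual cores) recover block-level truth.

It is aimed at biostatisticians and digital-pathology groups designing
tissue-based biomarker assays and sizing their validation studies.

## The statistics at its core

* **Variance components.**  Section measurements are modelled as
  `y_ij = μ + a_i + e_ij`, with patient effects `a_i ~ N(0, σ²_patient)`
  and section noise `e_ij ~ N(0, σ²_residual)`.  The package fits (i) a
  sequential two-factor fixed-effects ANOVA (`percent ~ patient + section`,
  patient first), reporting each factor's share of the total sum of
  squares, and (ii) the one-way random-intercept model by the ANOVA method
  of moments, reporting the intraclass correlation coefficient
  `ICC = σ²_patient / (σ²_patient + σ²_residual)`.
* **Section resampling.**  Patient truth is the mean over all sections;
  the cohort median is the candidate cut-off (value ≥ cut-off ⇒ high).
  Two 1000-round bootstrap schemes — sections-within-fixed-patients, and
  patients-then-sections — yield agreement, sensitivity and specificity of
  k-section classification.
* **Virtual core biopsies.**  Each slide's tumor region of interest (ROI)
  is tiled with 2 mm² rectangles; tiles with ≥ 0.7 mm² of ROI overlap and
  ≥ 33% tumor fraction become "cores" and are scored by exact
  point-in-polygon counting.  Subsampling k cores without replacement
  (mean or max summary) gives within-1-SD rates, out-of-bag differences
  (selected minus unselected cores), loess curves of variability versus
  mean staining, and ROC points at candidate cut-offs (1/2/5/10%).

## Worked example

```python
import tilsampling as ts

df = ts.generate_section_measurements(ts.default_groups(), seed=1)
anova = ts.fixed_effects_anova(df)
vc = ts.random_intercept_icc(df)
print(anova.to_frame().round(3))
print(f"ICC = {vc.icc:.3f}")

s = ts.resample_section_classification(df, k_sections=1, n_reps=1000, seed=2)
print(f"agreement {s.agreement_mean:.1f}% "
      f"(95% CI {s.agreement_ci95[0]:.1f}-{s.agreement_ci95[1]:.1f})")
```

prints (seed 1/2 of the default 25-patient cohort):

```
    term        ss  df  pct_of_total_ss
 patient 21060.593  24           99.430
 section     2.275   7            0.011
residual   118.422 168            0.559
ICC = 0.994
agreement 97.2% (95% CI 92.0-100.0)
```

Read: 99.4% of the variability in percent CD8+ sits between patients and
essentially none between step sections (ICC 0.994 — sections of one block
are nearly interchangeable), and classifying each patient from a single
random section agrees with the full-block truth in ~97% of bootstrap
rounds.  The `examples/` directory walks through each capability the same
way (cohort simulation, variance components, section resampling, core
grids, core subsampling + ROC, and the full pipeline), and the
`tilsampling` console script exposes the stages as subcommands
(`simulate`, `variance`, `sections-resample`, `cores-grid`,
`cores-resample`, `cores-roc`, `run-all`).

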