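"""How many core biopsies approximate a slide, and mean or max of them?

Builds a small bank of synthetic slides spanning 1-30% CD8+, subsamples
k = 1..5 cores per slide (without replacement, 1000 rounds), and prints
within-1-SD rates, out-of-bag difference SDs, and ROC points at the 5%
cut-off for both summary statistics.
"""

import numpy as np

import tilsampling as ts

units = {}
for i, target in enumerate([1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 20.0, 30.0]):
    pattern = "margin_enriched" if i % 4 == 2 else "uniform"
    spec = ts.SlideSpec(ts.rectangle_roi(9.0, 9.0), 600.0, target,
                        pattern=pattern, margin_width=300.0, margin_enrichment=3.0)
    geometry, cells = ts.generate_slide(spec, seed=100 + i)
    scored = ts.score_cores(ts.generate_core_grid(geometry), cells)
    units[f"slide-{i}"] = np.array([c.percent_cd8 for c in scored])

print("k  within-1SD(mean)  oob-SD(mean)  oob-SD(max)")
for k in range(1, 6):
    rates, sd_mean, sd_max = [], [], []
    for uid, v in units.items():
        sm = ts.subsample_cores(v, k=k, summary_stat="mean", n_reps=1000, seed=k)
        sx = ts.subsample_cores(v, k=k, summary_stat="max", n_reps=1000, seed=k)
        rates.append(sm.within_1sd_rate)
        sd_mean.append(sm.oob_diff_sd)
        sd_max.append(sx.oob_diff_sd)
    print(f"{k}  {100 * np.mean(rates):15.1f}%  {np.mean(sd_mean):11.3f}  "
          f"{np.mean(sd_max):11.3f}")

print("\nROC at the 5% cut-off (truth = slide core mean):")
points = ts.roc_over_cutoffs(units, ks=(1, 2, 3), cutoffs=(5.0,), n_reps=1000, seed=9)
for p in points:
    print(f"  k={p.k} {p.summary_stat:>4}: sens {p.sensitivity:5.1f}%  "
          f"spec {p.specificity:5.1f}%  acc {p.accuracy:5.1f}%")

print(
    "\nAveraging more cores tightens the estimate (out-of-bag SD falls, "
    "within-1-SD rate climbs, ROC moves toward the top-left); taking the "
    "max instead overestimates staining and bleeds specificity as k grows."
)
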