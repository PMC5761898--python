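"""Where does the variability in percent CD8+ live: patients or sections?

Fits the sequential two-factor ANOVA (patient first) and the one-way
random-intercept model on a simulated cohort, and prints the percent of
total sum of squares per factor plus the intraclass correlation
coefficient (ICC).
"""

import tilsampling as ts

df = ts.generate_section_measurements(ts.default_groups(), seed=1)

anova = ts.fixed_effects_anova(df)
print(anova.to_frame().round(3).to_string(index=False))
print(f"section-term F = {anova.f_section:.3f}, p = {anova.p_section:.3f}")

vc = ts.random_intercept_icc(df)
print(
    f"\nsigma2_patient = {vc.sigma2_patient:.2f}  "
    f"sigma2_residual = {vc.sigma2_residual:.2f}  ICC = {vc.icc:.3f}"
)
print(
    "\nNearly all variability is between patients (ICC close to 1): sections "
    "from the same block are close to interchangeable, so one stained level "
    "is representative of its block."
)
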