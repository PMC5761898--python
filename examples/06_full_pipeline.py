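"""Run the whole pipeline end to end on the default synthetic cohort.

One master seed drives every stage; rerunning with the same seed gives
byte-identical output tables.
"""

import tilsampling as ts

cfg = ts.RunConfig(seed=1, output_dir="scratch/full-run")
bundle = ts.run_pipeline(cfg)
out = bundle.write()

print(f"output tables written to {out}:")
for name, table in bundle.tables.items():
    print(f"  {name:22} {table.shape[0]:>6} rows x {table.shape[1]} cols")
print(f"metadata: {bundle.metadata}")

vc = bundle.tables["variance_components"].iloc[0]
print(
    f"\nheadline numbers: ICC = {vc['icc']:.3f}, patient share of SS = "
    f"{vc['pct_var_patient_ss']:.1f}%, section-term p = {vc['p_section']:.3f}"
)
print(
    "The config hash and seed in metadata.yaml tie every table to the "
    "exact generating conditions."
)
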