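"""Run the whole desk-scale study from one configuration.

Filters, summary statistics, the three-estimator comparison, trim-rate
sensitivity, skill subgroups and effect sizes, written as JSON and text
reports into a temporary directory.
"""

import tempfile
from pathlib import Path

import panelkink as pk

outdir = Path(tempfile.mkdtemp(prefix="panelkink_"))
config = pk.AnalysisConfig(arm="female", n_individuals=400, seed=11,
                           trim_rates=[0.2, 0.3, 0.4],
                           gmm=pk.GmmSpec(grid_points=150),
                           output_dir=str(outdir))
bundle = pk.run_analysis(config)

print("estimator comparison:")
cols = ["estimator", "alpha", "alpha_stars", "delta", "gamma", "n"]
print(bundle.estimator_table[cols].round(3).to_string(index=False))

print("\nthreshold estimates by trim rate:")
print(bundle.sensitivity_table[["trim_rate", "alpha", "delta", "gamma"]]
      .round(3).to_string(index=False))

eff = bundle.effect_sizes["female"]
print(f"\nabove-threshold slope {eff['slope_above']:+.2f} h per BMI unit "
      f"= {eff['effect_size_above_pct_sd']:+.1f}% of an outcome SD")

print(f"\nreports written to {outdir}:")
for path in sorted(outdir.iterdir()):
    print(f"  {path.name}")
print("\nEvery table cell traces back to a fit object; rerunning with the"
      "\nsame seed reproduces the report files byte for byte.")
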