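"""Generate a synthetic leaf-spectra study and partition it with SPXY.

Emulates the sampling design of a greenhouse nitrogen-stress trial (ten
nitrogen treatments, three growth stages, 735 leaf samples), draws per-sample
mean reflectance spectra on the 646-channel 430-900 nm grid, and splits them
3:1 into calibration and prediction sets with the joint x-y distance (SPXY)
algorithm.
"""

import leafspec as ls

design = ls.tomato_trial_design()
rows = ls.enumerate_design(design)
print(f"sampling design: {len(rows)} samples, {design.n_leaves} leaves")
print(rows.groupby("stage").size().to_string(), "\n")

cfg = ls.SimulationConfig(seed=42, n_samples=design.n_samples)
table, response = ls.simulate_spectra(cfg)
print(f"spectra: {table.n_samples} x {table.n_channels} channels "
      f"({table.grid.centers[0]:.1f}-{table.grid.centers[-1]:.1f} nm)")

split = ls.spxy_split(table, response, ratio=3.0)
print(f"SPXY 3:1 split: {split.calibration.size} calibration / "
      f"{split.prediction.size} prediction samples\n")

# per-set reference-value statistics (nitrogen, % dry mass)
print(ls.dataset_summary(response, split).round(4).to_string(index=False))
# The calibration set spans the full response range (max/min live there):
# SPXY picks boundary samples first, so extremes land in calibration.
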