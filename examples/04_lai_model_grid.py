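"""Fit the 15-combination x 3-model LAI estimation grid and map one plot.

Runs the full default pipeline (90 plots), then prints the validation
metrics of the XGBoost column and renders a per-pixel LAI inversion map for
one validation plot with the best cell's model.
"""

import numpy as np

import texlai

cfg = texlai.RunConfig(outdir="scratch/example_run", generator_seed=42, split_seed=43)
out = texlai.run_all(cfg)

grid = out["grid"]
xgb = grid[grid.model == "XGBoost"]
print("XGBoost validation metrics by input combination:")
print(
    xgb[["combination", "validation_R2", "validation_RMSE", "validation_MRE_pct"]]
    .round(3)
    .to_string(index=False)
)
combo, model = out["best_cell"]
print(f"\nbest cell: {combo} / {model}")

import tifffile

lai_map = tifffile.imread(out["map_path"])
vals = lai_map[np.isfinite(lai_map)]
print(f"inversion map of one validation plot: mean predicted LAI "
      f"{vals.mean():.2f} (spread {vals.min():.2f} - {vals.max():.2f})")
print("R^2 close to 1 with low RMSE/MRE means the fused spectral + texture")
print("inputs recover the latent LAI that generated the scenes.")
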