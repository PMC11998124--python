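"""Generate a synthetic landscape and inspect its structure.

The generator builds a 10-m DEM with depressions, a soil map-unit raster
with a multi-component attribute table, a multi-date speckled SAR stack,
binary wetland labels tied to pipeline-computed wetness predictors, and
a 30-m cropland mask — all deterministic under the configured seed.
"""

import numpy as np

from wetpot import SceneConfig, generate_scene

cfg = SceneConfig(n_rows=120, n_cols=120, seed=42)
bundle = generate_scene(cfg)

dem = bundle.dem
print(f"DEM: {dem.n_rows}x{dem.n_cols} cells at {dem.cell_size:.0f} m, "
      f"relief {dem.values.max() - dem.values.min():.1f} m")
print(f"soil map units: {len(bundle.soil_table.unit_keys())}, "
      f"{len(bundle.soil_table.df)} component records")
print(f"SAR stack: {len(bundle.sar_stack)} dates, mean VV "
      f"{np.mean([vv.values.mean() for _, vv, _ in bundle.sar_stack]):.1f} dB")
prev = (bundle.labels.values == 1).mean()
print(f"wetland prevalence: {prev:.3f} (target {cfg.target_prevalence})")
print(f"cropland fraction (30 m): {(bundle.cropland_30m.values == 1).mean():.3f}")
print(f"label threshold on latent suitability: {bundle.truth.threshold:.3f}")

# The prevalence lands on the target by construction: labels are the cells
# whose suitability score exceeds the matching quantile.
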