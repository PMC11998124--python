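"""Connectivity clusters and the cropland intersection.

Predicted wetland cells are grouped into 8-connected components
(corner contact merges), summarized by cluster-area statistics, and
intersected with the 30-m cropland mask to flag candidate restoration
sites on cultivated land (PWA–C).
"""

import numpy as np

from wetpot import (Grid, SceneConfig, areal_summary, cluster_stats,
                    cropland_overlay, gen_cropland, region_group)

rng = np.random.default_rng(9)
pwa = Grid((rng.uniform(size=(120, 120)) < 0.3).astype(np.int32), 10.0)

labeled, table = region_group(pwa)
stats = cluster_stats(table, pwa.cell_size)
print(f"{stats.n_clusters} clusters; mean {stats.mean * 1e6:.0f} m2, "
      f"median {stats.median * 1e6:.0f} m2, max {stats.max:.4f} km2")
print(f"share of wetland area in single-pixel clusters: "
      f"{stats.single_pixel_proportion:.2f}")

crop = gen_cropland(SceneConfig(n_rows=120, n_cols=120, seed=9,
                                cropland_fraction=0.3))
pwac = cropland_overlay(pwa, crop)
region = pwa.like(np.ones(pwa.shape, dtype=np.int32))
pwa_cov = areal_summary(pwa, region).iloc[0]
pwac_cov = areal_summary(pwac, region).iloc[0]
print(f"PWA covers {pwa_cov['class_pct']:.1f}% of the scene "
      f"({pwa_cov['class_km2']:.3f} km2)")
print(f"PWA on cropland covers {pwac_cov['class_pct']:.1f}% "
      f"({pwac_cov['class_km2']:.3f} km2)")

# PWA-C is the cell-wise intersection, so its area can never exceed
# either the wetland prediction or the cropland mask.
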