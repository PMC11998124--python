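"""Post-processing: connectivity clusters, cropland intersection, area summaries.

Predicted wetland cells are grouped into 8-connected components (any side
or vertex contact merges cells; nodata is a barrier, never connective),
summarized by cluster-size statistics, and intersected with a 3×-coarser
cropland mask to highlight candidate restoration sites on cultivated land.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import Grid, GridError, INT_NODATA

_EIGHT = np.ones((3, 3), dtype=int)


def region_group(binary: Grid) -> tuple[Grid, pd.DataFrame]:
    """Label maximal 8-connected components of 1-cells.

    Returns the labeled grid (labels 1..K, 0 elsewhere, nodata preserved)
    and a cluster table with columns ``cluster_id``, ``pixel_count`` and
    ``area_km2`` (pixel count × cell area).
    """
    vals = np.asarray(binary.values)
    valid = binary.valid_mask()
    ones = valid & (vals == 1)
    if not set(np.unique(vals[valid]).tolist()) <= {0, 1}:
        raise GridError("binary grid must contain only 0, 1 and nodata")
    labeled, k = ndimage.label(ones, structure=_EIGHT)
    counts = np.bincount(labeled.ravel(), minlength=k + 1)[1:]
    cell_area_km2 = binary.cell_size**2 / 1e6
    table = pd.DataFrame({
        "cluster_id": np.arange(1, k + 1, dtype=np.int64),
        "pixel_count": counts.astype(np.int64),
        "area_km2": counts * cell_area_km2,
    })
    out = labeled.astype(np.int32)
    out[~valid] = INT_NODATA
    return binary.like(out, units=""), table


@dataclass(frozen=True)
class ClusterStats:
    """Summary statistics over cluster areas (km²)."""

    n_clusters: int
    min: float
    max: float
    mean: float
    median: float
    p5: float
    p95: float
    sd: float
    single_pixel_proportion: float  # share of class area in 1-pixel clusters

    def as_dict(self) -> dict[str, float]:
        return {
            "n_clusters": self.n_clusters, "min_km2": self.min,
            "max_km2": self.max, "mean_km2": self.mean,
            "median_km2": self.median, "p5_km2": self.p5,
            "p95_km2": self.p95, "sd_km2": self.sd,
            "single_pixel_proportion": self.single_pixel_proportion,
        }


def cluster_stats(table: pd.DataFrame, cell_size: float) -> ClusterStats:
    """Statistics over cluster areas; percentiles by linear interpolation.

    The single-pixel proportion is the area in 1-pixel clusters divided by
    the total class area (on a 10-m grid a single pixel is 0.0001 km²).
    """
    if len(table) == 0:
        raise GridError("empty cluster table")
    areas = table["area_km2"].to_numpy(dtype=np.float64)
    counts = table["pixel_count"].to_numpy()
    total_pixels = counts.sum()
    single = counts[counts == 1].sum()
    return ClusterStats(
        n_clusters=len(table),
        min=float(areas.min()),
        max=float(areas.max()),
        mean=float(areas.mean()),
        median=float(np.percentile(areas, 50)),
        p5=float(np.percentile(areas, 5)),
        p95=float(np.percentile(areas, 95)),
        sd=float(areas.std(ddof=0)),
        single_pixel_proportion=float(single / total_pixels),
    )


def cropland_overlay(pwa: Grid, cropland_30m: Grid) -> Grid:
    """Intersect predicted wetland area with the coarse cropland mask.

    The cropland grid must sit on exactly 3× the PWA cell size with the
    same origin; each coarse cell paints its 3×3 block (nearest-neighbor
    resampling). Output is 1 where both PWA and cropland are 1, else 0;
    PWA nodata propagates.
    """
    ratio = cropland_30m.cell_size / pwa.cell_size
    if not math.isclose(ratio, 3.0, rel_tol=1e-9):
        raise GridError(f"cropland resolution must be 3x the PWA grid "
                        f"(got ratio {ratio})")
    if cropland_30m.origin != pwa.origin:
        raise GridError("cropland grid origin differs from the PWA grid")
    if (cropland_30m.n_rows * 3, cropland_30m.n_cols * 3) != pwa.shape:
        raise GridError("cropland extent does not cover the PWA grid")
    crop_fine = np.kron(np.asarray(cropland_30m.values) == 1,
                        np.ones((3, 3), dtype=bool))
    pwa_vals = np.asarray(pwa.values)
    valid = pwa.valid_mask()
    out = ((pwa_vals == 1) & crop_fine & valid).astype(np.int32)
    out[~valid] = INT_NODATA
    return pwa.like(out, units="")


def areal_summary(class_grid: Grid, region_mask: Grid) -> pd.DataFrame:
    """Class area and percent cover per region.

    ``region_mask`` holds integer region ids (nodata = outside). Returns
    a DataFrame with ``region``, ``region_km2``, ``class_km2`` and
    ``class_pct`` rows per region id.
    """
    if not class_grid.aligned_with(region_mask):
        raise GridError("region mask is not aligned with the class grid")
    regions = np.asarray(region_mask.values)
    rvalid = region_mask.valid_mask()
    cvals = np.asarray(class_grid.values)
    cvalid = class_grid.valid_mask()
    cell_km2 = class_grid.cell_size**2 / 1e6
    rows = []
    for rid in np.unique(regions[rvalid]):
        sel = rvalid & (regions == rid)
        n_region = int(sel.sum())
        if n_region == 0:
            raise GridError(f"region {rid} is empty")
        n_class = int((sel & cvalid & (cvals == 1)).sum())
        rows.append({
            "region": int(rid),
            "region_km2": n_region * cell_km2,
            "class_km2": n_class * cell_km2,
            "class_pct": 100.0 * n_class / n_region,
        })
    if not rows:
        raise GridError("region mask contains no regions")
    return pd.DataFrame(rows)
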