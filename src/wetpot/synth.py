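"""Synthetic landscape generator.

Produces aligned desk-scale stand-ins for the pipeline's continental
inputs — a DEM with pits, a soil map-unit raster with a multi-component
attribute table, a multi-date speckled SAR backscatter stack, binary
wetland labels, and a coarse cropland mask — under a known generative
rule, so every downstream stage (and end-to-end parameter recovery) is
testable without any downloads.

The coupling variable is a latent *wetness* field: the smoothed negative
relative elevation. Soils are wetter-drained, SAR backscatter is lower,
and wetland labels are more likely where wetness is high. Labels are
generated from the pipeline-computed CTI/PWS/VOFD rasters (not from the
latent field directly) so that recovering the generative weights
exercises the whole chain. The full bundle is a pure function of its
:class:`SceneConfig` — identical configs yield byte-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .grids import Grid, GridError
from .features import SoilComponentTable
from . import terrain


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one synthetic scene.

    Defaults describe a 256×256 cell (2.56 km square) 10-m landscape with
    moderate relief, a quarter of the land labeled wetland, and SAR
    speckle equivalent to a 5-look product.
    """

    n_rows: int = 240
    n_cols: int = 240
    cell_size: float = 10.0
    seed: int = 0
    relief: float = 30.0              # m, min-to-max of the random surface
    smoothness: float = 12.0          # correlation length, cells
    n_pits: int = 20
    n_map_units: int = 40
    components_per_unit: int = 3
    n_sar_dates: int = 12
    speckle_looks: float = 5.0
    effect_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)  # CTI, PWS, VOFD
    noise_sd: float = 0.25
    target_prevalence: float = 0.25
    cropland_fraction: float = 0.30
    temporal_sd: float = 0.5          # dB, date-to-date backscatter level shifts
    pwsl_only_fraction: float = 0.15  # units carrying only the PWSL fallback
    channel_threshold_cells: int | None = None  # None -> max(cells/100, 25)

    def __post_init__(self) -> None:
        if min(self.n_rows, self.n_cols, self.n_pits + 1, self.n_map_units,
               self.components_per_unit, self.n_sar_dates) < 1:
            raise GridError("all scene counts must be >= 1")
        if not (0.0 < self.target_prevalence < 1.0):
            raise GridError("target_prevalence must be in (0, 1)")
        if not (0.0 <= self.cropland_fraction <= 1.0):
            raise GridError("cropland_fraction must be in [0, 1]")
        if self.noise_sd < 0 or self.speckle_looks <= 0:
            raise GridError("noise_sd must be >= 0 and speckle_looks > 0")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent, reproducible stream for one generation stage."""
        return np.random.default_rng([self.seed % 2**31, stage])

    def threshold_cells(self) -> int:
        if self.channel_threshold_cells is not None:
            return self.channel_threshold_cells
        return max(self.n_rows * self.n_cols // 100, 25)


@dataclass
class SceneTruth:
    """Generative record for parameter-recovery checks."""

    suitability: Grid                  # the latent score s
    threshold: float
    weights: tuple[float, float, float]
    wetness: Grid


@dataclass
class SceneBundle:
    """All aligned synthetic inputs plus the generative truth record."""

    config: SceneConfig
    dem: Grid
    soil_map_unit_raster: Grid
    soil_table: SoilComponentTable
    sar_stack: list[tuple[str, Grid, Grid]]
    labels: Grid
    cropland_30m: Grid | None  # None when dims are not divisible by 3
    truth: SceneTruth
    terrain_layers: dict[str, Grid] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Elementary fields
# ---------------------------------------------------------------------------

def gen_dem(cfg: SceneConfig) -> Grid:
    """Correlated random surface + regional tilt, with carved single-cell pits.

    The base surface is white noise smoothed at the configured correlation
    length and scaled so its range equals ``relief``; a southward tilt of
    0.5 % keeps the landscape draining. ``n_pits`` well-separated interior
    cells are then lowered 1 m below their lowest neighbor.
    """
    rng = cfg.rng(1)
    shape = (cfg.n_rows, cfg.n_cols)
    if cfg.relief > 0:
        base = gaussian_filter(rng.standard_normal(shape), sigma=cfg.smoothness,
                               mode="reflect")
        lo, hi = base.min(), base.max()
        base = (base - lo) / (hi - lo) * cfg.relief if hi > lo else np.zeros(shape)
    else:
        base = np.zeros(shape)
    rows = np.arange(cfg.n_rows, dtype=np.float64)[:, None]
    tilt = 0.005 * cfg.cell_size * (cfg.n_rows - 1 - rows)  # south edge lowest
    z = base + np.broadcast_to(tilt, shape).copy()

    # carve pits at interior cells, at least 3 cells apart
    chosen: list[tuple[int, int]] = []
    interior_r = np.arange(2, cfg.n_rows - 2)
    interior_c = np.arange(2, cfg.n_cols - 2)
    attempts = 0
    while len(chosen) < cfg.n_pits and attempts < 100 * cfg.n_pits:
        attempts += 1
        r = int(rng.choice(interior_r))
        c = int(rng.choice(interior_c))
        if all(max(abs(r - rr), abs(c - cc)) >= 3 for rr, cc in chosen):
            chosen.append((r, c))
    if len(chosen) < cfg.n_pits:
        raise GridError("could not place the requested number of pits")
    for r, c in chosen:
        nb_min = min(z[r + dr, c + dc] for dr, dc in terrain.NEIGHBOR_OFFSETS)
        z[r, c] = nb_min - 1.0
    return Grid(z, cfg.cell_size, (0.0, 0.0), units="m")


def compute_wetness(dem: Grid, cfg: SceneConfig) -> Grid:
    """Latent wetness: standardized, smoothed negative relative elevation.

    High where the surface sits below its neighborhood mean (valley
    bottoms, depressions), standardized to zero mean and unit variance.
    """
    z = np.asarray(dem.values, dtype=np.float64)
    rel = gaussian_filter(z, sigma=cfg.smoothness, mode="reflect") - z
    w = gaussian_filter(rel, sigma=max(cfg.smoothness / 4.0, 1.0), mode="reflect")
    sd = w.std()
    w = (w - w.mean()) / sd if sd > 0 else np.zeros_like(w)
    return dem.like(w, units="z")


# ---------------------------------------------------------------------------
# Soils
# ---------------------------------------------------------------------------

_DRY_CLASSES = ("excessively", "somewhat-excessively", "well",
                "moderately-well", "somewhat-poorly")


def gen_soils(cfg: SceneConfig, wetness: Grid) -> tuple[Grid, SoilComponentTable]:
    """Voronoi map units with wetness-coupled component attributes.

    Map units are the Voronoi cells of ``n_map_units`` random seed points.
    Each unit gets ``components_per_unit`` components whose percents sum
    to 100; the probability that a component is poorly/very-poorly drained
    or hydric rises with the unit's mean wetness rank. A configurable
    fraction of units carries only a PWSL value (drainage and hydric
    unknown) to exercise the fallback path.
    """
    rng = cfg.rng(2)
    shape = (cfg.n_rows, cfg.n_cols)
    seeds = np.column_stack([rng.uniform(0, cfg.n_rows, cfg.n_map_units),
                             rng.uniform(0, cfg.n_cols, cfg.n_map_units)])
    rr, cc = np.meshgrid(np.arange(cfg.n_rows), np.arange(cfg.n_cols),
                         indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    _, unit_idx = cKDTree(seeds).query(pts)
    mu = (unit_idx.reshape(shape) + 1).astype(np.int32)  # unit keys 1..n

    w = np.asarray(wetness.values, dtype=np.float64)
    unit_ids = np.arange(1, cfg.n_map_units + 1)
    mean_w = np.array([w[mu == u].mean() if (mu == u).any() else 0.0
                       for u in unit_ids])
    rank = mean_w.argsort().argsort() / max(len(unit_ids) - 1, 1)  # [0, 1]

    n_pwsl_only = int(round(cfg.pwsl_only_fraction * cfg.n_map_units))
    pwsl_only = set(rng.choice(unit_ids, size=n_pwsl_only, replace=False).tolist())

    records = []
    for u, q in zip(unit_ids, rank):
        percents = rng.dirichlet(np.ones(cfg.components_per_unit)) * 100.0
        p_wet = float(np.clip(0.05 + 0.9 * q, 0.0, 1.0))
        for pct in percents:
            if u in pwsl_only:
                records.append((int(u), float(pct), "unknown", "unknown",
                                float(np.clip(100.0 * (q + rng.normal(0, 0.05)),
                                              0.0, 100.0))))
                continue
            if rng.uniform() < p_wet:
                drainage = rng.choice(["poorly", "very-poorly"])
            else:
                drainage = rng.choice(_DRY_CLASSES)
            hydric = "yes" if rng.uniform() < 0.5 * p_wet else "no"
            records.append((int(u), float(pct), str(drainage), hydric, np.nan))
    df = pd.DataFrame(records, columns=["map_unit", "component_percent",
                                        "drainage_class", "hydric",
                                        "pwsl_percent"])
    return wetness.like(mu, units=""), SoilComponentTable(df)


# ---------------------------------------------------------------------------
# SAR stack
# ---------------------------------------------------------------------------

def gen_sar_stack(cfg: SceneConfig, wetness: Grid) -> list[tuple[str, Grid, Grid]]:
    """Multi-date dual-pol backscatter: wetter cells darker, plus speckle.

    Per date, clean backscatter (dB) is a base level minus a gain times
    the wetness rank, shifted by a per-date level offset (acquisition
    conditions); gamma multiplicative speckle of mean 1 and variance
    ``1/speckle_looks`` is applied in linear power and converted back to
    dB. VH sits below VV with a slightly larger wetness gain.
    """
    rng = cfg.rng(3)
    w = np.asarray(wetness.values, dtype=np.float64)
    order = w.ravel().argsort().argsort()
    wet01 = (order / max(order.size - 1, 1)).reshape(w.shape)

    stack: list[tuple[str, Grid, Grid]] = []
    for t in range(cfg.n_sar_dates):
        offset = rng.normal(0.0, cfg.temporal_sd)
        vv_db = -8.0 - 6.0 * wet01 + offset
        vh_db = -14.0 - 8.0 * wet01 + offset
        out = []
        for band_db in (vv_db, vh_db):
            power = 10.0 ** (band_db / 10.0)
            speckle = rng.gamma(cfg.speckle_looks, 1.0 / cfg.speckle_looks,
                                size=power.shape)
            out.append(10.0 * np.log10(power * speckle))
        stack.append((f"date_{t:02d}",
                      wetness.like(out[0], units="dB"),
                      wetness.like(out[1], units="dB")))
    return stack


# ---------------------------------------------------------------------------
# Labels and cropland
# ---------------------------------------------------------------------------

def _zscore(grid: Grid) -> np.ndarray:
    vals = np.asarray(grid.values, dtype=np.float64)
    valid = grid.valid_mask()
    if not valid.any():
        raise GridError("label input grid contains only nodata")
    v = vals[valid]
    sd = v.std()
    out = np.full(grid.shape, np.nan)
    out[valid] = (vals[valid] - v.mean()) / (sd if sd > 0 else 1.0)
    return out


def gen_labels(cfg: SceneConfig, cti: Grid, pws: Grid,
               vofd: Grid) -> tuple[Grid, SceneTruth]:
    """Binary wetland labels from a weighted suitability score.

    ``s = w_cti·z(CTI) + w_pws·z(PWS) − w_vofd·z(VOFD) + ε`` with
    ``ε ~ N(0, noise_sd)``; cells above the quantile threshold that yields
    ``target_prevalence`` are labeled 1. The score grid and threshold are
    returned for parameter-recovery tests.
    """
    rng = cfg.rng(4)
    w_cti, w_pws, w_vofd = cfg.effect_weights
    s = (w_cti * _zscore(cti) + w_pws * _zscore(pws) - w_vofd * _zscore(vofd))
    valid = ~np.isnan(s)
    if cfg.noise_sd > 0:
        s = s + rng.normal(0.0, cfg.noise_sd, size=s.shape)
        s[~valid] = np.nan
    thr = float(np.quantile(s[valid], 1.0 - cfg.target_prevalence))
    from .grids import INT_NODATA

    labels = np.where(valid, (s > thr).astype(np.int32), INT_NODATA)
    truth = SceneTruth(cti.like(s, units=""), thr, cfg.effect_weights,
                       wetness=cti.like(np.full(cti.shape, np.nan)))
    return cti.like(labels, units=""), truth


def gen_cropland(cfg: SceneConfig) -> Grid:
    """Blobby binary cropland mask on a 3×-coarser aligned grid.

    A smoothed noise field is thresholded at the quantile matching
    ``cropland_fraction``, producing contiguous blobs whose realized
    fraction is within rounding of the target.
    """
    if cfg.n_rows % 3 or cfg.n_cols % 3:
        raise GridError("scene dimensions must be divisible by 3 for the "
                        "30-m cropland grid")
    rng = cfg.rng(5)
    shape = (cfg.n_rows // 3, cfg.n_cols // 3)
    if cfg.cropland_fraction == 0.0:
        vals = np.zeros(shape, dtype=np.int32)
    elif cfg.cropland_fraction == 1.0:
        vals = np.ones(shape, dtype=np.int32)
    else:
        f = gaussian_filter(rng.standard_normal(shape), sigma=4.0, mode="reflect")
        thr = np.quantile(f, 1.0 - cfg.cropland_fraction)
        vals = (f > thr).astype(np.int32)
    return Grid(vals, cfg.cell_size * 3.0, (0.0, 0.0), units="")


# ---------------------------------------------------------------------------
# Full scene
# ---------------------------------------------------------------------------

def generate_scene(cfg: SceneConfig) -> SceneBundle:
    """Generate the full aligned input bundle for one synthetic scene.

    Runs the real terrain pipeline (pit removal, D-infinity routing,
    accumulation, channels with outlets-as-channels, VOFD, CTI) on the
    generated DEM so the wetland labels are tied to pipeline-computed
    predictors, then derives soils-, SAR- and cropland layers from the
    shared latent wetness field.
    """
    dem = gen_dem(cfg)
    wetness = compute_wetness(dem, cfg)
    mu_raster, soil_table = gen_soils(cfg, wetness)
    sar = gen_sar_stack(cfg, wetness)

    filled = terrain.remove_pits(dem, epsilon=1e-4)
    flow = terrain.dinf_flow_direction(filled)
    acc = terrain.dinf_accumulation(flow)
    channels = terrain.extract_channels(acc, cfg.threshold_cells())
    vofd = terrain.distance_down(flow, filled, channels, "vertical",
                                 outlets_as_channels=True)
    cti = terrain.compute_cti(acc, flow.slope_grid())

    from .features import compute_pws

    pws = compute_pws(mu_raster, soil_table)
    labels, truth = gen_labels(cfg, cti, pws, vofd)
    truth.wetness = wetness
    # the 30-m cropland grid only tiles scenes divisible by 3
    divisible = cfg.n_rows % 3 == 0 and cfg.n_cols % 3 == 0
    cropland = gen_cropland(cfg) if divisible else None

    terrain_layers = {"filled_dem": filled, "accumulation": acc,
                      "vofd": vofd, "cti": cti,
                      "channels": channels.mask}
    return SceneBundle(cfg, dem, mu_raster, soil_table, sar, labels,
                       cropland, truth, terrain_layers)
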