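"""Non-topographic predictors and the 17-layer feature stack.

* PWS (potential wetland soils): percent of each soil map unit covered by
  poorly/very-poorly drained or hydric components, with the survey's
  "potential wetland soil landscapes" (PWSL) percentage as a fallback for
  units lacking drainage/hydric information.
* SAR temporal percentiles: per-cell 10th/50th/90th percentiles of the VV
  and VH backscatter series and of their band ratio.
* Wetland label reclassification from subsystem categories to a binary
  {wetland=1, non-wetland=0, nodata} raster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import Grid, GridError, INT_NODATA, require_aligned

#: Predictor layer names, in stack order.
FEATURE_NAMES: tuple[str, ...] = (
    "VV10", "VV50", "VV90",
    "VH10", "VH50", "VH90",
    "VVVH10", "VVVH50", "VVVH90",
    "Elevation", "Slope", "Aspect", "CTI",
    "HOFD", "VOFD", "POFD",
    "PWS",
)

WET_DRAINAGE_CLASSES = frozenset({"poorly", "very-poorly"})
DRAINAGE_CLASSES = frozenset({
    "excessively", "somewhat-excessively", "well", "moderately-well",
    "somewhat-poorly", "poorly", "very-poorly", "unknown",
})


# ---------------------------------------------------------------------------
# Soil component table and PWS
# ---------------------------------------------------------------------------

@dataclass
class SoilComponentTable:
    """Soil component records keyed by map unit.

    Columns: ``map_unit`` (integer key), ``component_percent`` (0–100),
    ``drainage_class`` (one of :data:`DRAINAGE_CLASSES`), ``hydric``
    ({yes, no, unknown}), ``pwsl_percent`` (0–100 or NaN). Per-unit
    component percents must not exceed 100.
    """

    df: pd.DataFrame

    REQUIRED = ("map_unit", "component_percent", "drainage_class",
                "hydric", "pwsl_percent")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise GridError(f"soil table missing columns: {missing}")
        bad_dr = set(self.df["drainage_class"]) - DRAINAGE_CLASSES
        if bad_dr:
            raise GridError(f"unknown drainage classes: {sorted(bad_dr)}")
        bad_hy = set(self.df["hydric"]) - {"yes", "no", "unknown"}
        if bad_hy:
            raise GridError(f"unknown hydric ratings: {sorted(bad_hy)}")
        if (self.df["component_percent"] < 0).any():
            raise GridError("component_percent must be >= 0")
        sums = self.df.groupby("map_unit")["component_percent"].sum()
        if (sums > 100 + 1e-6).any():
            over = sums[sums > 100 + 1e-6].index.tolist()
            raise GridError(f"component percents exceed 100 for units {over}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SoilComponentTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> Path:
        self.df.to_csv(path, index=False)
        return Path(path)

    def unit_keys(self) -> np.ndarray:
        return self.df["map_unit"].unique()


def pws_by_unit(table: SoilComponentTable) -> pd.Series:
    """Per-map-unit PWS percent (NaN where neither rule nor fallback applies).

    A component contributes its percent once if its drainage class is
    poorly/very-poorly drained OR its hydric rating is yes. Units where
    every component has unknown drainage and unknown hydric fall back to
    the unit's PWSL percent. The sum is capped at 100.
    """
    df = table.df
    eligible = df["drainage_class"].isin(WET_DRAINAGE_CLASSES) | (df["hydric"] == "yes")
    informative = (df["drainage_class"] != "unknown") | (df["hydric"] != "unknown")

    out = {}
    for unit, grp in df.groupby("map_unit"):
        if informative.loc[grp.index].any():
            out[unit] = min(100.0, float(grp.loc[eligible.loc[grp.index],
                                                 "component_percent"].sum()))
        else:
            pwsl = grp["pwsl_percent"].dropna()
            out[unit] = float(pwsl.iloc[0]) if len(pwsl) else np.nan
    return pd.Series(out, name="pws")


def compute_pws(mu_raster: Grid, table: SoilComponentTable) -> Grid:
    """Paint per-unit PWS percentages onto the map-unit raster.

    Raster keys absent from the table are reported via a warning and their
    cells become nodata.
    """
    per_unit = pws_by_unit(table)
    keys = np.asarray(mu_raster.values)
    valid = mu_raster.valid_mask()
    present = np.unique(keys[valid])
    missing = sorted(set(present.tolist()) - set(per_unit.index.tolist()))
    if missing:
        warnings.warn(f"map units absent from soil table: {missing}", stacklevel=2)
    lut = per_unit.reindex(present)
    mapping = dict(zip(present.tolist(), lut.to_numpy()))
    out = np.full(mu_raster.shape, np.nan)
    for key, val in mapping.items():
        out[(keys == key) & valid] = val
    return mu_raster.like(out, units="%")


# ---------------------------------------------------------------------------
# SAR temporal percentiles
# ---------------------------------------------------------------------------

def sar_percentiles(stack: Sequence[tuple[Grid, Grid]],
                    ratio_scale: str = "db-diff") -> dict[str, Grid]:
    """Per-cell temporal percentiles of VV, VH, and the VV/VH band ratio.

    ``stack`` is a sequence of per-date (VV, VH) grid pairs in dB. The
    ratio series is the dB difference VV − VH (the linear power ratio
    expressed in dB) by default, or the linear ratio with
    ``ratio_scale="linear"``. Percentiles (10/50/90) use linear
    interpolation between order statistics; cells with fewer than two
    valid dates are nodata.
    """
    if len(stack) == 0:
        raise GridError("empty SAR stack")
    if len(stack) < 2:
        raise GridError("SAR percentiles need at least 2 dates")
    if ratio_scale not in ("db-diff", "linear"):
        raise GridError(f"unknown ratio_scale {ratio_scale!r}")
    ref = stack[0][0]
    for vv, vh in stack:
        require_aligned(ref, vv, vh)
    vv_arr = np.stack([np.asarray(vv.values, dtype=np.float64) for vv, _ in stack])
    vh_arr = np.stack([np.asarray(vh.values, dtype=np.float64) for _, vh in stack])
    if ratio_scale == "db-diff":
        ratio = vv_arr - vh_arr
    else:
        ratio = 10.0 ** (vv_arr / 10.0) / 10.0 ** (vh_arr / 10.0)
    # a date is valid for the ratio only when both bands are
    ratio[np.isnan(vv_arr) | np.isnan(vh_arr)] = np.nan

    out: dict[str, Grid] = {}
    for band, arr in (("VV", vv_arr), ("VH", vh_arr), ("VVVH", ratio)):
        n_valid = np.sum(~np.isnan(arr), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pct = np.nanpercentile(arr, [10, 50, 90], axis=0)
        pct[:, n_valid < 2] = np.nan
        for p, name in zip(pct, ("10", "50", "90")):
            out[f"{band}{name}"] = ref.like(p, units="dB")
    return out


# ---------------------------------------------------------------------------
# Wetland label reclassification
# ---------------------------------------------------------------------------

#: Default designation of wetland-inventory subsystems.
DEFAULT_SUBSYSTEM_MAPPING: dict[str, str] = {
    # wetland class
    "Riverine intermittent": "wetland",
    "Lacustrine littoral": "wetland",
    "Palustrine aquatic bed": "wetland",
    "Palustrine farmed": "wetland",
    "Palustrine forested": "wetland",
    "Palustrine moss-lichen": "wetland",
    "Palustrine rock bottom": "wetland",
    "Palustrine scrub-shrub": "wetland",
    "Palustrine unconsolidated bottom": "wetland",
    "Lacustrine diked/impounded": "wetland",
    "Lacustrine excavated": "wetland",
    # non-wetland (deep/open water systems)
    "Marine subtidal": "non-wetland",
    "Marine intertidal": "non-wetland",
    "Estuarine subtidal": "non-wetland",
    "Estuarine intertidal": "non-wetland",
    # excluded from training
    "Riverine tidal": "not-included",
    "Riverine lower perennial": "not-included",
    "Riverine upper perennial": "not-included",
    "Riverine unknown": "not-included",
    "Lacustrine limnetic": "not-included",
    "Lacustrine": "not-included",
}

_CLASS_VALUES = {"wetland": 1, "non-wetland": 0, "not-included": None}


def reclass_wetlands(subsystem_raster: Grid,
                     categories: Mapping[int, str],
                     mapping: Mapping[str, str] | None = None) -> Grid:
    """Reclassify a categorical subsystem raster to binary wetland labels.

    ``categories`` maps raster codes to subsystem names; ``mapping`` maps
    names to {wetland, non-wetland, not-included} (default
    :data:`DEFAULT_SUBSYSTEM_MAPPING`). Wetland → 1, non-wetland → 0,
    not-included → nodata; background cells outside every mapped category
    (the raster's nodata) → 0.
    """
    if mapping is None:
        mapping = DEFAULT_SUBSYSTEM_MAPPING
    codes = np.asarray(subsystem_raster.values)
    valid = subsystem_raster.valid_mask()
    present = np.unique(codes[valid])
    out = np.zeros(subsystem_raster.shape, dtype=np.int32)  # background = 0
    for code in present.tolist():
        if code not in categories:
            raise GridError(f"raster code {code} missing from the category table")
        name = categories[code]
        if name not in mapping:
            raise GridError(f"unmapped subsystem category {name!r}")
        cls = mapping[name]
        if cls not in _CLASS_VALUES:
            raise GridError(f"unknown class {cls!r} for category {name!r}")
        value = _CLASS_VALUES[cls]
        sel = (codes == code) & valid
        out[sel] = INT_NODATA if value is None else value
    return subsystem_raster.like(out, units="")


# ---------------------------------------------------------------------------
# Stack assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureStack:
    """The ordered 17-layer predictor stack with a shared validity mask.

    Cells that are nodata in *any* layer are masked everywhere
    (complete-case predictor matrix).
    """

    layers: dict[str, Grid]
    mask: np.ndarray = field(repr=False, default=None)  # True = usable

    @property
    def names(self) -> tuple[str, ...]:
        return FEATURE_NAMES

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[FEATURE_NAMES[0]].shape

    @property
    def cell_size(self) -> float:
        return self.layers[FEATURE_NAMES[0]].cell_size

    def __len__(self) -> int:
        return len(self.layers)

    def matrix(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n, 17) float matrix of feature values at the given cells."""
        out = np.empty((len(rows), len(FEATURE_NAMES)))
        for j, name in enumerate(FEATURE_NAMES):
            out[:, j] = np.asarray(self.layers[name].values,
                                   dtype=np.float64)[rows, cols]
        return out


def assemble_stack(layers: Mapping[str, Grid]) -> FeatureStack:
    """Validate names and alignment, and derive the complete-case mask."""
    missing = [n for n in FEATURE_NAMES if n not in layers]
    if missing:
        raise GridError(f"missing feature layers: {missing}")
    extra = [n for n in layers if n not in FEATURE_NAMES]
    if extra:
        raise GridError(f"unexpected feature layers: {extra}")
    ref = layers[FEATURE_NAMES[0]]
    mask = np.ones(ref.shape, dtype=bool)
    for name in FEATURE_NAMES:
        g = layers[name]
        if not ref.aligned_with(g):
            raise GridError(f"layer {name!r} is misaligned")
        mask &= g.valid_mask()
    return FeatureStack({n: layers[n] for n in FEATURE_NAMES}, mask)
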