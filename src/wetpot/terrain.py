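"""Terrain hydrology: pit removal, D-infinity routing, and derived predictors.

Implements the topographic half of the predictor set: pit-filled elevation,
D-infinity flow direction and accumulation (Tarboton's triangular-facet
construction), channel extraction by an accumulation threshold, the three
channel-referenced distance-down measures (HOFD, VOFD, POFD), the compound
topographic index (CTI), and 4-neighbor slope/aspect.

Conventions
-----------
* Flow angles are radians counter-clockwise from east in ``[0, 2π)``.
* Flats are resolved inside :func:`remove_pits` by priority-flood filling
  with an epsilon increment, so routing never sees a flat.
* A valid cell bordering the grid edge or a nodata cell with no in-grid
  downslope neighbor is an *outlet*: its accumulated flow leaves the grid.
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .grids import Grid, GridError, focal_mean3

# 8-neighborhood, indexed counter-clockwise from east.
# (dr, dc) with row 0 north: E, NE, N, NW, W, SW, S, SE
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
)
NEIGHBOR_ANGLES = tuple(k * math.pi / 4 for k in range(8))
_SQRT2 = math.sqrt(2.0)
NEIGHBOR_DISTS = tuple(_SQRT2 if dr and dc else 1.0 for dr, dc in NEIGHBOR_OFFSETS)

# Triangular facets as (cardinal index, diagonal index, orientation):
# the facet spans 45° from the cardinal toward the diagonal neighbor;
# orientation +1 means the diagonal is counter-clockwise of the cardinal.
_FACETS: tuple[tuple[int, int, int], ...] = (
    (0, 1, +1),  # E  -> NE
    (2, 1, -1),  # N  -> NE
    (2, 3, +1),  # N  -> NW
    (4, 3, -1),  # W  -> NW
    (4, 5, +1),  # W  -> SW
    (6, 5, -1),  # S  -> SW
    (6, 7, +1),  # S  -> SE
    (0, 7, -1),  # E  -> SE
)


class ChannelSource(IntEnum):
    NONE = 0
    THRESHOLD = 1
    COASTAL = 2


# ---------------------------------------------------------------------------
# Pit removal (priority-flood with epsilon)
# ---------------------------------------------------------------------------

def remove_pits(dem: Grid, epsilon: float = 1e-4) -> Grid:
    """Fill depressions so every valid cell drains to the grid boundary.

    Priority-flood: seed a min-heap with all boundary cells (grid edge or
    nodata-adjacent via the 8-neighborhood counts as boundary only for grid
    edge / nodata contact), then grow inward, raising each newly reached
    cell to at least the pour elevation plus ``epsilon``. With
    ``epsilon > 0`` the result is flat-free: every interior cell has a
    strictly descending 8-neighbor path to the boundary. Cells not inside
    a depression are returned unchanged. Output >= input everywhere.
    """
    if epsilon < 0:
        raise GridError("epsilon must be >= 0")
    z = np.asarray(dem.values, dtype=np.float64).copy()
    valid = dem.valid_mask()
    n_rows, n_cols = dem.shape

    # boundary = valid cells on the grid edge or 8-adjacent to nodata
    boundary = np.zeros_like(valid)
    boundary[0, :] = boundary[-1, :] = True
    boundary[:, 0] = boundary[:, -1] = True
    if not valid.all():
        inv = ~valid
        for dr, dc in NEIGHBOR_OFFSETS:
            shifted = np.zeros_like(inv)
            rs = slice(max(0, -dr), n_rows - max(0, dr))
            cs = slice(max(0, -dc), n_cols - max(0, dc))
            shifted[rs, cs] = inv[slice(max(0, dr), n_rows + min(0, dr)),
                                  slice(max(0, dc), n_cols + min(0, dc))]
            boundary |= shifted
    boundary &= valid
    if not boundary.any():
        raise GridError("no valid outlet: every valid cell is fully enclosed")

    INF = np.inf
    filled = np.where(valid, INF, np.nan)
    heap: list[tuple[float, int, int]] = []
    for r, c in np.argwhere(boundary):
        filled[r, c] = z[r, c]
        heapq.heappush(heap, (z[r, c], int(r), int(c)))

    while heap:
        zc, r, c = heapq.heappop(heap)
        if zc > filled[r, c]:
            continue  # stale entry
        for dr, dc in NEIGHBOR_OFFSETS:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < n_rows and 0 <= nc < n_cols):
                continue
            if not valid[nr, nc] or filled[nr, nc] < INF:
                continue
            filled[nr, nc] = max(z[nr, nc], zc + epsilon)
            heapq.heappush(heap, (filled[nr, nc], nr, nc))

    return dem.like(filled)


# ---------------------------------------------------------------------------
# D-infinity flow direction
# ---------------------------------------------------------------------------

@dataclass
class FlowField:
    """Per-cell D-infinity flow direction and two-neighbor flow split.

    ``angle`` is NaN for nodata and outlet cells. ``idx1``/``idx2`` index
    :data:`NEIGHBOR_OFFSETS` (-1 = unused); ``p1 + p2 = 1`` on routed
    cells. ``slope`` is the downslope gradient (rise/run, dimensionless)
    of the steepest facet — zero on outlets. ``elevation`` keeps the
    pit-filled surface the field was derived from; distance-down uses it
    for vertical drops.
    """

    angle: np.ndarray
    idx1: np.ndarray
    p1: np.ndarray
    idx2: np.ndarray
    p2: np.ndarray
    slope: np.ndarray
    outlet: np.ndarray
    elevation: Grid

    @property
    def shape(self) -> tuple[int, int]:
        return self.angle.shape

    @property
    def cell_size(self) -> float:
        return self.elevation.cell_size

    def valid_mask(self) -> np.ndarray:
        return self.elevation.valid_mask()

    def slope_grid(self) -> Grid:
        """Facet slope as angle in radians (0 on outlets), for CTI."""
        out = np.arctan(self.slope)
        out[~self.valid_mask()] = np.nan
        return self.elevation.like(out, units="rad")


def dinf_flow_direction(dem: Grid) -> FlowField:
    """Tarboton D-infinity flow direction on a pit-free, flat-free DEM.

    For each valid cell the steepest downward slope over the eight
    triangular facets (each spanned by a cardinal and a diagonal neighbor)
    fixes the flow angle; flow is split between the two facet neighbors in
    proportion to angular proximity. Cells with incomplete neighborhoods
    fall back to the steepest single-neighbor descent. Cells with no
    in-grid descent are outlets when they touch the grid edge or nodata,
    and an error otherwise (pit or flat: the precondition is violated).
    """
    z = np.asarray(dem.values, dtype=np.float64)
    valid = dem.valid_mask()
    n_rows, n_cols = dem.shape
    d = dem.cell_size

    zp = np.full((n_rows + 2, n_cols + 2), np.nan)
    zp[1:-1, 1:-1] = np.where(valid, z, np.nan)

    def nb(k: int) -> np.ndarray:
        dr, dc = NEIGHBOR_OFFSETS[k]
        return zp[1 + dr:n_rows + 1 + dr, 1 + dc:n_cols + 1 + dc]

    best_s = np.full(dem.shape, -np.inf)
    best_angle = np.full(dem.shape, np.nan)
    best_i1 = np.full(dem.shape, -1, dtype=np.int8)
    best_i2 = np.full(dem.shape, -1, dtype=np.int8)
    best_p1 = np.zeros(dem.shape)

    quarter = math.pi / 4
    for card, diag, orient in _FACETS:
        z1, z2 = nb(card), nb(diag)
        with np.errstate(invalid="ignore"):
            s1 = (z - z1) / d
            s2 = (z1 - z2) / d
            r = np.arctan2(s2, s1)
            smag = np.hypot(s1, s2)
            lo = r < 0
            r = np.where(lo, 0.0, r)
            smag = np.where(lo, s1, smag)
            hi = r > quarter
            r = np.where(hi, quarter, r)
            smag = np.where(hi, (z - z2) / (d * _SQRT2), smag)
        ok = np.isfinite(smag) & (smag > 0) & (smag > best_s)
        angle = (NEIGHBOR_ANGLES[card] + orient * r) % (2 * math.pi)
        pdiag = r / quarter
        best_angle = np.where(ok, angle, best_angle)
        best_i1 = np.where(ok, np.int8(card), best_i1)
        best_i2 = np.where(ok, np.int8(diag), best_i2)
        best_p1 = np.where(ok, 1.0 - pdiag, best_p1)
        best_s = np.where(ok, smag, best_s)

    # single-neighbor fallback for cells whose facets are incomplete
    # (boundary / nodata-adjacent); a full facet always dominates its edges
    for k in range(8):
        zk = nb(k)
        with np.errstate(invalid="ignore"):
            sk = (z - zk) / (d * NEIGHBOR_DISTS[k])
        ok = np.isfinite(sk) & (sk > 0) & (sk > best_s)
        best_angle = np.where(ok, NEIGHBOR_ANGLES[k], best_angle)
        best_i1 = np.where(ok, np.int8(k), best_i1)
        best_i2 = np.where(ok, np.int8(-1), best_i2)
        best_p1 = np.where(ok, 1.0, best_p1)
        best_s = np.where(ok, sk, best_s)

    unrouted = valid & ~(best_s > 0)
    # cells touching the edge or nodata may legitimately drain off-grid
    edge_contact = np.zeros(dem.shape, dtype=bool)
    edge_contact[0, :] = edge_contact[-1, :] = True
    edge_contact[:, 0] = edge_contact[:, -1] = True
    if not valid.all():
        inv = ~valid
        for dr, dc in NEIGHBOR_OFFSETS:
            rs = slice(max(0, -dr), n_rows - max(0, dr))
            cs = slice(max(0, -dc), n_cols - max(0, dc))
            sub = np.zeros(dem.shape, dtype=bool)
            sub[rs, cs] = inv[slice(max(0, dr), n_rows + min(0, dr)),
                              slice(max(0, dc), n_cols + min(0, dc))]
            edge_contact |= sub
    outlet = unrouted & edge_contact
    stuck = unrouted & ~edge_contact
    if stuck.any():
        r, c = np.argwhere(stuck)[0]
        raise GridError(
            f"flat or pit at interior cell ({r}, {c}): remove_pits with "
            "epsilon > 0 must run first")

    # exact-alignment cleanup: a proportion of 1 drops the second neighbor
    exact = best_p1 >= 1.0
    best_i2 = np.where(exact, np.int8(-1), best_i2)
    zerop = (best_p1 <= 0.0) & (best_i2 >= 0)
    best_i1 = np.where(zerop, best_i2, best_i1)
    best_p1 = np.where(zerop, 1.0, best_p1)
    best_i2 = np.where(zerop, np.int8(-1), best_i2)

    routed = valid & ~outlet
    angle = np.where(routed, best_angle, np.nan)
    slope = np.where(valid, np.where(routed, best_s, 0.0), np.nan)
    idx1 = np.where(routed, best_i1, np.int8(-1)).astype(np.int8)
    idx2 = np.where(routed, best_i2, np.int8(-1)).astype(np.int8)
    p1 = np.where(routed, best_p1, 0.0)
    p2 = np.where(idx2 >= 0, 1.0 - p1, 0.0)
    p1 = np.where(idx2 >= 0, p1, np.where(routed, 1.0, 0.0))
    return FlowField(angle, idx1, p1, idx2, p2, slope, outlet, dem.copy())


# ---------------------------------------------------------------------------
# Topological ordering of the routing graph
# ---------------------------------------------------------------------------

def _receiver_arrays(flow: FlowField) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flattened (recv1, recv2, valid_flat) receiver indices; -1 = none."""
    n_rows, n_cols = flow.shape
    flat = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    recv = []
    for idx in (flow.idx1, flow.idx2):
        r = np.full(flow.shape, -1, dtype=np.int64)
        for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
            sel = idx == k
            if not sel.any():
                continue
            rr, cc = np.nonzero(sel)
            r[rr, cc] = flat[rr + dr, cc + dc]
        recv.append(r.ravel())
    return recv[0], recv[1], flow.valid_mask().ravel()


def topological_order(flow: FlowField) -> np.ndarray:
    """Flat cell indices ordered upstream-to-downstream (Kahn's algorithm).

    Raises :class:`GridError` if the routing graph contains a cycle.
    """
    recv1, recv2, valid = _receiver_arrays(flow)
    n = valid.size
    indeg = np.zeros(n, dtype=np.int64)
    for recv in (recv1, recv2):
        has = recv >= 0
        np.add.at(indeg, recv[has], 1)
    order = np.empty(valid.sum(), dtype=np.int64)
    queue = deque(np.nonzero(valid & (indeg == 0))[0].tolist())
    pos = 0
    while queue:
        i = queue.popleft()
        order[pos] = i
        pos += 1
        for recv in (recv1, recv2):
            j = recv[i]
            if j >= 0:
                indeg[j] -= 1
                if indeg[j] == 0:
                    queue.append(j)
    if pos != order.size:
        raise GridError("cycle detected in flow routing graph")
    return order


# ---------------------------------------------------------------------------
# Flow accumulation
# ---------------------------------------------------------------------------

def dinf_accumulation(flow: FlowField) -> Grid:
    """D-infinity contributing area in cell counts (own cell included).

    ``a(i) = 1 + Σ_j p(j→i) a(j)`` over upslope neighbors ``j``, evaluated
    in topological order. Total outflow across outlets equals the number
    of valid cells (mass conservation).
    """
    recv1, recv2, valid = _receiver_arrays(flow)
    order = topological_order(flow)
    acc = np.where(valid, 1.0, np.nan)
    p1 = flow.p1.ravel()
    p2 = flow.p2.ravel()
    for i in order:
        a = acc[i]
        j = recv1[i]
        if j >= 0:
            acc[j] += p1[i] * a
        j = recv2[i]
        if j >= 0:
            acc[j] += p2[i] * a
    return flow.elevation.like(acc.reshape(flow.shape), units="cells")


# ---------------------------------------------------------------------------
# Channels
# ---------------------------------------------------------------------------

@dataclass
class ChannelMask:
    """Binary channel raster with per-cell provenance.

    ``source`` distinguishes threshold-exceeding cells from coastal-injected
    ones (valid cells 8-adjacent to a supplied coastal/ocean mask).
    """

    mask: Grid            # int {0,1} + nodata
    source: np.ndarray    # ChannelSource codes

    def is_empty(self) -> bool:
        return not (np.asarray(self.mask.values) == 1).any()


def extract_channels(acc: Grid, threshold_cells: int = 45_000,
                     coastal_mask: Grid | None = None) -> ChannelMask:
    """Channel cells: accumulation >= threshold, plus coastal injection.

    The comparison is inclusive (a cell accumulating exactly the threshold
    is a channel). If ``coastal_mask`` is given, every valid cell
    8-adjacent to (or on) a masked cell is additionally flagged, standing
    in for flow into oceans and estuaries.
    """
    if threshold_cells < 1:
        raise GridError("threshold_cells must be >= 1")
    vals = np.asarray(acc.values, dtype=np.float64)
    valid = acc.valid_mask()
    source = np.zeros(acc.shape, dtype=np.uint8)
    source[valid & (vals >= threshold_cells)] = ChannelSource.THRESHOLD
    if coastal_mask is not None:
        if not acc.aligned_with(coastal_mask):
            raise GridError("coastal mask is not aligned with the accumulation grid")
        coast = np.asarray(coastal_mask.values) == 1
        near = coast.copy()
        n_rows, n_cols = acc.shape
        for dr, dc in NEIGHBOR_OFFSETS:
            rs = slice(max(0, -dr), n_rows - max(0, dr))
            cs = slice(max(0, -dc), n_cols - max(0, dc))
            sub = np.zeros_like(coast)
            sub[rs, cs] = coast[slice(max(0, dr), n_rows + min(0, dr)),
                                slice(max(0, dc), n_cols + min(0, dc))]
            near |= sub
        inject = valid & near & (source == 0)
        source[inject] = ChannelSource.COASTAL
    from .grids import INT_NODATA

    out = np.where(valid, (source > 0).astype(np.int32), INT_NODATA)
    return ChannelMask(acc.like(out, units=""), source)


# ---------------------------------------------------------------------------
# Distance down to channel
# ---------------------------------------------------------------------------

_METRICS = ("horizontal", "vertical", "pythagoras")


def distance_down(flow: FlowField, dem: Grid, channels: ChannelMask,
                  metric: str, outlets_as_channels: bool = False) -> Grid:
    """Flow-weighted average distance down to the channel network.

    ``d = 0`` on channel cells; elsewhere
    ``d(i) = Σ_k p(i→k) (seg(i,k) + d(k))`` over the receiving neighbors,
    evaluated downstream-first. The segment length is the center-to-center
    planar distance (``horizontal``), the elevation drop on the pit-filled
    DEM (``vertical``), or the per-segment hypotenuse (``pythagoras``).
    Cells whose flow leaves the grid without meeting a channel are nodata
    unless ``outlets_as_channels`` makes outlets zero-distance.
    """
    if metric not in _METRICS:
        raise GridError(f"unknown metric {metric!r}; expected one of {_METRICS}")
    if channels.is_empty() and not outlets_as_channels:
        raise GridError("channel mask is empty and outlets_as_channels is off")
    n_rows, n_cols = flow.shape
    d_cell = flow.cell_size
    z = np.asarray(flow.elevation.values, dtype=np.float64).ravel()
    recv1, recv2, valid = _receiver_arrays(flow)
    order = topological_order(flow)

    is_channel = (np.asarray(channels.mask.values) == 1).ravel()
    outlet = flow.outlet.ravel()
    p1 = flow.p1.ravel()
    p2 = flow.p2.ravel()

    # per-receiver horizontal lengths
    hdist1 = np.zeros(valid.size)
    hdist2 = np.zeros(valid.size)
    for k in range(8):
        hdist1[ (flow.idx1.ravel() == k) ] = NEIGHBOR_DISTS[k] * d_cell
        hdist2[ (flow.idx2.ravel() == k) ] = NEIGHBOR_DISTS[k] * d_cell

    dist = np.full(valid.size, np.nan)
    for i in order[::-1]:  # downstream first
        if is_channel[i]:
            dist[i] = 0.0
            continue
        if outlet[i]:
            dist[i] = 0.0 if outlets_as_channels else np.nan
            continue
        total = 0.0
        ok = True
        for recv, p, hd in ((recv1, p1, hdist1), (recv2, p2, hdist2)):
            j = recv[i]
            if j < 0:
                continue
            dj = dist[j]
            if math.isnan(dj):
                ok = False
                break
            if metric == "horizontal":
                seg = hd[i]
            elif metric == "vertical":
                seg = z[i] - z[j]
            else:
                seg = math.hypot(hd[i], z[i] - z[j])
            total += p[i] * (seg + dj)
        dist[i] = total if ok else np.nan
    dist[~valid] = np.nan
    return flow.elevation.like(dist.reshape(n_rows, n_cols), units="m")


# ---------------------------------------------------------------------------
# CTI, slope, aspect
# ---------------------------------------------------------------------------

SLOPE_EPS_RAD = 1e-4  # guard added to slope before taking the tangent


def compute_cti(acc: Grid, slope_rad: Grid, cell_size: float | None = None) -> Grid:
    """Compound topographic index ``ln(a·Δ / tan(β + 0.0001))``.

    ``a`` is contributing area in cell counts, so ``a·Δ`` is the specific
    catchment area per unit contour width (one cell side Δ). The 0.0001 rad
    addition keeps the tangent positive on perfectly flat cells, so the
    index is finite everywhere.
    """
    if cell_size is None:
        cell_size = acc.cell_size
    if not acc.aligned_with(slope_rad):
        raise GridError("slope grid is not aligned with the accumulation grid")
    a = np.asarray(acc.values, dtype=np.float64)
    beta = np.asarray(slope_rad.values, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        cti = np.log(a * cell_size / np.tan(beta + SLOPE_EPS_RAD))
    cti[acc.nodata_mask() | slope_rad.nodata_mask()] = np.nan
    return acc.like(cti, units="")


def smooth_and_scale_cti(cti: Grid) -> Grid:
    """3×3 focal-mean smoothing, then linear min-max scaling onto 0–1000.

    The smoothed minimum maps to 0 and the maximum to 1000 exactly;
    values are rounded to the nearest integer (half away from zero).
    Raises on a constant grid (zero range).
    """
    in_vals = np.asarray(cti.values, dtype=np.float64)[cti.valid_mask()]
    if in_vals.size == 0:
        raise GridError("CTI grid has no valid cells")
    if np.unique(in_vals).size < 2:
        raise GridError("cannot scale a constant CTI grid (zero range)")
    sm = focal_mean3(cti)
    vals = np.asarray(sm.values, dtype=np.float64)
    valid = ~np.isnan(vals)
    lo, hi = np.nanmin(vals), np.nanmax(vals)
    if hi == lo:
        raise GridError("cannot scale a constant CTI grid (zero range)")
    scaled = (vals - lo) / (hi - lo) * 1000.0
    out = np.where(valid, np.floor(scaled + 0.5), 0.0).astype(np.int32)
    from .grids import INT_NODATA

    out[~valid] = INT_NODATA
    return cti.like(out, units="")


def slope_aspect(dem: Grid) -> tuple[Grid, Grid]:
    """Slope and aspect from 4-neighbor central differences, in degrees.

    Slope is ``atan(|∇z|)``; aspect is the compass direction of steepest
    descent, degrees clockwise from north in ``[0, 360)``, with flat cells
    assigned 0 by convention. Edge cells use one-sided differences.
    """
    z = np.asarray(dem.values, dtype=np.float64)
    z = np.where(dem.valid_mask(), z, np.nan)
    d = dem.cell_size
    # np.gradient axis 0 is the row axis (southward); the northward
    # gradient flips its sign
    dz_drow, dz_dcol = np.gradient(z, d)
    gx = dz_dcol            # eastward gradient
    gy = -dz_drow           # northward gradient
    mag = np.hypot(gx, gy)
    slope = np.degrees(np.arctan(mag))
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    aspect = np.where(mag == 0, 0.0, aspect)
    nan = dem.nodata_mask()
    slope[nan] = np.nan
    aspect[nan] = np.nan
    return dem.like(slope, units="deg"), dem.like(aspect, units="deg")
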