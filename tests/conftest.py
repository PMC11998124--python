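"""Shared fixtures and independent oracle implementations.

The oracles here deliberately use brute-force formulations (dense linear
solves, exhaustive sweeps, flood fill) that share no code with the
package's implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from wetpot import Grid, SceneConfig, remove_pits
from wetpot.terrain import NEIGHBOR_OFFSETS, NEIGHBOR_DISTS, FlowField


# ---------------------------------------------------------------------------
# DEM helpers
# ---------------------------------------------------------------------------

def random_dem(rng: np.random.Generator, n: int = 8, cell_size: float = 10.0,
               smooth: bool = True) -> Grid:
    """Random rough surface with a tilt so most cells drain."""
    z = rng.normal(0.0, 1.0, size=(n, n))
    if smooth:
        from scipy.ndimage import gaussian_filter

        z = gaussian_filter(z, sigma=1.0, mode="reflect")
    rows = np.arange(n, dtype=float)[:, None]
    z = z + 0.3 * (n - rows)  # south edge lowest
    return Grid(z, cell_size)


def random_pitfree_dem(rng: np.random.Generator, n: int = 8,
                       cell_size: float = 10.0) -> Grid:
    return remove_pits(random_dem(rng, n, cell_size), epsilon=1e-3)


# ---------------------------------------------------------------------------
# Flow-direction sweep oracle
# ---------------------------------------------------------------------------

def sweep_direction_oracle(dem: Grid, r: int, c: int,
                           n_dirs: int = 3600) -> tuple[float, float]:
    """Steepest-descent direction by dense angular sweep at one cell.

    Evaluates the directional downslope gradient for ``n_dirs`` equally
    spaced directions by planar interpolation within the triangular facet
    containing each direction, and returns (argmax angle, max slope).
    """
    z = np.asarray(dem.values, dtype=float)
    d = dem.cell_size
    z0 = z[r, c]
    quarter = math.pi / 4
    best_angle, best_slope = math.nan, -math.inf
    for i in range(n_dirs):
        theta = 2 * math.pi * i / n_dirs
        sector = int(theta // quarter) % 8
        # facet spanned by the two neighbors bounding this 45° sector
        k1 = sector            # counter-clockwise boundary neighbor is k1+1
        k2 = (sector + 1) % 8
        dr1, dc1 = NEIGHBOR_OFFSETS[k1]
        dr2, dc2 = NEIGHBOR_OFFSETS[k2]
        z1 = z[r + dr1, c + dc1]
        z2 = z[r + dr2, c + dc2]
        # one of (k1, k2) is cardinal; measure the in-facet angle from it
        if k1 % 2 == 0:  # k1 cardinal, k2 diagonal
            zc, zdg = z1, z2
            t = theta - k1 * quarter
        else:            # k1 diagonal, k2 cardinal
            zc, zdg = z2, z1
            t = (k2 % 8) * quarter - theta if k2 != 0 else 2 * math.pi - theta
        s1 = (z0 - zc) / d
        s2 = (zc - zdg) / d
        slope = s1 * math.cos(t) + s2 * math.sin(t)
        if slope > best_slope:
            best_slope, best_angle = slope, theta
    return best_angle, best_slope


def sweep_direction_oracle_fast(dem: Grid, r: int, c: int,
                                n_dirs: int = 3600) -> tuple[float, float]:
    """Vectorized variant of :func:`sweep_direction_oracle` (same math)."""
    z = np.asarray(dem.values, dtype=float)
    d = dem.cell_size
    quarter = math.pi / 4
    thetas = 2 * math.pi * np.arange(n_dirs) / n_dirs
    sectors = (thetas // quarter).astype(int) % 8
    k1 = sectors
    k2 = (sectors + 1) % 8
    zn = np.array([z[r + dr, c + dc] for dr, dc in NEIGHBOR_OFFSETS])
    card_is_k1 = k1 % 2 == 0
    zc = np.where(card_is_k1, zn[k1], zn[k2])
    zdg = np.where(card_is_k1, zn[k2], zn[k1])
    card_angle = np.where(card_is_k1, k1 * quarter,
                          np.where(k2 == 0, 2 * math.pi, k2 * quarter))
    t = np.abs(thetas - card_angle)
    s1 = (z[r, c] - zc) / d
    s2 = (zc - zdg) / d
    slopes = s1 * np.cos(t) + s2 * np.sin(t)
    i = int(np.argmax(slopes))
    return float(thetas[i]), float(slopes[i])


def directional_slope(dem: Grid, r: int, c: int, theta: float) -> float:
    """Directional downslope gradient at one exact angle (same facet math)."""
    z = np.asarray(dem.values, dtype=float)
    d = dem.cell_size
    quarter = math.pi / 4
    theta = theta % (2 * math.pi)
    sector = int(theta // quarter) % 8
    k1, k2 = sector, (sector + 1) % 8
    dr1, dc1 = NEIGHBOR_OFFSETS[k1]
    dr2, dc2 = NEIGHBOR_OFFSETS[k2]
    z1, z2 = z[r + dr1, c + dc1], z[r + dr2, c + dc2]
    if k1 % 2 == 0:
        zc, zdg = z1, z2
        t = theta - k1 * quarter
    else:
        zc, zdg = z2, z1
        t = (k2 * quarter if k2 else 2 * math.pi) - theta
    s1 = (z[r, c] - zc) / d
    s2 = (zc - zdg) / d
    return s1 * math.cos(t) + s2 * math.sin(t)


# ---------------------------------------------------------------------------
# Dense linear-system oracles
# ---------------------------------------------------------------------------

def routing_matrix(flow: FlowField) -> np.ndarray:
    """Dense (N, N) matrix P with P[i, k] = proportion of cell i's flow to k."""
    n_rows, n_cols = flow.shape
    n = n_rows * n_cols
    P = np.zeros((n, n))
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            for idx, p in ((flow.idx1[r, c], flow.p1[r, c]),
                           (flow.idx2[r, c], flow.p2[r, c])):
                if idx >= 0 and p > 0:
                    dr, dc = NEIGHBOR_OFFSETS[idx]
                    P[i, (r + dr) * n_cols + (c + dc)] = p
    return P


def accumulation_oracle(flow: FlowField) -> np.ndarray:
    """Solve (I - P^T) a = 1 densely for the contributing area."""
    P = routing_matrix(flow)
    n = P.shape[0]
    a = np.linalg.solve(np.eye(n) - P.T, np.ones(n))
    return a.reshape(flow.shape)


def distance_down_oracle(flow: FlowField, channel: np.ndarray, metric: str,
                         outlets_as_channels: bool = True) -> np.ndarray:
    """Dense linear solve for the expected flow-path distance to channel."""
    n_rows, n_cols = flow.shape
    n = n_rows * n_cols
    z = np.asarray(flow.elevation.values, dtype=float).ravel()
    d_cell = flow.cell_size
    A = np.eye(n)
    b = np.zeros(n)
    ch = channel.ravel()
    outlet = flow.outlet.ravel()
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            if ch[i]:
                continue  # d = 0
            if outlet[i]:
                if not outlets_as_channels:
                    raise ValueError("oracle only supports outlets-as-channels")
                continue  # d = 0
            for idx, p in ((flow.idx1[r, c], flow.p1[r, c]),
                           (flow.idx2[r, c], flow.p2[r, c])):
                if idx < 0 or p == 0:
                    continue
                dr, dc = NEIGHBOR_OFFSETS[idx]
                k = (r + dr) * n_cols + (c + dc)
                h = NEIGHBOR_DISTS[idx] * d_cell
                v = z[i] - z[k]
                seg = {"horizontal": h, "vertical": v,
                       "pythagoras": math.hypot(h, v)}[metric]
                A[i, k] -= p
                b[i] += p * seg
    return np.linalg.solve(A, b).reshape(n_rows, n_cols)


# ---------------------------------------------------------------------------
# Other oracles
# ---------------------------------------------------------------------------

def flood_fill_components(binary: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components of True cells by explicit flood fill."""
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    n_rows, n_cols = binary.shape
    for r0 in range(n_rows):
        for c0 in range(n_cols):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            comp, frontier = set(), [(r0, c0)]
            seen[r0, c0] = True
            while frontier:
                r, c = frontier.pop()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = r + dr, c + dc
                        if (0 <= nr < n_rows and 0 <= nc < n_cols
                                and binary[nr, nc] and not seen[nr, nc]):
                            seen[nr, nc] = True
                            frontier.append((nr, nc))
            comps.append(comp)
    return comps


def has_nonascending_path_to_edge(dem: Grid) -> bool:
    """BFS drainage oracle: every valid cell reaches the boundary (or a
    nodata cell) along a non-ascending 8-neighbor path."""
    z = np.asarray(dem.values, dtype=float)
    valid = dem.valid_mask()
    n_rows, n_cols = dem.shape
    reachable = np.zeros_like(valid)
    frontier = []
    for r in range(n_rows):
        for c in range(n_cols):
            if not valid[r, c]:
                continue
            on_edge = r in (0, n_rows - 1) or c in (0, n_cols - 1)
            near_nodata = any(
                0 <= r + dr < n_rows and 0 <= c + dc < n_cols
                and not valid[r + dr, c + dc]
                for dr, dc in NEIGHBOR_OFFSETS)
            if on_edge or near_nodata:
                reachable[r, c] = True
                frontier.append((r, c))
    # walk upstream: a cell drains if some non-higher... a neighbor with
    # z >= current can step down onto the current reachable cell
    while frontier:
        r, c = frontier.pop()
        for dr, dc in NEIGHBOR_OFFSETS:
            nr, nc = r + dr, c + dc
            if (0 <= nr < n_rows and 0 <= nc < n_cols and valid[nr, nc]
                    and not reachable[nr, nc] and z[nr, nc] >= z[r, c]):
                reachable[nr, nc] = True
                frontier.append((nr, nc))
    return bool(reachable[valid].all())


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_scene():
    """Modest synthetic scene shared by non-acceptance tests."""
    from wetpot import generate_scene

    return generate_scene(SceneConfig(n_rows=120, n_cols=120, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
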