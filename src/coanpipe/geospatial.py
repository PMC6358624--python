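"""Map placement, cluster-density colouring and spatial smoothing of
copying vectors.

Individuals are placed at the centroid of their four grandparental
birthplaces (planar km); individuals with any grandparent farther than
80 km from the centroid are dropped from maps (recent-migration filter), and
co-located display points are jittered by at most 24 km. Cluster densities
and copying vectors are smoothed onto a regular grid of 3-km cells with a
Gaussian kernel whose bandwidth adapts to the local density of data points
(distance to the k-th nearest retained individual, floored at a base
bandwidth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import fit_ancestry_profile

__all__ = [
    "PlacedIndividual",
    "SpatialGrid",
    "place_individuals",
    "cluster_density_grid",
    "smoothed_copying_grid",
    "grid_profiles",
]


@dataclass
class PlacedIndividual:
    id: str
    centroid: tuple
    max_gp_distance: float
    retained: bool
    display: tuple


@dataclass
class SpatialGrid:
    """Regular axis-aligned grid; cells identified by lower-left corner
    (half-open intervals), values at cell centres."""

    x0: float
    y0: float
    cell_km: float
    nx: int
    ny: int
    values: np.ndarray  # (ny, nx, G)
    columns: list
    bandwidth: np.ndarray | None = None  # (ny, nx)
    empty_mask: np.ndarray | None = None  # (ny, nx) cells with no support

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.cell_km
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.cell_km
        return xs, ys

    def to_frame(self) -> pd.DataFrame:
        xs, ys = self.cell_centres()
        recs = []
        for iy in range(self.ny):
            for ix in range(self.nx):
                rec = {"x_km": xs[ix], "y_km": ys[iy]}
                if self.bandwidth is not None:
                    rec["bandwidth_km"] = self.bandwidth[iy, ix]
                for g, v in zip(self.columns, self.values[iy, ix]):
                    rec[str(g)] = v
                recs.append(rec)
        return pd.DataFrame(recs)


def place_individuals(
    metadata: pd.DataFrame,
    max_gp_km: float = 80.0,
    jitter_km: float = 24.0,
    seed: int = 0,
    pairwise_rule: bool = False,
) -> list[PlacedIndividual]:
    """Centroid placement with the 80-km retention filter and 24-km jitter.

    Requires columns gp1_x..gp4_y; individuals with missing grandparent
    coordinates are not placeable and are skipped. By default retention
    requires all four grandparents within ``max_gp_km`` of their centroid;
    ``pairwise_rule`` instead requires all pairwise distances within the
    limit.
    """
    rng = np.random.default_rng(seed)
    cols = [f"gp{k}_{ax}" for k in range(1, 5) for ax in "xy"]
    placed: list[PlacedIndividual] = []
    seen: dict[tuple, int] = {}
    for ind, row in metadata.iterrows():
        if any(c not in metadata.columns or pd.isna(row[c]) for c in cols):
            continue
        gp = np.array([[row[f"gp{k}_x"], row[f"gp{k}_y"]] for k in range(1, 5)])
        centroid = gp.mean(axis=0)
        d = np.linalg.norm(gp - centroid, axis=1)
        if pairwise_rule:
            pair_d = np.linalg.norm(gp[:, None, :] - gp[None, :, :], axis=2)
            retained = bool(pair_d.max() <= max_gp_km)
        else:
            retained = bool(d.max() <= max_gp_km)
        key = (round(centroid[0], 6), round(centroid[1], 6))
        if key in seen:
            seen[key] += 1
            r = jitter_km * np.sqrt(rng.random())
            th = rng.uniform(0, 2 * np.pi)
            display = (centroid[0] + r * np.cos(th), centroid[1] + r * np.sin(th))
        else:
            seen[key] = 1
            display = (float(centroid[0]), float(centroid[1]))
        placed.append(
            PlacedIndividual(
                id=str(ind),
                centroid=(float(centroid[0]), float(centroid[1])),
                max_gp_distance=float(d.max()),
                retained=retained,
                display=display,
            )
        )
    return placed


def _grid_spec(points: np.ndarray, cell_km: float, pad_km: float):
    x0 = np.floor((points[:, 0].min() - pad_km) / cell_km) * cell_km
    y0 = np.floor((points[:, 1].min() - pad_km) / cell_km) * cell_km
    nx = int(np.ceil((points[:, 0].max() + pad_km - x0) / cell_km)) + 1
    ny = int(np.ceil((points[:, 1].max() + pad_km - y0) / cell_km)) + 1
    return x0, y0, nx, ny


def cluster_density_grid(
    placed: list[PlacedIndividual],
    cluster_of: dict,
    cell_km: float = 3.0,
    kernel_km: float = 20.0,
    pad_km: float = 10.0,
) -> SpatialGrid:
    """Per-cell relative cluster contributions from Gaussian densities
    centred on each retained individual; contributions sum to 1 per cell."""
    pts = [p for p in placed if p.retained and p.id in cluster_of]
    if not pts:
        raise ValueError("no retained individuals to grid")
    xy = np.array([p.centroid for p in pts])
    labels = [cluster_of[p.id] for p in pts]
    clusters = sorted(set(labels), key=str)
    x0, y0, nx, ny = _grid_spec(xy, cell_km, pad_km)
    xs = x0 + (np.arange(nx) + 0.5) * cell_km
    ys = y0 + (np.arange(ny) + 0.5) * cell_km
    gx, gy = np.meshgrid(xs, ys)
    dens = np.zeros((ny, nx, len(clusters)))
    for p, lab in zip(xy, labels):
        w = np.exp(-((gx - p[0]) ** 2 + (gy - p[1]) ** 2) / (2 * kernel_km**2))
        dens[:, :, clusters.index(lab)] += w
    tot = dens.sum(axis=2, keepdims=True)
    empty = tot[:, :, 0] <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.where(tot > 0, dens / tot, np.nan)
    return SpatialGrid(x0, y0, cell_km, nx, ny, dens, clusters, empty_mask=empty)


def smoothed_copying_grid(
    placed: list[PlacedIndividual],
    vectors: pd.DataFrame,
    cell_km: float = 3.0,
    k_neighbours: int = 10,
    base_bandwidth_km: float = 3.0,
    pad_km: float = 10.0,
    region_ids: list | None = None,
    region_bbox: tuple | None = None,
) -> SpatialGrid:
    """Adaptive-bandwidth Gaussian smoothing of per-individual copying
    vectors onto the grid.

    Bandwidth at a cell is max(base, distance to the k-th nearest retained
    individual). A "no-fine-geography" region may be designated by
    ``region_ids`` (individuals without usable coordinates) and
    ``region_bbox`` (xmin, xmax, ymin, ymax in km): region individuals are
    excluded from the kernel smoothing and every cell whose centre falls in
    the bbox carries one constant vector, the plain average over the region
    individuals.
    """
    pts = [p for p in placed if p.retained and p.id in vectors.index]
    if not pts:
        raise ValueError("no retained individuals with vectors")
    region = set(region_ids or [])
    main = [p for p in pts if p.id not in region]
    if not main:
        raise ValueError("no individuals left outside the constant region")
    xy = np.array([p.centroid for p in main])
    V = vectors.loc[[p.id for p in main]].to_numpy(dtype=float)
    # the grid covers every retained individual, region members included
    xy_all = np.array([p.centroid for p in pts])
    x0, y0, nx, ny = _grid_spec(xy_all, cell_km, pad_km)
    xs = x0 + (np.arange(nx) + 0.5) * cell_km
    ys = y0 + (np.arange(ny) + 0.5) * cell_km
    gx, gy = np.meshgrid(xs, ys)
    d2 = (gx[:, :, None] - xy[None, None, :, 0]) ** 2 + (
        gy[:, :, None] - xy[None, None, :, 1]
    ) ** 2
    k = min(k_neighbours, len(main))
    kth = np.sqrt(np.partition(d2, k - 1, axis=2)[:, :, k - 1])
    bw = np.maximum(base_bandwidth_km, kth)
    w = np.exp(-d2 / (2 * bw[:, :, None] ** 2))
    tot = w.sum(axis=2)
    empty = tot <= 1e-300
    vals = np.einsum("yxn,ng->yxg", w, V)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(tot[:, :, None] > 1e-300, vals / tot[:, :, None], np.nan)
    if region:
        present = [i for i in vectors.index if i in region]
        if present and region_bbox is not None:
            const = vectors.loc[present].to_numpy(dtype=float).mean(axis=0)
            xmin, xmax, ymin, ymax = region_bbox
            in_region = (
                (gx >= xmin) & (gx <= xmax) & (gy >= ymin) & (gy <= ymax)
            )
            vals[in_region] = const
            bw = np.where(in_region, base_bandwidth_km, bw)
            empty = empty & ~in_region
    return SpatialGrid(
        x0, y0, cell_km, nx, ny, vals, list(vectors.columns), bandwidth=bw,
        empty_mask=empty,
    )


def grid_profiles(grid: SpatialGrid, B: pd.DataFrame) -> SpatialGrid:
    """Fit an ancestry profile at every grid cell (target = the cell's
    smoothed copying vector, normalized to proportions)."""
    ny, nx, G = grid.values.shape
    out = np.full((ny, nx, len(B.index)), np.nan)
    for iy in range(ny):
        for ix in range(nx):
            y = grid.values[iy, ix]
            if not np.all(np.isfinite(y)) or y.sum() <= 0:
                continue
            prof = fit_ancestry_profile(y / y.sum(), B)
            out[iy, ix] = prof.coefficients
    return SpatialGrid(
        grid.x0,
        grid.y0,
        grid.cell_km,
        grid.nx,
        grid.ny,
        out,
        list(B.index),
        bandwidth=grid.bandwidth,
        empty_mask=grid.empty_mask,
    )
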