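"""Fixed-kernel utilization distributions on the unfolded enclosure surface.

Home range (HR) and core area (CA) follow the fixed-kernel convention from
wildlife ecology: a single bandwidth ``h`` from the optimal-bandwidth rule

    h_opt = (2 / (3 n)) ** (1/4) * sigma,

where ``n`` is the number of location fixes and ``sigma`` the standard
distance (root mean squared distance of fixes from their centroid), a
quartic (biweight) kernel on a regular cell grid, and isopleths taken as
the smallest-area cell set holding 95% (HR) or 50% (CA) of the probability
mass.  The enclosure border acts as a barrier: kernel mass falling outside
the unfolded surface is clipped and the remainder renormalized to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely import contains_xy as _poly_contains

from .geometry import EnclosureSpec, SurfacePoint, UnfoldedSurface

__all__ = [
    "DensitySurface",
    "RangeEstimate",
    "BandwidthError",
    "EmptyInputError",
    "InsufficientLocationsError",
    "DegenerateSpreadWarning",
    "element_use",
    "isopleth",
    "kernel_density",
    "optimal_bandwidth",
    "range_summary",
    "standard_distance",
]


class InsufficientLocationsError(ValueError):
    pass


class BandwidthError(ValueError):
    pass


class EmptyInputError(ValueError):
    pass


class DegenerateSpreadWarning(UserWarning):
    """All locations coincide; the density collapses to a point mass."""


def standard_distance(points: np.ndarray) -> float:
    """Standard distance of planar points: RMS distance from the centroid.

    ``sqrt((sum (x-xbar)^2 + sum (y-ybar)^2) / n)`` — the spatial analogue
    of a standard deviation, with an ``n`` (not ``n-1``) denominator as is
    conventional in GIS.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise InsufficientLocationsError(
            f"need >= 2 planar points, got shape {np.shape(points)}"
        )
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2) / len(pts)))


def optimal_bandwidth(n: int, sigma: float) -> float:
    """The fixed-kernel optimal bandwidth (2/(3n))^(1/4) * sigma, in cm."""
    if n < 1:
        raise InsufficientLocationsError(f"need n >= 1 locations, got {n}")
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0:
        warnings.warn(
            "zero standard distance: bandwidth 0, density is a point mass",
            DegenerateSpreadWarning,
            stacklevel=2,
        )
        return 0.0
    return float((2.0 / (3.0 * n)) ** 0.25 * sigma)


@dataclass(frozen=True)
class DensitySurface:
    """A gridded utilization density over the unfolded surface.

    ``density[i, j]`` is the density (cm^-2) at the center of the cell with
    x-index i, y-index j; cells outside the surface are exactly zero.
    ``renormalization`` records the share of raw kernel mass that fell
    inside the barrier before rescaling (the barrier-clipping audit trail).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray
    inside: np.ndarray
    cell_size: float
    bandwidth: float
    n_locations: int
    renormalization: float
    surface: UnfoldedSurface

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = (self.x_edges[:-1] + self.x_edges[1:]) / 2
        cy = (self.y_edges[:-1] + self.y_edges[1:]) / 2
        return np.meshgrid(cx, cy, indexing="ij")


def _quartic_raw_density(
    pts: np.ndarray, h: float, x_edges: np.ndarray, y_edges: np.ndarray
) -> np.ndarray:
    """Unclipped quartic-kernel density evaluated at cell centers."""
    cx = (x_edges[:-1] + x_edges[1:]) / 2
    cy = (y_edges[:-1] + y_edges[1:]) / 2
    X, Y = np.meshgrid(cx, cy, indexing="ij")
    dens = np.zeros_like(X)
    norm = 3.0 / (np.pi * h**2 * len(pts))
    for px, py in pts:
        # finite support: only cells within h of the point contribute
        i0, i1 = np.searchsorted(cx, [px - h, px + h])
        j0, j1 = np.searchsorted(cy, [py - h, py + h])
        if i0 == i1 or j0 == j1:
            continue
        u2 = (
            (X[i0:i1, j0:j1] - px) ** 2 + (Y[i0:i1, j0:j1] - py) ** 2
        ) / h**2
        w = np.where(u2 < 1.0, (1.0 - u2) ** 2, 0.0)
        dens[i0:i1, j0:j1] += norm * w
    return dens


def _gaussian_raw_density(
    pts: np.ndarray, h: float, x_edges: np.ndarray, y_edges: np.ndarray
) -> np.ndarray:
    cx = (x_edges[:-1] + x_edges[1:]) / 2
    cy = (y_edges[:-1] + y_edges[1:]) / 2
    X, Y = np.meshgrid(cx, cy, indexing="ij")
    dens = np.zeros_like(X)
    norm = 1.0 / (2 * np.pi * h**2 * len(pts))
    for px, py in pts:
        d2 = (X - px) ** 2 + (Y - py) ** 2
        dens += norm * np.exp(-d2 / (2 * h**2))
    return dens


def kernel_density(
    points: list[SurfacePoint] | np.ndarray,
    h: float,
    surface: UnfoldedSurface,
    cell_size: float | None = None,
    kernel: str = "quartic",
) -> DensitySurface:
    """Fixed-kernel density on the unfolded surface with a barrier border.

    ``points`` are surface points or an (n, 2) array of unfolded-plane
    coordinates.  The default cell size is ``min(length, width)/200``;
    resolutions coarser than ``h/2`` are rejected so the kernel is always
    resolved.  Mass outside the surface outline is clipped and the interior
    renormalized to one.
    """
    if h <= 0:
        raise BandwidthError(f"bandwidth must be positive, got {h}")
    if isinstance(points, np.ndarray):
        pts = np.asarray(points, dtype=float)
    else:
        pts = np.asarray([(p.x, p.y) for p in points], dtype=float)
    if pts.size == 0:
        raise EmptyInputError("no location points supplied")
    spec = surface.spec
    if cell_size is None:
        cell_size = min(spec.length, spec.width) / 200.0
        cell_size = min(cell_size, h / 2.0)
    if cell_size > h / 2.0 + 1e-12:
        raise BandwidthError(
            f"cell size {cell_size} too coarse for bandwidth {h} (need <= h/2)"
        )

    x0, y0, x1, y1 = surface.polygon.bounds
    # pad by the kernel support so clipped (outside) mass is fully audited
    pad = cell_size * np.ceil((h if kernel == "quartic" else 5 * h) / cell_size)
    x0, y0 = x0 - pad, y0 - pad
    nx = int(np.ceil((x1 + pad - x0) / cell_size))
    ny = int(np.ceil((y1 + pad - y0) / cell_size))
    x_edges = x0 + cell_size * np.arange(nx + 1)
    y_edges = y0 + cell_size * np.arange(ny + 1)

    if kernel == "quartic":
        dens = _quartic_raw_density(pts, h, x_edges, y_edges)
    elif kernel == "gaussian":
        dens = _gaussian_raw_density(pts, h, x_edges, y_edges)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")

    X, Y = np.meshgrid(
        (x_edges[:-1] + x_edges[1:]) / 2,
        (y_edges[:-1] + y_edges[1:]) / 2,
        indexing="ij",
    )
    inside = _poly_contains(surface.polygon.buffer(1e-9), X, Y)
    raw_mass = dens.sum() * cell_size**2
    dens = np.where(inside, dens, 0.0)
    kept = dens.sum() * cell_size**2
    if kept <= 0:
        raise EmptyInputError("all kernel mass fell outside the surface")
    dens = dens / kept
    return DensitySurface(
        x_edges=x_edges,
        y_edges=y_edges,
        density=dens,
        inside=inside,
        cell_size=cell_size,
        bandwidth=h,
        n_locations=len(pts),
        renormalization=float(kept / raw_mass) if raw_mass > 0 else 0.0,
        surface=surface,
    )


@dataclass(frozen=True)
class RangeEstimate:
    """An isopleth region of a utilization distribution.

    ``member``: boolean cell mask; ``area`` = member cells x cell area;
    ``proportion`` = area / unfolded surface area.
    """

    level: float
    member: np.ndarray
    area: float
    proportion: float
    cell_size: float

    def contains_point(self, density: DensitySurface, x: float, y: float) -> bool:
        """Whether the plane point (x, y) falls in a member cell."""
        i = int(np.searchsorted(density.x_edges, x, side="right")) - 1
        j = int(np.searchsorted(density.y_edges, y, side="right")) - 1
        if 0 <= i < self.member.shape[0] and 0 <= j < self.member.shape[1]:
            return bool(self.member[i, j])
        return False


def isopleth(density: DensitySurface, level: float) -> RangeEstimate:
    """Smallest-area cell set holding ``level`` of the probability mass.

    Cells are ranked by density (descending, ties broken by flat cell index)
    and accumulated until the target mass is reached — the fixed-kernel
    home-range (0.95) / core-area (0.50) construction.
    """
    if not 0 < level < 1:
        raise ValueError(f"isopleth level must be in (0, 1), got {level}")
    if abs(density.total_mass() - 1.0) > 1e-6:
        raise ValueError(
            "density is not normalized; kernel_density output required"
        )
    flat = density.density.ravel()
    # stable sort descending with index tie-break
    order = np.argsort(-flat, kind="stable")
    masses = flat[order] * density.cell_area
    cum = np.cumsum(masses)
    k = int(np.searchsorted(cum, level) + 1)
    k = min(k, int((flat > 0).sum()))
    member = np.zeros(flat.shape, dtype=bool)
    member[order[:k]] = True
    member = member.reshape(density.density.shape)
    area = float(k * density.cell_area)
    return RangeEstimate(
        level=level,
        member=member,
        area=area,
        proportion=area / density.surface.total_area,
        cell_size=density.cell_size,
    )


def range_summary(
    estimate: RangeEstimate, surface: UnfoldedSurface, spec: EnclosureSpec
) -> tuple[float, float]:
    """(proportion of enclosure surface, true area cm^2) of a range.

    The proportion is the gridded isopleth area over the unfolded surface
    area; the true area rescales it by the analytic floor-plus-wall area of
    the enclosure, removing grid discretization from the reported size.
    """
    proportion = estimate.area / surface.total_area
    return proportion, proportion * spec.surface_area()


def density_to_ascii_grid(density: DensitySurface, path) -> None:
    """Write a density surface in ESRI ASCII grid format (row-major, north up)."""
    header = (
        f"ncols {density.density.shape[0]}\n"
        f"nrows {density.density.shape[1]}\n"
        f"xllcorner {density.x_edges[0]}\n"
        f"yllcorner {density.y_edges[0]}\n"
        f"cellsize {density.cell_size}\n"
        "NODATA_value -9999\n"
    )
    grid = np.where(density.inside, density.density, -9999.0)
    # ASCII grids are written top row first (max y)
    body = "\n".join(
        " ".join(f"{v:.8g}" for v in grid[:, j]) for j in range(grid.shape[1] - 1, -1, -1)
    )
    with open(path, "w") as fh:
        fh.write(header + body + "\n")


def range_to_geojson(estimate: RangeEstimate, density: DensitySurface) -> dict:
    """Isopleth member cells dissolved into a GeoJSON (multi)polygon."""
    from shapely.geometry import box as _box, mapping
    from shapely.ops import unary_union

    cells = []
    xs, ys = density.x_edges, density.y_edges
    ii, jj = np.nonzero(estimate.member)
    for i, j in zip(ii, jj):
        cells.append(_box(xs[i], ys[j], xs[i + 1], ys[j + 1]))
    geom = unary_union(cells) if cells else _box(0, 0, 0, 0)
    return {
        "type": "Feature",
        "properties": {"level": estimate.level, "area_cm2": estimate.area,
                       "proportion": estimate.proportion},
        "geometry": mapping(geom),
    }


def element_use(dataset, drop_excluded_hours: bool = True):
    """Subject-level and summary use of elements and usage categories.

    From the 2-min location stream: per subject x condition x phase, the
    proportion of fixes on each element (ground/wall/ceiling/furniture) and
    in each usage category (In Hide / On Furniture / Open Space), then the
    across-subject mean and SD.  Returns (subject_level, summary) frames.
    """
    import pandas as pd

    meta = dataset.sessions_with_phase()[["session_id", "condition", "phase"]]
    df = dataset.locations.merge(meta, on="session_id", how="left")
    if drop_excluded_hours:
        df = df[df["phase"] != "excluded"]

    frames = []
    for col in ("element", "usage"):
        counts = (
            df.groupby(["subject_id", "condition", "phase", col], sort=True)
            .size()
            .rename("n")
            .reset_index()
        )
        totals = counts.groupby(["subject_id", "condition", "phase"])["n"].transform("sum")
        counts["proportion"] = counts["n"] / totals
        counts = counts.rename(columns={col: "category"})
        counts["kind"] = col
        frames.append(counts)
    subject_level = pd.concat(frames, ignore_index=True)

    # complete the category grid with zeros so means include non-users,
    # but only for (subject, condition, phase) groups that have fixes
    full = []
    for kind in ("element", "usage"):
        sub = subject_level[subject_level["kind"] == kind]
        if sub.empty:
            continue
        wide = sub.pivot_table(
            index=["subject_id", "condition", "phase"], columns="category",
            values="proportion", fill_value=0.0,
        )
        long = wide.stack().rename("proportion").reset_index()
        long["kind"] = kind
        full.append(long)
    completed = pd.concat(full, ignore_index=True)

    summary = (
        completed.groupby(["kind", "condition", "phase", "category"], sort=True)
        ["proportion"].agg(mean="mean", sd="std", n_subjects="size").reset_index()
    )
    return completed, summary
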