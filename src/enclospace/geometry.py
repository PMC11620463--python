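"""Enclosure geometry: 3-D box enclosures, surface unfolding, and zones.

A terrarium is modeled as a rectangular box whose interior floor and four
walls form the surface an animal can occupy.  For planar space-use analysis
the surface is *unfolded* into a single 2-D "cross" (net) diagram: the floor
stays central and each wall rotates outward about its shared floor edge, so
a point at height ``z`` on a wall lands at planar distance ``z`` from the
hinge edge.  This preserves each panel's area and distances-from-ground,
which is what isopleth areas and zone proportions depend on.

Recorded locations arrive on a square observation-map grid (600x600 by
default); :func:`map_grid_location` scales declared grid regions onto the
physical panels, and :func:`rubbersheet_transform` provides control-point
georeferencing for maps whose drawn panels do not line up with the physical
diagram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator
from shapely.geometry import MultiPoint, MultiPolygon, Point, Polygon, box
from shapely.ops import unary_union, voronoi_diagram

__all__ = [
    "EnclosureSpec",
    "FurnitureElement",
    "GeometryError",
    "InsufficientControlError",
    "InvalidSpecificationError",
    "MapLayout",
    "SurfacePoint",
    "UnassignedZoneError",
    "UnfoldedSurface",
    "UnmappableLocationError",
    "ZonePartition",
    "build_unfolded_surface",
    "complex_enclosure",
    "default_map_layout",
    "default_zone_partition",
    "enclosure_volume",
    "map_grid_location",
    "point_in_zone",
    "rubbersheet_transform",
    "standard_enclosure",
]

GRID_SIZE = 600  # observation-app map grid is 600x600 units

PANELS = ("floor", "wall_S", "wall_N", "wall_W", "wall_E")


class GeometryError(ValueError):
    """Base class for geometry contract violations."""


class InvalidSpecificationError(GeometryError):
    pass


class UnmappableLocationError(GeometryError):
    """A grid point falls outside every declared panel region."""


class UnassignedZoneError(GeometryError):
    """A surface point lies outside every zone polygon."""


class InsufficientControlError(GeometryError):
    """Fewer than three non-collinear rubbersheet control pairs."""


@dataclass(frozen=True)
class FurnitureElement:
    """A structural element standing on the enclosure floor.

    ``footprint`` is a simple polygon in floor coordinates (cm).  ``is_hide``
    marks elements an animal can shelter under; ``top_surface`` marks
    elements it can stand on.
    """

    name: str
    footprint: Polygon
    is_hide: bool = False
    top_surface: bool = True

    def __post_init__(self) -> None:
        if not self.footprint.is_valid or self.footprint.area <= 0:
            raise InvalidSpecificationError(
                f"furniture {self.name!r}: footprint must be a simple polygon "
                "with positive area"
            )


@dataclass(frozen=True)
class SurfacePoint:
    """A point on the unfolded plane, tagged with its panel of origin."""

    x: float
    y: float
    panel: str = "floor"

    def __post_init__(self) -> None:
        if self.panel not in PANELS:
            raise InvalidSpecificationError(f"unknown panel {self.panel!r}")


@dataclass(frozen=True)
class ZonePartition:
    """An ordered list of named zones tiling the unfolded surface.

    Zone order is semantic: boundary points are assigned to the earliest
    zone containing them (documented tie-break of :func:`point_in_zone`).
    """

    zones: tuple[tuple[str, Polygon | MultiPolygon], ...]

    def __post_init__(self) -> None:
        if len(self.zones) < 1:
            raise InvalidSpecificationError("a partition needs at least one zone")
        names = [n for n, _ in self.zones]
        if len(set(names)) != len(names):
            raise InvalidSpecificationError("zone names must be unique")

    @property
    def n_zones(self) -> int:
        return len(self.zones)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.zones]

    def area_proportions(self) -> dict[str, float]:
        """Expected-use proportions p_i = zone area / total partition area."""
        areas = {n: g.area for n, g in self.zones}
        total = sum(areas.values())
        return {n: a / total for n, a in areas.items()}

    def validate_against(self, surface: "UnfoldedSurface", rtol: float = 1e-6) -> None:
        """Check the zones tile the surface with disjoint interiors."""
        total = sum(g.area for _, g in self.zones)
        if not math.isclose(total, surface.total_area, rel_tol=rtol):
            raise InvalidSpecificationError(
                f"zone areas sum to {total:.6g}, surface area is "
                f"{surface.total_area:.6g}"
            )
        geoms = [g for _, g in self.zones]
        for i in range(len(geoms)):
            for j in range(i + 1, len(geoms)):
                inter = geoms[i].intersection(geoms[j]).area
                if inter > rtol * surface.total_area:
                    raise InvalidSpecificationError(
                        f"zones {self.zones[i][0]!r} and {self.zones[j][0]!r} "
                        "have overlapping interiors"
                    )


@dataclass(frozen=True)
class EnclosureSpec:
    """Physical description of one housing condition.

    Dimensions in cm; ``length`` runs along x, ``width`` along y, ``height``
    along z.  Furniture footprints must lie within the floor rectangle.
    """

    label: str
    length: float
    width: float
    height: float
    substrate_depth: float = 0.0
    furniture: tuple[FurnitureElement, ...] = ()
    zones: ZonePartition | None = None

    def __post_init__(self) -> None:
        for dim, val in (("length", self.length), ("width", self.width),
                         ("height", self.height)):
            if not (val > 0):
                raise InvalidSpecificationError(
                    f"{self.label}: {dim} must be positive, got {val}"
                )
        floor = box(0, 0, self.length, self.width)
        for f in self.furniture:
            if not floor.buffer(1e-9).contains(f.footprint):
                raise InvalidSpecificationError(
                    f"{self.label}: footprint of {f.name!r} extends beyond the floor"
                )

    @property
    def floor_area(self) -> float:
        return self.length * self.width

    @property
    def wall_area(self) -> float:
        return 2 * self.height * (self.length + self.width)

    def surface_area(self, include_ceiling: bool = False) -> float:
        """Analytic floor + wall area (optionally + ceiling) in cm^2."""
        area = self.floor_area + self.wall_area
        if include_ceiling:
            area += self.floor_area
        return area

    def hide_names(self) -> set[str]:
        return {f.name for f in self.furniture if f.is_hide}


def enclosure_volume(spec: EnclosureSpec) -> float:
    """Interior volume length * width * height in cm^3."""
    return spec.length * spec.width * spec.height


@dataclass(frozen=True)
class UnfoldedSurface:
    """The floor-plus-wall-flaps net of an enclosure.

    Floor occupies ``[0, L] x [0, W]``; the south/north flaps extend below
    y=0 / above y=W and the west/east flaps left of x=0 / right of x=L, each
    by the wall height.  Distance from the hinge edge equals height above
    the floor.
    """

    spec: EnclosureSpec
    panels: dict[str, Polygon] = field(repr=False)

    @property
    def floor_polygon(self) -> Polygon:
        return self.panels["floor"]

    @property
    def wall_flaps(self) -> dict[str, Polygon]:
        return {k: v for k, v in self.panels.items() if k != "floor"}

    @property
    def total_area(self) -> float:
        return sum(p.area for p in self.panels.values())

    @property
    def polygon(self) -> Polygon:
        """Union of all panels (the cross-shaped outline)."""
        return unary_union(list(self.panels.values()))

    def contains(self, p: SurfacePoint, tol: float = 1e-9) -> bool:
        return self.panels[p.panel].buffer(tol).covers(Point(p.x, p.y))

    def to_plane(self, x: float, y: float, z: float) -> SurfacePoint:
        """Map a 3-D surface position to the unfolded plane.

        Accepts floor points (z == 0) and wall points (position on one of
        the four vertical boundary planes).  Ceiling or interior points have
        no image on the diagram and raise :class:`UnmappableLocationError`.
        """
        L, W, H = self.spec.length, self.spec.width, self.spec.height
        tol = 1e-9
        if not (0 - tol <= z <= H + tol):
            raise UnmappableLocationError(f"z={z} outside [0, {H}]")
        if abs(z) <= tol and 0 <= x <= L and 0 <= y <= W:
            return SurfacePoint(x, y, "floor")
        if abs(y) <= tol and 0 <= x <= L:
            return SurfacePoint(x, -z, "wall_S")
        if abs(y - W) <= tol and 0 <= x <= L:
            return SurfacePoint(x, W + z, "wall_N")
        if abs(x) <= tol and 0 <= y <= W:
            return SurfacePoint(-z, y, "wall_W")
        if abs(x - L) <= tol and 0 <= y <= W:
            return SurfacePoint(L + z, y, "wall_E")
        raise UnmappableLocationError(
            f"({x}, {y}, {z}) is not on the floor or a wall of {self.spec.label}"
        )

    def to_enclosure(self, p: SurfacePoint) -> tuple[float, float, float]:
        """Invert :meth:`to_plane`: recover the 3-D surface position."""
        L, W = self.spec.length, self.spec.width
        if not self.contains(p):
            raise UnmappableLocationError(f"{p} is not on panel {p.panel!r}")
        if p.panel == "floor":
            return (p.x, p.y, 0.0)
        if p.panel == "wall_S":
            return (p.x, 0.0, -p.y)
        if p.panel == "wall_N":
            return (p.x, W, p.y - W)
        if p.panel == "wall_W":
            return (0.0, p.y, -p.x)
        return (L, p.y, p.x - L)  # wall_E


def build_unfolded_surface(spec: EnclosureSpec) -> UnfoldedSurface:
    """Unfold an enclosure's floor and walls into the cross-shaped net."""
    L, W, H = spec.length, spec.width, spec.height
    panels = {
        "floor": box(0, 0, L, W),
        "wall_S": box(0, -H, L, 0),
        "wall_N": box(0, W, L, W + H),
        "wall_W": box(-H, 0, 0, W),
        "wall_E": box(L, 0, L + H, W),
    }
    return UnfoldedSurface(spec=spec, panels=panels)


# ---------------------------------------------------------------------------
# map-grid import


@dataclass(frozen=True)
class MapLayout:
    """Which rectangular regions of the observation grid depict which panels.

    ``regions[panel] = (gx0, gy0, gx1, gy1)`` in grid units; each region is
    scaled linearly onto its panel's physical rectangle.  Grid y increases
    downward on screen maps, but only the declared correspondence matters:
    region corner (gx0, gy0) maps to the panel rectangle's min corner.
    """

    regions: dict[str, tuple[float, float, float, float]]
    grid_size: int = GRID_SIZE

    def __post_init__(self) -> None:
        for panel, (gx0, gy0, gx1, gy1) in self.regions.items():
            if panel not in PANELS:
                raise InvalidSpecificationError(f"unknown panel {panel!r}")
            if gx1 <= gx0 or gy1 <= gy0:
                raise InvalidSpecificationError(
                    f"degenerate grid region for {panel!r}"
                )


def default_map_layout(spec: EnclosureSpec, grid_size: int = GRID_SIZE) -> MapLayout:
    """Inscribe the unfolded cross into the square grid at uniform scale.

    The cross's bounding box ``[-H, L+H] x [-H, W+H]`` is anchored at grid
    (0, 0) and scaled by a single factor so the longer extent spans the
    whole grid — mirroring a map drawn to scale in the observation app.
    """
    surface = build_unfolded_surface(spec)
    L, W, H = spec.length, spec.width, spec.height
    extent = max(L + 2 * H, W + 2 * H)
    scale = grid_size / extent  # grid units per cm
    regions = {}
    for panel, poly in surface.panels.items():
        x0, y0, x1, y1 = poly.bounds
        regions[panel] = (
            (x0 + H) * scale,
            (y0 + H) * scale,
            (x1 + H) * scale,
            (y1 + H) * scale,
        )
    return MapLayout(regions=regions, grid_size=grid_size)


def map_grid_location(
    gx: float, gy: float, spec: EnclosureSpec, map_layout: MapLayout
) -> SurfacePoint:
    """Scale a recorded grid location onto the unfolded surface.

    Panels are tried in declaration order (floor first in the default
    layout) so locations on a shared region edge resolve deterministically.
    Grid cells are half-open ``[g, g+1)``; the scaling is continuous-linear.
    """
    if not (0 <= gx < map_layout.grid_size and 0 <= gy < map_layout.grid_size):
        raise UnmappableLocationError(
            f"grid point ({gx}, {gy}) outside the {map_layout.grid_size}-grid"
        )
    surface = build_unfolded_surface(spec)
    for panel, (gx0, gy0, gx1, gy1) in map_layout.regions.items():
        if gx0 <= gx <= gx1 and gy0 <= gy <= gy1:
            x0, y0, x1, y1 = surface.panels[panel].bounds
            x = x0 + (gx - gx0) / (gx1 - gx0) * (x1 - x0)
            y = y0 + (gy - gy0) / (gy1 - gy0) * (y1 - y0)
            return SurfacePoint(x, y, panel)
    raise UnmappableLocationError(
        f"grid point ({gx}, {gy}) outside every declared panel region"
    )


# ---------------------------------------------------------------------------
# rubbersheet georeferencing


def _affine_fit(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares affine map src -> dst as a 2x3 matrix [A | b]."""
    n = len(src)
    X = np.hstack([src, np.ones((n, 1))])
    coef, *_ = np.linalg.lstsq(X, dst, rcond=None)
    return coef.T  # (2, 3)


def rubbersheet_transform(
    control_pairs: list[tuple[tuple[float, float], tuple[float, float]]],
    p: tuple[float, float],
) -> tuple[float, float]:
    """Piecewise-smooth control-point georeferencing of a single point.

    A global affine map is fit to the control pairs by least squares; the
    residual displacements at the controls are then interpolated with a
    smooth piecewise-cubic (Clough–Tocher) scheme inside the control hull.
    Each control source therefore maps exactly onto its target, the map is
    smooth between controls, and outside the hull it degrades to the global
    affine fit.
    """
    if len(control_pairs) < 3:
        raise InsufficientControlError("need at least 3 control pairs")
    src = np.asarray([s for s, _ in control_pairs], dtype=float)
    dst = np.asarray([t for _, t in control_pairs], dtype=float)
    # collinearity check: rank of centered sources must be 2
    if np.linalg.matrix_rank(src - src.mean(axis=0), tol=1e-9) < 2:
        raise InsufficientControlError("control sources are collinear")
    M = _affine_fit(src, dst)
    resid = dst - (src @ M[:, :2].T + M[:, 2])
    q = np.asarray(p, dtype=float)
    out = q @ M[:, :2].T + M[:, 2]
    if np.max(np.abs(resid)) > 1e-12:
        interp = CloughTocher2DInterpolator(src, resid, fill_value=np.nan)
        d = interp(q[None, :])[0]
        if not np.any(np.isnan(d)):  # inside the hull
            out = out + d
    return (float(out[0]), float(out[1]))


# ---------------------------------------------------------------------------
# zones


def point_in_zone(p: SurfacePoint, zones: ZonePartition) -> str:
    """Assign a surface point to a zone (spatial join for one point).

    Boundary points belong to the earliest zone in partition order.
    """
    pt = Point(p.x, p.y)
    for name, geom in zones.zones:
        if geom.covers(pt):
            return name
    # tolerate float fuzz on outer boundaries before giving up
    for name, geom in zones.zones:
        if geom.distance(pt) < 1e-9:
            return name
    raise UnassignedZoneError(f"({p.x}, {p.y}) lies outside every zone")


def default_zone_partition(
    surface: UnfoldedSurface, n_floor_zones: int | None = None
) -> ZonePartition:
    """Furniture-centred zones on the floor plus one wall zone.

    The floor is split into the Voronoi cells of the furniture footprint
    centroids (one zone per element, named "<element> Zone"); the four wall
    flaps form a single "Wall Zone".  This is a documented approximation of
    a hand-drawn zone map: real zone maps should be supplied explicitly.
    """
    spec = surface.spec
    floor = surface.floor_polygon
    zones: list[tuple[str, Polygon | MultiPolygon]] = []
    if len(spec.furniture) == 0:
        zones.append(("Floor Zone", floor))
    elif len(spec.furniture) == 1:
        zones.append((f"{spec.furniture[0].name} Zone", floor))
    else:
        seeds = [f.footprint.centroid for f in spec.furniture]
        cells = voronoi_diagram(MultiPoint(seeds), envelope=floor.buffer(10.0))
        # match each Voronoi cell to its seed, clip to the floor
        for f, seed in zip(spec.furniture, seeds):
            cell = next(g for g in cells.geoms if g.covers(seed))
            zones.append((f"{f.name} Zone", cell.intersection(floor)))
    wall = unary_union(list(surface.wall_flaps.values()))
    zones.append(("Wall Zone", wall))
    return ZonePartition(zones=tuple(zones))


def zone_partition_to_geojson(zones: ZonePartition) -> dict:
    """Zone polygons as a GeoJSON FeatureCollection (plane coordinates, cm)."""
    from shapely.geometry import mapping

    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"name": name, "order": i},
                "geometry": mapping(geom),
            }
            for i, (name, geom) in enumerate(zones.zones)
        ],
    }


def zone_partition_from_geojson(obj: dict) -> ZonePartition:
    """Rebuild a ZonePartition from :func:`zone_partition_to_geojson` output."""
    from shapely.geometry import shape

    feats = sorted(obj["features"], key=lambda f: f["properties"].get("order", 0))
    return ZonePartition(
        zones=tuple(
            (f["properties"]["name"], shape(f["geometry"])) for f in feats
        )
    )


# ---------------------------------------------------------------------------
# the study's two housing conditions


def standard_enclosure() -> EnclosureSpec:
    """Standard housing: 27x27x21 cm bin with cork bark and a water dish."""
    cork = FurnitureElement(
        "Cork Bark", box(8, 10, 20, 17), is_hide=False, top_surface=True
    )
    return EnclosureSpec(
        label="Standard", length=27, width=27, height=21,
        substrate_depth=2.5, furniture=(cork,),
    )


def complex_enclosure() -> EnclosureSpec:
    """Complex housing: 71x41x31 cm container with six structural elements.

    Two plastic plants, a dead-fall branch, a plaster rock cave, an inverted
    garden pot with a cut-out entrance, and a large U-shaped wooden hide
    ("Log").  The branch, cave, pot, and log can shelter an animal.
    """
    furniture = (
        FurnitureElement("Plant A", box(6, 28, 14, 36), top_surface=False),
        FurnitureElement("Plant B", box(58, 5, 66, 13), top_surface=False),
        FurnitureElement("Branch", box(22, 4, 46, 12), is_hide=True),
        FurnitureElement("Rock Cave", box(8, 6, 16, 14), is_hide=True),
        FurnitureElement("Garden Pot", box(54, 26, 64, 36), is_hide=True),
        FurnitureElement("Log", box(28, 24, 48, 36), is_hide=True),
    )
    return EnclosureSpec(
        label="Complex", length=71, width=41, height=31,
        substrate_depth=2.5, furniture=furniture,
    )
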