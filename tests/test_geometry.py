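"""Unfolding, map-grid import, rubbersheeting, and zone assignment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, Polygon, box

from enclospace.geometry import (
    EnclosureSpec,
    FurnitureElement,
    InsufficientControlError,
    InvalidSpecificationError,
    SurfacePoint,
    UnassignedZoneError,
    UnmappableLocationError,
    ZonePartition,
    build_unfolded_surface,
    default_map_layout,
    default_zone_partition,
    enclosure_volume,
    map_grid_location,
    point_in_zone,
    rubbersheet_transform,
    zone_partition_from_geojson,
    zone_partition_to_geojson,
)


class TestUnfolding:
    def test_standard_areas(self, standard_spec, standard_surface):
        assert standard_spec.floor_area == 27 * 27 == 729
        assert standard_surface.total_area == pytest.approx(729 + 4 * 27 * 21)
        assert standard_surface.total_area == pytest.approx(2997)

    def test_complex_areas(self, complex_spec, complex_surface):
        expected = 71 * 41 + 2 * 71 * 31 + 2 * 41 * 31
        assert expected == 9855
        assert complex_surface.total_area == pytest.approx(expected)

    def test_panel_areas_match_3d(self, complex_spec, complex_surface):
        L, W, H = complex_spec.length, complex_spec.width, complex_spec.height
        flaps = complex_surface.wall_flaps
        assert flaps["wall_S"].area == pytest.approx(L * H)
        assert flaps["wall_E"].area == pytest.approx(W * H)

    def test_hinge_identity_unit_cube(self):
        spec = EnclosureSpec(label="unit", length=1, width=1, height=1)
        surf = build_unfolded_surface(spec)
        p = surf.to_plane(0.5, 0.0, 0.0)
        # a wall point at height 0 sits exactly on the hinge edge
        assert p.y == pytest.approx(0.0)

    def test_wall_point_distance_from_hinge(self, standard_surface):
        p = standard_surface.to_plane(10.0, 0.0, 7.5)
        assert p.panel == "wall_S"
        assert abs(p.y) == pytest.approx(7.5)

    @given(
        x=st.floats(0, 27), y=st.sampled_from([0.0, 27.0]),
        z=st.floats(0, 21),
    )
    @settings(deadline=None, max_examples=50)
    def test_unfold_roundtrip_walls(self, x, y, z):
        surf = build_unfolded_surface(
            EnclosureSpec(label="s", length=27, width=27, height=21)
        )
        back = surf.to_enclosure(surf.to_plane(x, y, z))
        assert np.allclose(back, (x, y, z), atol=1e-9)

    @given(x=st.floats(0, 71), y=st.floats(0, 41))
    @settings(deadline=None, max_examples=50)
    def test_unfold_roundtrip_floor(self, x, y):
        surf = build_unfolded_surface(
            EnclosureSpec(label="c", length=71, width=41, height=31)
        )
        assert np.allclose(surf.to_enclosure(surf.to_plane(x, y, 0.0)),
                           (x, y, 0.0), atol=1e-9)

    def test_ceiling_has_no_image(self, standard_surface):
        with pytest.raises(UnmappableLocationError):
            standard_surface.to_plane(13.0, 13.0, 21.0)

    def test_invalid_dimension_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            EnclosureSpec(label="bad", length=0, width=10, height=10)

    def test_furniture_outside_floor_rejected(self):
        f = FurnitureElement("big", box(-5, 0, 5, 5))
        with pytest.raises(InvalidSpecificationError):
            EnclosureSpec(label="bad", length=10, width=10, height=5,
                          furniture=(f,))


class TestVolume:
    def test_printed_dimensions(self, standard_spec, complex_spec):
        assert enclosure_volume(standard_spec) == 27 * 27 * 21 == 15309
        assert enclosure_volume(complex_spec) == 71 * 41 * 31 == 90241

    def test_complex_about_six_times_larger(self, standard_spec, complex_spec):
        ratio = enclosure_volume(complex_spec) / enclosure_volume(standard_spec)
        assert round(ratio) == 6


class TestMapGrid:
    def test_floor_region_corner_maps_to_floor_corner(self, standard_spec):
        layout = default_map_layout(standard_spec)
        gx0, gy0, _, _ = layout.regions["floor"]
        p = map_grid_location(gx0, gy0, standard_spec, layout)
        assert (p.x, p.y, p.panel) == (0.0, 0.0, "floor")

    def test_floor_region_centroid_maps_to_floor_center(self, standard_spec):
        layout = default_map_layout(standard_spec)
        gx0, gy0, gx1, gy1 = layout.regions["floor"]
        p = map_grid_location((gx0 + gx1) / 2, (gy0 + gy1) / 2,
                              standard_spec, layout)
        assert (p.x, p.y) == pytest.approx((13.5, 13.5))

    def test_wall_region_center_maps_to_half_height(self, standard_spec):
        layout = default_map_layout(standard_spec)
        gx0, gy0, gx1, gy1 = layout.regions["wall_S"]
        p = map_grid_location((gx0 + gx1) / 2, (gy0 + gy1) / 2,
                              standard_spec, layout)
        surf = build_unfolded_surface(standard_spec)
        _, _, z = surf.to_enclosure(p)
        assert z == pytest.approx(21 / 2)

    def test_unmappable_point_flagged(self, standard_spec):
        layout = default_map_layout(standard_spec)
        with pytest.raises(UnmappableLocationError):
            # the cross's corner notches are not part of any panel
            map_grid_location(1.0, 1.0, standard_spec, layout)
        with pytest.raises(UnmappableLocationError):
            map_grid_location(-1.0, 5.0, standard_spec, layout)


class TestRubbersheet:
    CORNERS = [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)]

    def test_exact_at_controls(self):
        pairs = [((0, 0), (1, 2)), ((10, 0), (11, 1)), ((4, 9), (5, 10.5)),
                 ((7, 3), (6.5, 3.5))]
        for src, dst in pairs:
            out = rubbersheet_transform(pairs, src)
            assert out == pytest.approx(dst, abs=1e-9)

    def test_identity_controls_identity_map(self):
        pairs = [(c, c) for c in self.CORNERS]
        for p in [(5, 5), (2.5, 7.5), (9, 1)]:
            assert rubbersheet_transform(pairs, p) == pytest.approx(p)

    def test_pure_translation(self):
        pairs = [(c, (c[0] + 5, c[1])) for c in self.CORNERS]
        assert rubbersheet_transform(pairs, (3.3, 4.4)) == pytest.approx((8.3, 4.4))

    def test_affine_outside_hull(self):
        pairs = [(c, (2 * c[0], 2 * c[1])) for c in self.CORNERS]
        assert rubbersheet_transform(pairs, (20.0, 20.0)) == pytest.approx((40, 40))

    def test_insufficient_controls(self):
        with pytest.raises(InsufficientControlError):
            rubbersheet_transform([((0, 0), (0, 0)), ((1, 1), (1, 1))], (0.5, 0.5))
        collinear = [((0, 0), (0, 0)), ((1, 1), (1, 1)), ((2, 2), (2, 2))]
        with pytest.raises(InsufficientControlError):
            rubbersheet_transform(collinear, (0.5, 0.5))


def _ray_casting(poly: Polygon, x: float, y: float) -> bool:
    """Independent even-odd ray-casting point-in-polygon check."""
    geoms = getattr(poly, "geoms", [poly])
    for g in geoms:
        rings = [g.exterior] + list(g.interiors)
        inside = False
        for ring in rings:
            coords = list(ring.coords)
            j = len(coords) - 2
            for i in range(len(coords) - 1):
                xi, yi = coords[i]
                xj, yj = coords[j]
                if (yi > y) != (yj > y) and (
                    x < (xj - xi) * (y - yi) / (yj - yi) + xi
                ):
                    inside = not inside
                j = i
        if inside:
            return True
    return False


class TestZones:
    def test_partition_tiles_surface(self, complex_surface, complex_zones):
        complex_zones.validate_against(complex_surface)
        total = sum(g.area for _, g in complex_zones.zones)
        assert total == pytest.approx(complex_surface.total_area, rel=1e-9)

    def test_interior_point(self, complex_zones):
        # centroid of the Log footprint is strictly inside the Log Zone
        log = dict(complex_zones.zones)["Log Zone"]
        c = log.representative_point()
        assert point_in_zone(SurfacePoint(c.x, c.y), complex_zones) == "Log Zone"

    def test_boundary_tie_break_earliest_zone(self):
        zp = ZonePartition(zones=(
            ("left", box(0, 0, 5, 10)), ("right", box(5, 0, 10, 10)),
        ))
        assert point_in_zone(SurfacePoint(5.0, 5.0), zp) == "left"

    def test_outside_all_zones(self, complex_zones):
        with pytest.raises(UnassignedZoneError):
            point_in_zone(SurfacePoint(500.0, 500.0), complex_zones)

    def test_agrees_with_ray_casting_oracle(self, complex_surface, complex_zones, rng):
        x0, y0, x1, y1 = complex_surface.polygon.bounds
        hits = 0
        checked = 0
        for _ in range(1000):
            x = rng.uniform(x0, x1)
            y = rng.uniform(y0, y1)
            expected = [
                name for name, g in complex_zones.zones if _ray_casting(g, x, y)
            ]
            if not expected:
                continue
            checked += 1
            # skip points within float fuzz of a shared boundary
            pt = Point(x, y)
            near_edge = any(
                g.boundary.distance(pt) < 1e-9 for _, g in complex_zones.zones
            )
            if near_edge:
                continue
            got = point_in_zone(SurfacePoint(x, y), complex_zones)
            hits += got == expected[0]
        assert checked > 500
        assert hits == pytest.approx(checked)

    def test_geojson_roundtrip(self, complex_zones):
        gj = zone_partition_to_geojson(complex_zones)
        back = zone_partition_from_geojson(gj)
        assert back.names == complex_zones.names
        for (_, a), (_, b) in zip(back.zones, complex_zones.zones):
            assert a.symmetric_difference(b).area < 1e-9
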