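"""Geometry construction: NACA sections, placement, domain assembly, spiral metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon

from spiralfoil import geometry as geo
from spiralfoil.exceptions import GeometryError, PlacementError


class TestNaca4:
    def test_symmetric_code_has_zero_camber_and_mirror_symmetry(self):
        x = np.linspace(0, 300, 500)
        assert np.all(geo.naca4_camber("0030", 300, x) == 0.0)
        prof = geo.naca4_profile("0030", 300, 100)
        # reflecting about the chord line maps the polygon onto itself
        mirrored = prof * np.array([1.0, -1.0])
        p1, p2 = Polygon(prof), Polygon(mirrored)
        assert p1.symmetric_difference(p2).area < 1e-9 * p1.area

    def test_cambered_9730_max_camber_position_and_height(self):
        # standard 4-digit camber law evaluated at x/c = p
        x = np.linspace(0, 300, 20001)
        yc = geo.naca4_camber("9730", 300, x)
        assert yc.max() == pytest.approx(0.09 * 300, rel=1e-9)
        assert x[np.argmax(yc)] == pytest.approx(0.7 * 300, abs=0.05)

    def test_9730_max_thickness_matches_brute_force_sampling(self):
        # brute-force max over dense sampling of the thickness polynomial
        x = np.linspace(0, 300, 200001)
        yt = geo.naca4_thickness("9730", 300, x)
        assert 2 * yt.max() == pytest.approx(0.30 * 300, rel=2e-4)
        assert x[np.argmax(yt)] / 300 == pytest.approx(0.30, abs=0.01)

    def test_profile_is_simple_and_closed(self):
        prof = geo.naca4_profile("9730", 300, 200)
        assert np.allclose(prof[0], prof[-1])
        assert Polygon(prof).is_valid

    @pytest.mark.parametrize("bad", ["973", "97a0", "9750", "9700", "973012"])
    def test_malformed_codes_rejected(self, bad):
        with pytest.raises(GeometryError):
            geo.parse_naca4(bad)

    def test_too_few_points_rejected(self):
        with pytest.raises(GeometryError):
            geo.naca4_profile("9730", 300, 10)


class TestPlacement:
    def test_zero_angle_zero_anchor_is_identity(self):
        prof = geo.naca4_profile("9730", 300, 80)
        spec = geo.HydrofoilSpec(attack_angle=0.0, anchor=(0.0, 0.0))
        assert np.allclose(geo.place_hydrofoil(prof, spec), prof)

    def test_rigid_rotation_preserves_area(self):
        prof = geo.naca4_profile("9730", 300, 120)
        spec = geo.HydrofoilSpec(attack_angle=30.0, anchor=(250.0, 62.0))
        placed = geo.place_hydrofoil(prof, spec)
        assert Polygon(placed).area == pytest.approx(Polygon(prof).area, rel=1e-9)

    def test_rotated_extent_matches_vertex_transform_oracle(self):
        # brute-force min/max of the explicitly rotated vertex cloud
        prof = geo.naca4_profile("9730", 300, 150)
        spec = geo.HydrofoilSpec(attack_angle=30.0, anchor=(100.0, 130.0))
        placed = geo.place_hydrofoil(prof, spec)
        a = math.radians(30.0)
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        oracle = prof @ rot.T + np.array([100.0, 130.0])
        assert np.allclose(placed.min(axis=0), oracle.min(axis=0))
        assert np.allclose(placed.max(axis=0), oracle.max(axis=0))
        # axial extent bounded by the chord (rotation cannot stretch it)
        assert placed[:, 0].max() - placed[:, 0].min() <= 300.0 + 1e-9

    def test_placement_outside_channel_raises(self):
        prof = geo.naca4_profile("9730", 300, 80)
        spec = geo.HydrofoilSpec(attack_angle=30.0, anchor=(0.0, 250.0))
        with pytest.raises(PlacementError):
            geo.place_hydrofoil(prof, spec, channel_width=300.0)


class TestDomain:
    def test_default_outlet_partition_is_75_50_175(self):
        dom = geo.build_downstream_domain()
        assert dom.outlet_partition == (75.0, 50.0, 175.0)
        assert sum(dom.outlet_partition) == dom.width

    def test_wall_omitted_gives_single_full_width_outlet(self):
        dom = geo.build_downstream_domain(include_wall=False)
        assert dom.ctc_width == dom.width
        assert dom.waste_width == 0.0

    def test_centered_wall_partition(self):
        wall = geo.SeparationWallSpec(center_offset=150.0, minor_diameter=50.0)
        dom = geo.build_downstream_domain(wall=wall)
        assert dom.outlet_partition == (125.0, 50.0, 125.0)

    def test_solids_are_simple_and_disjoint(self):
        dom = geo.build_downstream_domain()
        polys = [Polygon(p) for p in dom.solids()]
        assert all(p.is_valid for p in polys)
        assert not polys[0].intersects(polys[1])

    def test_wall_touching_channel_wall_rejected(self):
        wall = geo.SeparationWallSpec(center_offset=20.0, minor_diameter=50.0)
        with pytest.raises(GeometryError):
            geo.build_downstream_domain(wall=wall)

    def test_export_roundtrip(self, tmp_path):
        dom = geo.build_downstream_domain()
        paths = dom.export(tmp_path)
        assert (tmp_path / "domain.json").exists()
        assert len(paths) == 3


class TestSpiralMetrics:
    def test_reference_channel_hydraulic_diameter(self):
        m = geo.spiral_metrics(geo.SpiralSpec(width=300, depth=100))
        assert m["hydraulic_diameter"] == pytest.approx(150.0)

    def test_square_duct_hydraulic_diameter_equals_side(self):
        m = geo.spiral_metrics(geo.SpiralSpec(width=120, depth=120))
        assert m["hydraulic_diameter"] == pytest.approx(120.0)

    def test_arc_length_against_polyline_oracle(self):
        spec = geo.SpiralSpec(width=300, depth=100, loops=4, gap=150,
                              start_radius=1000)
        m = geo.spiral_metrics(spec)
        theta = np.linspace(0, 2 * np.pi * spec.loops, 100001)
        r = spec.start_radius + spec.pitch / (2 * np.pi) * theta
        xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        poly_len = np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1))
        assert m["centerline_length"] == pytest.approx(poly_len, rel=1e-3)

    @given(
        w=st.floats(50, 1000),
        g=st.floats(0, 500),
        loops=st.integers(1, 8),
    )
    @settings(max_examples=50, deadline=None)
    def test_pitch_is_width_plus_gap(self, w, g, loops):
        spec = geo.SpiralSpec(width=w, depth=100, loops=loops, gap=g)
        assert geo.spiral_metrics(spec)["pitch"] == pytest.approx(w + g)

    def test_invalid_specs_rejected(self):
        with pytest.raises(GeometryError):
            geo.SpiralSpec(width=-1)
        with pytest.raises(GeometryError):
            geo.SpiralSpec(loops=0)
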