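"""Geometry profiles, obstruction, strain, modulus and wall tension."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coasim.cohort import generate_material_curve, make_group
from coasim.geometry import (
    build_diameter_profile,
    compute_obstruction,
    export_surface_stl,
    forward_strain,
    invert_obstruction,
    normalized_wall_tension,
    radial_strain,
    scale_profile_to_age,
    tangent_modulus,
    tune_modulus,
)


class TestDiameterProfile:
    def test_constant_stations(self):
        prof = build_diameter_profile([(-10, 5), (0, 5), (10, 5)])
        assert np.allclose(prof(np.linspace(-10, 10, 41)), 5.0)

    def test_interpolates_stations_exactly(self):
        pts = [(-20, 6.0), (-5, 4.5), (0, 2.1), (8, 5.0), (20, 5.5)]
        prof = build_diameter_profile(pts)
        for s, d in pts:
            assert prof(s) == pytest.approx(d, rel=1e-12)

    def test_no_overshoot_below_minimum(self):
        prof = build_diameter_profile([(-10, 5), (0, 2), (10, 5)])
        s = np.linspace(-10, 10, 401)
        vals = prof(s)
        assert vals.min() == pytest.approx(2.0, rel=1e-9)
        assert np.all(vals >= 2.0 - 1e-9)

    def test_duplicate_station_rejected(self):
        with pytest.raises(ValueError):
            build_diameter_profile([(-1, 5), (-1, 5), (2, 4)])


class TestScaleProfile:
    _pts = [(-30, 5.5), (-10, 5.2), (0, 5.0), (10, 5.2), (30, 5.6)]

    def test_identity_at_same_weight(self):
        prof = build_diameter_profile(self._pts)
        scaled = scale_profile_to_age(prof, 4.35, 4.35)
        assert np.allclose(scaled.d_mm, prof.d_mm)

    def test_control_geometric_scaling(self):
        prof = build_diameter_profile(self._pts)
        scaled = scale_profile_to_age(prof, 4.35, 1.5)
        assert np.allclose(scaled.d_mm, prof.d_mm * (1.5 / 4.35) ** (1 / 3))

    def test_permanent_coarctation_held_at_wire(self):
        """The throat stays at the wire while the reference shrinks younger."""
        g = make_group("permanent", "ge20")
        pts = [(-30, 6.5), (-10, 6.0), (0, 1.6), (10, 6.0), (30, 6.5)]
        prof = build_diameter_profile(pts, coa_diameter_mm=1.6)
        for w_young in (3.35, 1.82, 1.5):
            scaled = scale_profile_to_age(prof, 4.35, w_young, group=g, t_weeks=1.0)
            assert scaled.coa_diameter_mm == pytest.approx(1.6)
            assert scaled(0.0) == pytest.approx(1.6, rel=1e-6)
            assert scaled(-30.0) < 6.5  # reference did shrink


class TestObstruction:
    def test_reference_values(self):
        assert compute_obstruction(1.6, 5.66) == pytest.approx(92.0, abs=0.05)
        assert compute_obstruction(4.12, 5.66) == pytest.approx(47.0, abs=0.1)
        assert compute_obstruction(3.0, 3.0) == 0.0

    def test_larger_than_reference_rejected(self):
        with pytest.raises(ValueError):
            compute_obstruction(6.0, 5.0)

    @given(st.floats(0.0, 99.9), st.floats(1.0, 10.0))
    @settings(max_examples=60, deadline=None)
    def test_invert_round_trip(self, obs, d_ref):
        d = invert_obstruction(obs, d_ref)
        assert compute_obstruction(d, d_ref) == pytest.approx(obs, abs=1e-9)


class TestStrainModulus:
    def test_radial_strain_values(self):
        assert radial_strain(5.0, 5.55) == pytest.approx(11.0)
        assert radial_strain(4.0, 4.48) == pytest.approx(12.0)
        assert radial_strain(3.0, 3.0) == 0.0

    def test_negative_strain_warns(self):
        with pytest.warns(UserWarning):
            assert radial_strain(5.0, 4.9) < 0

    def test_tangent_modulus_linear(self):
        curve = generate_material_curve(200.0, 0.1, coef_b=0.0)
        for eps in (0.0, 0.1, 0.3):
            assert tangent_modulus(curve, eps) == pytest.approx(200.0, rel=1e-9)

    def test_tangent_modulus_exponential(self):
        curve = generate_material_curve(500 * np.exp(0.55), 0.11, coef_b=5.0)
        assert tangent_modulus(curve, 0.11) == pytest.approx(866.6, abs=0.1)

    def test_tangent_outside_domain_rejected(self):
        curve = generate_material_curve(200.0, 0.1)
        with pytest.raises(ValueError):
            tangent_modulus(curve, 0.9)

    def test_tune_modulus_reference(self):
        # thin-wall relation at the control operating point
        assert tune_modulus(11.0, 0.29, 3.05, 14.9) == pytest.approx(190.0, abs=1.0)

    @given(st.floats(1.0, 30.0), st.floats(0.1, 1.0), st.floats(1.0, 6.0),
           st.floats(5.0, 40.0))
    @settings(max_examples=60, deadline=None)
    def test_modulus_strain_round_trip(self, eps, h, r, pp):
        e = tune_modulus(eps, h, r, pp)
        assert forward_strain(e, h, r, pp) == pytest.approx(eps, rel=1e-12)

    def test_zero_strain_rejected(self):
        with pytest.raises(ValueError):
            tune_modulus(0.0, 0.3, 3.0, 14.9)


class TestWallTension:
    def test_unit_conversion_product(self):
        assert normalized_wall_tension(70.0, 3.3, 3.0) == pytest.approx(2800, rel=0.001)

    def test_zero_displacement(self):
        assert normalized_wall_tension(70.0, 3.0, 3.0) == 0.0

    def test_control_anchor(self):
        # systolic 63.15 mmHg on an 11 % strained 2.7 mm radius: ~2500 dyn/cm
        assert normalized_wall_tension(63.15, 2.997, 2.7) == pytest.approx(2500, rel=0.01)

    def test_negative_displacement_clamped(self):
        with pytest.warns(UserWarning):
            assert normalized_wall_tension(70.0, 2.9, 3.0) == 0.0

    @given(st.floats(10, 120), st.floats(0.0, 1.0))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_pressure_and_displacement(self, p, disp):
        base = normalized_wall_tension(p, 3.0 + disp, 3.0)
        assert normalized_wall_tension(p + 5, 3.0 + disp, 3.0) >= base
        assert normalized_wall_tension(p, 3.0 + disp + 0.1, 3.0) >= base


def test_stl_export_watertight_and_area(tmp_path):
    """Surface-of-revolution export: watertight, cross-sections match profile."""
    trimesh = pytest.importorskip("trimesh")
    prof = build_diameter_profile([(-20, 6.0), (0, 3.0), (20, 6.0)])
    path = tmp_path / "vessel.stl"
    export_surface_stl(prof, path, n_theta=128, ds_mm=0.5)
    mesh = trimesh.load_mesh(path)
    assert mesh.is_watertight
    for s in (-10.0, 0.0, 12.5):
        section = mesh.section(plane_origin=[0, 0, s], plane_normal=[0, 0, 1])
        area = section.to_2D()[0].area if hasattr(section, "to_2D") else None
        if area is None:
            continue
        expected = np.pi * (0.5 * float(prof(s))) ** 2
        assert area == pytest.approx(expected, rel=0.005)
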