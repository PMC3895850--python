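"""Phantom generator: rendering, encoding, ground truth, cine series."""

import numpy as np
import pytest

import densewall as dw
from densewall.phantom import (
    TETRAHEDRAL_DIRECTIONS,
    circle_rectangle_area,
    deform_points,
    disk_coverage,
    true_displacement,
)

from conftest import replace


class TestCircleRectangleOverlap:
    @pytest.mark.parametrize(
        "rect",
        [
            (-0.5, -0.5, 0.5, 0.5),
            (0.6, 0.2, 1.4, 0.9),
            (-2.0, -2.0, 2.0, 2.0),
            (0.9, -0.3, 1.3, 0.3),
            (-1.2, 0.7, 0.1, 1.6),
        ],
    )
    def test_matches_supersampled_oracle(self, rect):
        x0, y0, x1, y1 = rect
        exact = circle_rectangle_area(0.0, 0.0, 1.0, x0, y0, x1, y1)
        n = 1500
        xs = np.linspace(x0, x1, n)
        ys = np.linspace(y0, y1, n)
        X, Y = np.meshgrid(xs, ys)
        mc = np.mean(X**2 + Y**2 <= 1.0) * (x1 - x0) * (y1 - y0)
        assert exact == pytest.approx(mc, abs=5e-3)

    def test_full_disk_inside_large_rectangle(self):
        assert circle_rectangle_area(0, 0, 2.0, -5, -5, 5, 5) == pytest.approx(
            np.pi * 4.0, rel=1e-12
        )

    def test_coverage_sums_to_disk_area(self):
        frac = disk_coverage((32.0, 32.0), 10.0, (28, 28), 2.3)
        assert frac.sum() * 2.3**2 == pytest.approx(np.pi * 100.0, rel=1e-10)


class TestSpecValidation:
    def test_invariants_enforced(self, identity_spec):
        with pytest.raises(dw.ParameterError):
            replace(identity_spec, wall_thickness=-1.0).validate()
        with pytest.raises(dw.ParameterError):
            replace(identity_spec, mid_radius=1.0, wall_thickness=3.0).validate()
        with pytest.raises(dw.ParameterError):
            replace(
                identity_spec, stretch_pattern=dw.StretchPattern(0.5, ((0.6, 0.0),))
            ).validate()
        with pytest.raises(dw.ParameterError):
            replace(identity_spec, lumen_magnitude=2.0).validate()
        with pytest.raises(dw.ParameterError):
            replace(identity_spec, snr=-3.0).validate()

    def test_spec_dict_round_trip(self, asymmetric_spec):
        spec = replace(asymmetric_spec, rotation=0.1, translation=(1.0, -2.0))
        assert dw.PhantomSpec.from_dict(spec.to_dict()) == spec


class TestMakePhantom:
    def test_identity_deformation_gives_zero_phase(self, identity_spec):
        acq, truth, delin = dw.make_phantom(identity_spec)
        assert np.allclose(acq.phases[:, delin.mask], 0.0)
        assert np.allclose(truth.displacement, 0.0)

    def test_phase_encodes_displacement_projection(self):
        """In-plane phase magnitude pi/2 for 3.125 mm radial motion at
        k_e = 0.08 cycles/mm, by phi = 2 pi k_e u."""
        spec = dw.PhantomSpec(
            stretch_pattern=dw.StretchPattern(1.0 + 3.125 / 15.0),
            encoding_directions=((0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)),
        )
        acq, truth, delin = dw.make_phantom(spec)
        u = truth.displacement[delin.mask]
        assert np.allclose(np.linalg.norm(u[:, :2], axis=1), 3.125, atol=1e-9)
        phi_xy = 2 * np.pi * 0.08 * u[:, :2]  # unwrapped in-plane phase
        assert np.allclose(np.linalg.norm(phi_xy, axis=1), np.pi / 2, atol=1e-9)
        # stored phases are the wrapped projections (no wraps occur here)
        assert np.allclose(acq.phases[1][delin.mask], phi_xy[:, 0], atol=1e-12)

    def test_wrap_handling_matches_modular_arithmetic(self):
        """6.5 mm displacement at k_e = 0.08 -> phase 1.04 pi stored as
        1.04 pi - 2 pi."""
        assert dw.wrap_phase(1.04 * np.pi) == pytest.approx(1.04 * np.pi - 2 * np.pi)
        spec = dw.PhantomSpec(
            stretch_pattern=dw.StretchPattern(1.0 + 6.5 / 15.0),
            encoding_directions=((0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)),
        )
        acq, truth, delin = dw.make_phantom(spec)
        phi_unwrapped = 2 * np.pi * 0.08 * truth.displacement[..., 0]
        expect = phi_unwrapped - 2 * np.pi * np.round(phi_unwrapped / (2 * np.pi))
        assert np.allclose(acq.phases[1][delin.mask], expect[delin.mask], atol=1e-12)
        assert np.any(np.abs(phi_unwrapped[delin.mask]) > np.pi)  # wraps did occur

    def test_black_blood_lumen_below_exclusion_threshold(self, uniform_spec):
        acq, truth, delin = dw.make_phantom(uniform_spec, exclusion_fraction=0.3)
        geo = dw.geometry.annulus_pixels(
            truth.contours[("inner", "rest")],
            truth.contours[("outer", "rest")],
            acq.magnitude.shape,
            acq.pixel_spacing,
        )
        lumen = disk_coverage(
            uniform_spec.center_mm,
            uniform_spec.mid_radius - uniform_spec.wall_thickness / 2,
            acq.magnitude.shape,
            uniform_spec.pixel_spacing,
        ) > 0.999
        threshold = 0.3 * np.median(acq.magnitude[geo])
        assert np.all(acq.magnitude[lumen] < threshold)

    def test_same_seed_bit_identical(self, uniform_spec):
        spec = replace(uniform_spec, snr=10.0, seed=5)
        a1, t1, _ = dw.make_phantom(spec)
        a2, t2, _ = dw.make_phantom(spec)
        assert np.array_equal(a1.magnitude, a2.magnitude)
        assert np.array_equal(a1.phases, a2.phases)
        a3, _, _ = dw.make_phantom(replace(spec, seed=6))
        assert not np.array_equal(a1.phases, a3.phases)

    def test_ground_truth_displacement_is_analytic_map(self, asymmetric_spec):
        spec = replace(asymmetric_spec, rotation=0.2, through_plane_shift=2.0)
        acq, truth, delin = dw.make_phantom(spec)
        gx, gy = dw.geometry.pixel_centers(
            acq.magnitude.shape, acq.pixel_spacing
        )
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        expect = true_displacement(spec, pts).reshape(truth.displacement.shape)
        assert np.array_equal(truth.displacement, expect)

    def test_ground_truth_round_trip(self, tmp_path, asymmetric_spec):
        acq, truth, delin = dw.make_phantom(asymmetric_spec)
        dw.write_ground_truth(truth, tmp_path / "gt")
        back = dw.read_ground_truth(tmp_path / "gt")
        assert np.array_equal(back.displacement, truth.displacement)
        assert back.spec == truth.spec


class TestAnalyticStretchProfile:
    def test_uniform_scaling_gives_constant_stretch(self):
        spec = dw.PhantomSpec(stretch_pattern=dw.StretchPattern(1.07))
        prof = dw.analytic_stretch_profile(spec, np.linspace(0, 2 * np.pi, 32))
        assert np.allclose(prof, 1.07, atol=1e-9)

    def test_rotation_only_gives_unit_stretch(self):
        spec = dw.PhantomSpec(
            stretch_pattern=dw.StretchPattern(1.0),
            rotation=0.3,
            translation=(2.0, 1.0),
            through_plane_shift=3.0,
        )
        prof = dw.analytic_stretch_profile(spec, np.linspace(0, 2 * np.pi, 32))
        assert np.allclose(prof, 1.0, atol=1e-9)

    def test_matches_polygonal_arc_length_oracle(self, asymmetric_spec):
        """Dense polygonal arc-length densities reproduce the profile."""
        spec = asymmetric_spec
        thetas = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        prof = dw.analytic_stretch_profile(spec, thetas)
        # oracle: 1e5-vertex polygonal approximation of local arc length
        n = 100000
        h = 2 * np.pi / n
        for theta, lam in zip(thetas, prof):
            th = theta + h * np.array([-1.0, 0.0, 1.0])
            ray = dw.geometry.unit_vector_at_angle(th)
            sys = spec.stretch_pattern(th)[:, None] * 15.0 * ray
            dia = 15.0 * ray
            lam_oracle = np.linalg.norm(sys[2] - sys[0]) / np.linalg.norm(
                dia[2] - dia[0]
            )
            assert lam == pytest.approx(lam_oracle, abs=1e-6)


class TestCineSeries:
    def test_identity_deformation_constant_area(self, identity_spec):
        series = dw.make_cine_series(identity_spec, n_frames=8)
        assert dw.relative_area_change(series) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_scaling_area_ratio_is_s_squared(self):
        spec = dw.PhantomSpec(stretch_pattern=dw.StretchPattern(1.2))
        series = dw.make_cine_series(spec, n_frames=21)
        assert series.areas.max() / series.areas.min() == pytest.approx(1.44, rel=1e-6)
        assert dw.relative_area_change(series) == pytest.approx(0.44, abs=1e-6)

    def test_two_frames_are_exact_endpoints(self, uniform_spec):
        series = dw.make_cine_series(uniform_spec, n_frames=2)
        rho = uniform_spec.mid_radius - uniform_spec.wall_thickness / 2
        r0 = np.linalg.norm(series.contours[0] - uniform_spec.center_mm, axis=1)
        r1 = np.linalg.norm(series.contours[1] - uniform_spec.center_mm, axis=1)
        assert np.allclose(r0, rho, atol=1e-12)
        assert np.allclose(r1, 1.06 * rho, atol=1e-12)

    def test_single_frame_rejected(self, uniform_spec):
        with pytest.raises(dw.ParameterError):
            dw.make_cine_series(uniform_spec, n_frames=1)

    def test_jitter_is_seeded(self, uniform_spec):
        s1 = dw.make_cine_series(uniform_spec, 6, seed=2, jitter_mm=0.05)
        s2 = dw.make_cine_series(uniform_spec, 6, seed=2, jitter_mm=0.05)
        s3 = dw.make_cine_series(uniform_spec, 6, seed=3, jitter_mm=0.05)
        assert np.array_equal(s1.contours[3], s2.contours[3])
        assert not np.array_equal(s1.contours[3], s3.contours[3])


class TestEncodingRoundTrip:
    def test_noise_free_decode_restores_truth(self, asymmetric_spec):
        spec = replace(
            asymmetric_spec, rotation=0.05, through_plane_shift=1.0
        )
        acq, truth, delin = dw.make_phantom(spec)
        field = dw.decode_displacement(acq, mask=delin.mask)
        err = np.abs(field.u - truth.displacement)[delin.mask]
        assert err.max() < 1e-6  # no wraps occur at this deformation scale

    def test_decode_after_unwrap_when_wraps_occur(self):
        spec = dw.PhantomSpec(stretch_pattern=dw.StretchPattern(1.0 + 6.5 / 15.0))
        acq, truth, delin = dw.make_phantom(spec)
        cert = dw.certainty_from_magnitude(acq.magnitude, delin.mask)
        ref = acq.reference_index
        others = [i for i in range(4) if i != ref]
        net = dw.wrap_phase(acq.phases[others] - acq.phases[ref])
        unwrapped = np.stack(
            [dw.unwrap_poisson(p, delin.mask, cert) for p in net]
        )
        net_dirs = acq.encoding_directions[others] - acq.encoding_directions[ref]
        u = dw.solve_encoding_system(unwrapped, net_dirs, acq.k_e)
        err = np.abs(u - truth.displacement)[delin.mask]
        assert err.max() < 1e-6

    def test_tetrahedral_default_directions(self, uniform_spec):
        acq, _, _ = dw.make_phantom(uniform_spec)
        assert np.allclose(acq.encoding_directions, TETRAHEDRAL_DIRECTIONS)
        assert np.allclose(np.linalg.norm(acq.encoding_directions, axis=1), 1.0)


def test_deform_points_preserves_wall_thickness(asymmetric_spec):
    spec = asymmetric_spec
    theta = np.linspace(0, 2 * np.pi, 32, endpoint=False)
    ray = dw.geometry.unit_vector_at_angle(theta)
    c = spec.center_mm
    inner = deform_points(spec, c + 13.75 * ray)
    outer = deform_points(spec, c + 16.25 * ray)
    thickness = np.linalg.norm((outer - inner)[:, :2], axis=1)
    assert np.allclose(thickness, 2.5, atol=1e-9)
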