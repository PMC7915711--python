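"""Ray tracing of the illumination lens: refraction, lateral fan, elevation
prism, and screen-profile / FWHM analysis."""

import math

import numpy as np
import pytest

from truspa import lens_optics as lo


def unit(angle_deg):
    a = math.radians(angle_deg)
    return np.array([math.sin(a), math.cos(a)])


class TestRefract:
    def test_normal_incidence_unchanged(self):
        d = np.array([0.0, 1.0])
        out, tir = lo.refract(d, np.array([0.0, -1.0]), 1.0, 1.519)
        assert not tir
        np.testing.assert_allclose(out, d, atol=1e-12)

    def test_snell_45_into_glass(self):
        out, tir = lo.refract(unit(45.0), np.array([0.0, -1.0]), 1.0, 1.519)
        assert not tir
        theta_out = math.degrees(math.atan2(out[0], out[1]))
        assert theta_out == pytest.approx(27.744, abs=1e-3)

    def test_total_internal_reflection_past_critical(self):
        # critical angle asin(1/1.519) = 41.17 deg < 45 deg
        _, tir = lo.refract(unit(45.0), np.array([0.0, -1.0]), 1.519, 1.0)
        assert tir

    @pytest.mark.parametrize("bad_dir, bad_norm", [
        (np.array([0.0, 2.0]), np.array([0.0, 1.0])),
        (np.array([0.0, 1.0]), np.array([0.0, 0.0])),
    ])
    def test_validation_errors(self, bad_dir, bad_norm):
        with pytest.raises(ValueError):
            lo.refract(bad_dir, bad_norm, 1.0, 1.5)

    def test_scalar_oracle_equivalence_1000_cases(self, rng):
        """Vector refraction agrees with the scalar Snell closed form."""
        for _ in range(1000):
            theta_in = rng.uniform(0.0, 89.0)
            phi_n = rng.uniform(-180.0, 180.0)
            n1, n2 = rng.uniform(1.0, 2.0, size=2)
            normal = unit(phi_n)
            side = rng.choice([-1.0, 1.0])
            d = unit(phi_n + 180.0 + side * theta_in)
            out, tir = lo.refract(d, normal, n1, n2)
            s = n1 * math.sin(math.radians(theta_in)) / n2
            if s > 1.0:
                assert tir
                continue
            assert not tir
            # compare sin(theta_out) via the 2-D cross product: robust to
            # 1e-9 rad even at near-normal incidence
            sin_got = abs(out[0] * normal[1] - out[1] * normal[0])
            assert sin_got == pytest.approx(s, abs=1e-9)
            assert abs(np.linalg.norm(out) - 1.0) < 1e-12


class TestLensDesignValidation:
    def test_radius_ordering(self):
        with pytest.raises(ValueError):
            lo.LensDesign(inner_radius_mm=12.0, outer_radius_mm=11.5)

    def test_marginal_ray_must_strike_entry(self):
        with pytest.raises(ValueError):
            lo.LensDesign(aperture_lateral_mm=17.0)

    def test_refractive_index_bound(self):
        with pytest.raises(ValueError):
            lo.LensDesign(refractive_index=0.9)

    def test_ray2d_invariants(self):
        with pytest.raises(ValueError):
            lo.Ray2D(np.zeros(2), np.array([0.0, 2.0]))
        with pytest.raises(ValueError):
            lo.Ray2D(np.zeros(2), np.array([0.0, 1.0]), weight=-1.0)


class TestTraceLateral:
    def test_index_matched_lens_passes_straight(self):
        lens = lo.LensDesign(refractive_index=1.0 + 1e-9)
        trace = lo.trace_lateral(lens, 101)
        assert trace.fov_full_angle_deg < 1e-4
        assert trace.tir_count == 0

    def test_default_design_fov_near_105(self, default_trace):
        """The design radii fan the 13 mm beam to ~105 degrees (+-10%)."""
        assert default_trace.fov_full_angle_deg == pytest.approx(105.0, rel=0.10)

    def test_chief_ray_undeviated(self, default_trace):
        angles = default_trace.exit_rays.angles_deg
        chief = np.argmin(np.abs(default_trace.exit_rays.origins[:, 0]))
        assert abs(angles[chief]) < 1e-9

    def test_even_ray_count_rejected(self, default_lens):
        with pytest.raises(ValueError):
            lo.trace_lateral(default_lens, 100)

    def test_marginal_incidence_concentric(self):
        """Chord-height geometry: marginal incidence = asin(6.5/8)."""
        lens = lo.LensDesign.concentric()
        entry, _, z0 = lens.lateral_surfaces()
        origin = np.array([[6.5, z0]])
        d = np.array([[0.0, 1.0]])
        s = entry.intersect(origin, d)
        p = origin + s[:, None] * d
        n = entry.normal_at(p)[0]
        inc = math.degrees(math.acos(abs(np.dot([0.0, 1.0], n))))
        assert inc == pytest.approx(math.degrees(math.asin(6.5 / 8.0)), abs=1e-9)
        assert inc == pytest.approx(54.34, abs=0.01)

    def test_bouguer_invariant_concentric(self):
        """n r sin(phi) about the shared centre is conserved to 1e-9."""
        trace = lo.trace_lateral(lo.LensDesign.concentric(), 501)
        n = 1.519
        k_in = lo.bouguer_invariant(
            trace.entry_rays.select(trace.surviving_mask), (0.0, 0.0), 1.0
        )
        k_glass = lo.bouguer_invariant(trace.glass_rays, (0.0, 0.0), n)
        k_out = lo.bouguer_invariant(trace.exit_rays, (0.0, 0.0), 1.0)
        np.testing.assert_allclose(k_glass, k_in, atol=1e-9)
        np.testing.assert_allclose(k_out, k_in, atol=1e-9)

    def test_fov_monotone_in_curvature_concentric(self):
        """Stronger entry curvature (smaller inner radius) -> wider fan."""
        fovs = [
            lo.trace_lateral(lo.LensDesign.concentric(inner_radius_mm=r), 301
                             ).fov_full_angle_deg
            for r in (10.0, 9.0, 8.0, 7.5, 7.0)
        ]
        assert all(b > a for a, b in zip(fovs, fovs[1:]))

    def test_energy_conservation(self, default_trace):
        total_in = default_trace.entry_rays.weights.sum()
        total_out = default_trace.exit_rays.weights.sum() + default_trace.tir_weight
        assert total_out == pytest.approx(total_in, abs=1e-12)

    @pytest.mark.parametrize("geometry", ["diverging", "concentric"])
    def test_reversibility(self, geometry):
        """Reversed exit rays retrace to the original entry rays."""
        lens = lo.LensDesign(geometry=geometry)
        trace = lo.trace_lateral(lens, 101)
        entry, exit_, z0 = lens.lateral_surfaces()
        n = lens.refractive_index
        # step the exit rays forward, then send them back
        origins = trace.exit_rays.origins + 1.0 * trace.exit_rays.directions
        dirs = -trace.exit_rays.directions
        s = exit_.intersect(origins, dirs)
        assert not np.any(np.isnan(s))
        p2 = origins + s[:, None] * dirs
        d_glass, tir = lo.refract(dirs, exit_.normal_at(p2), 1.0, n)
        assert not np.any(tir)
        s1 = entry.intersect(p2, d_glass)
        assert not np.any(np.isnan(s1))
        p1 = p2 + s1[:, None] * d_glass
        d_out, tir = lo.refract(d_glass, entry.normal_at(p1), n, 1.0)
        assert not np.any(tir)
        np.testing.assert_allclose(
            d_out, np.tile([0.0, -1.0], (len(d_out), 1)), atol=1e-9
        )
        x_at_start = p1[:, 0] + (z0 - p1[:, 1]) / d_out[:, 1] * d_out[:, 0]
        x_expected = trace.entry_rays.origins[trace.surviving_mask, 0]
        np.testing.assert_allclose(x_at_start, x_expected, atol=1e-6)


class TestTraceElevation:
    def test_parallel_faces_no_deviation(self):
        lens = lo.LensDesign(oblique_inclination_deg=90.0)
        res = lo.trace_elevation(lens)
        assert res.deviation_angle_deg == 0.0
        assert math.isinf(res.crossing_depth_mm)

    def test_prism_deviation_80deg_face(self, default_lens):
        res = lo.trace_elevation(default_lens)
        expected = math.degrees(
            math.asin(1.519 * math.sin(math.radians(10.0)))) - 10.0
        assert res.deviation_angle_deg == pytest.approx(expected, abs=1e-9)
        assert res.deviation_angle_deg == pytest.approx(5.29, abs=0.01)

    def test_crossing_depth_design_focus(self, default_lens):
        res = lo.trace_elevation(default_lens, beam_center_offset_mm=2.316)
        assert res.crossing_depth_mm == pytest.approx(
            2.316 / math.tan(math.radians(res.deviation_angle_deg)), rel=1e-12
        )
        assert res.crossing_depth_mm == pytest.approx(25.0, abs=0.01)

    def test_offset_validation(self, default_lens):
        with pytest.raises(ValueError):
            lo.trace_elevation(default_lens, beam_center_offset_mm=0.0)


class TestScreenProfileAndFwhm:
    def _rays_from_positions(self, xs, weights=None):
        n = len(xs)
        return lo.RayBundle(
            np.stack([xs, np.zeros(n)], axis=1),
            np.tile([0.0, 1.0], (n, 1)),
            np.ones(n) if weights is None else weights,
        )

    def test_profile_integral_equals_weight(self):
        rays = self._rays_from_positions(np.linspace(-5, 5, 1001))
        prof = lo.screen_profile(rays, depth_mm=30.0, bin_width_mm=0.5)
        assert prof.intensity.sum() == pytest.approx(1001.0)

    def test_rectangular_profile_fwhm(self):
        xs = np.linspace(-5.0, 5.0, 20001)
        prof = lo.BeamProfile(10.0, xs, np.where(np.abs(xs) <= 3.0, 1.0, 0.0),
                              smoothing_window=1)
        assert lo.fwhm(prof) == pytest.approx(6.0, abs=2 * (xs[1] - xs[0]))

    def test_gaussian_profile_fwhm(self):
        xs = np.arange(-60.0, 60.0, 0.1)
        prof = lo.BeamProfile(10.0, xs, np.exp(-0.5 * (xs / 10.0) ** 2),
                              smoothing_window=1)
        assert lo.fwhm(prof) == pytest.approx(23.548, abs=0.1)

    def test_bimodal_outermost_crossings(self):
        """Split no-lens beams: width spans rise of the first lobe to fall
        of the second, computed by brute-force crossing scan."""
        xs = np.arange(-20.0, 20.0, 0.05)
        y = (np.where(np.abs(xs + 8) <= 2.0, 1.0, 0.0)
             + np.where(np.abs(xs - 8) <= 2.0, 1.0, 0.0))
        prof = lo.BeamProfile(10.0, xs, y, smoothing_window=1)
        # brute-force oracle: outermost samples at or above half max
        above = np.nonzero(y >= 0.5)[0]
        oracle = xs[above[-1]] - xs[above[0]]
        assert oracle == pytest.approx(20.0, abs=0.1)
        assert lo.fwhm(prof) == pytest.approx(oracle, abs=0.1)

    def test_smoothing_window_default_is_30(self):
        rays = self._rays_from_positions(np.linspace(-5, 5, 101))
        prof = lo.screen_profile(rays, depth_mm=10.0)
        assert prof.smoothing_window == 30

    def test_empty_screen_errors(self):
        rays = self._rays_from_positions(np.array([0.0]))
        with pytest.raises(ValueError, match="no energy"):
            lo.screen_profile(rays, depth_mm=-5.0)
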