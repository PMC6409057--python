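"""Level-set machinery: profiles, SDF init, window stats, forces, curvature,
reaction-diffusion stabilization."""

import numpy as np
import pytest

import drls
from drls.levelset import (
    LocalStats,
    mean_curvature,
    ms_force,
    um_force,
    window_stat_fields,
)


class TestSmoothedProfiles:
    def test_interior_saturation_and_midpoint(self):
        eps = 1.5
        assert drls.smoothed_heaviside(np.array(-10 * eps), eps) == pytest.approx(1.0, abs=1e-3)
        assert drls.smoothed_heaviside(np.array(10 * eps), eps) == pytest.approx(0.0, abs=1e-3)
        assert drls.smoothed_heaviside(np.array(0.0), eps) == 0.5

    def test_monotone_and_bounded(self):
        eps = 2.0
        x = np.linspace(-5, 5, 401)
        h = drls.smoothed_heaviside(x, eps)
        assert np.all(np.diff(h) <= 1e-15)  # decreasing in phi (interior profile)
        assert h.min() >= 0 and h.max() <= 1

    def test_dirac_matches_profile_derivative(self):
        # |dH/dphi| via central differences at 20 sampled points
        eps = 1.5
        xs = np.linspace(-1.4 * eps, 1.4 * eps, 20)
        h_step = 1e-6
        for x in xs:
            num = (
                drls.smoothed_heaviside(np.array(x - h_step), eps)
                - drls.smoothed_heaviside(np.array(x + h_step), eps)
            ) / (2 * h_step)
            assert float(num) == pytest.approx(
                float(drls.smoothed_dirac(np.array(x), eps)), abs=1e-4
            )

    def test_dirac_nonnegative_symmetric_unit_mass(self):
        eps = 1.5
        x = np.linspace(-3, 3, 6001)
        d = drls.smoothed_dirac(x, eps)
        assert np.all(d >= 0)
        assert np.allclose(d, d[::-1])
        assert np.trapezoid(d, x) == pytest.approx(1.0, abs=1e-6)

    def test_eps_must_be_positive(self):
        with pytest.raises(ValueError):
            drls.smoothed_heaviside(np.zeros(3), 0.0)


class TestInitSdfBall:
    def test_center_value_and_zero_crossing(self):
        field = drls.init_sdf_ball((21, 21, 21), (10, 10, 10), 6)
        assert field.phi[10, 10, 10] == pytest.approx(-6.0)
        assert field.phi[16, 10, 10] == pytest.approx(0.0, abs=1e-12)

    def test_gradient_magnitude_is_unit(self):
        field = drls.init_sdf_ball((41, 41, 41), (20, 20, 20), 10)
        gx, gy, gz = np.gradient(field.phi)
        mag = np.sqrt(gx**2 + gy**2 + gz**2)
        interior = mag[3:-3, 3:-3, 3:-3]
        # away from the exact center singularity
        r = drls.init_sdf_ball((41, 41, 41), (20, 20, 20), 0.001).phi[3:-3, 3:-3, 3:-3]
        sel = r > 3
        assert np.all(np.abs(mag[3:-3, 3:-3, 3:-3][sel] - 1) < 0.05)

    def test_invalid_radius_and_offgrid_ball(self):
        with pytest.raises(ValueError):
            drls.init_sdf_ball((20, 20, 20), (10, 10, 10), -1)
        with pytest.raises(ValueError):
            drls.init_sdf_ball((20, 20, 20), (200, 200, 200), 3)


def brute_force_local_stats(intensity, phi, center, rad, eps):
    """Reference voxel loop for the Heaviside-weighted window statistics."""
    shape = intensity.shape
    su = sv = ain = aout = 0.0
    tot = n = 0.0
    for dx in range(-rad, rad + 1):
        for dy in range(-rad, rad + 1):
            for dz in range(-rad, rad + 1):
                x, y, z = center[0] + dx, center[1] + dy, center[2] + dz
                if not (0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]):
                    continue
                w = float(drls.smoothed_heaviside(np.array(phi[x, y, z]), eps))
                su += intensity[x, y, z] * w
                sv += intensity[x, y, z] * (1 - w)
                ain += w
                aout += 1 - w
                tot += intensity[x, y, z]
                n += 1
    u = su / ain if ain > 1e-9 else tot / n
    v = sv / aout if aout > 1e-9 else tot / n
    return u, v, ain, aout


class TestLocalWindowStats:
    def test_constant_image_means_equal_constant(self):
        vol = drls.ScalarVolume(np.full((20, 20, 20), 7.5))
        phi = drls.init_sdf_ball((20, 20, 20), (9.5,) * 3, 5)
        st = drls.local_window_stats(vol, phi, (12, 9, 9), 4)
        assert st.u_x == pytest.approx(7.5)
        assert st.v_x == pytest.approx(7.5)

    def test_two_level_image_sharp_interface(self):
        shape = (30, 30, 30)
        phi = drls.init_sdf_ball(shape, (14.5,) * 3, 8)
        img = np.where(phi.mask, 40.0, 100.0)
        # sharp Heaviside: tiny eps
        st = drls.local_window_stats(drls.ScalarVolume(img), phi, (22, 14, 14), 5, eps=1e-6)
        assert st.u_x == pytest.approx(40.0, abs=1e-9)
        assert st.v_x == pytest.approx(100.0, abs=1e-9)

    def test_matches_brute_force_on_random_instances(self, rng):
        shape = (17, 15, 13)
        intensity = rng.normal(50, 20, shape)
        phi = rng.normal(0, 3, shape)
        vol = drls.ScalarVolume(intensity)
        for center in [(8, 7, 6), (0, 0, 0), (16, 14, 12), (3, 10, 5)]:
            st = drls.local_window_stats(vol, phi, center, 4, eps=1.5)
            u, v, ain, aout = brute_force_local_stats(intensity, phi, center, 4, 1.5)
            assert st.u_x == pytest.approx(u, abs=1e-10)
            assert st.v_x == pytest.approx(v, abs=1e-10)
            assert st.a_in == pytest.approx(ain, abs=1e-10)
            assert st.a_out == pytest.approx(aout, abs=1e-10)

    def test_field_version_matches_pointwise_version(self, rng):
        shape = (12, 12, 12)
        intensity = rng.normal(0, 1, shape)
        phi = rng.normal(0, 2, shape)
        fields = window_stat_fields(intensity, phi, 3, 1.5)
        vol = drls.ScalarVolume(intensity)
        for center in [(5, 5, 5), (0, 11, 3), (11, 0, 0)]:
            st = drls.local_window_stats(vol, phi, center, 3, eps=1.5)
            assert fields["u"][center] == pytest.approx(st.u_x, abs=1e-10)
            assert fields["v"][center] == pytest.approx(st.v_x, abs=1e-10)
            assert fields["a_in"][center] == pytest.approx(st.a_in, abs=1e-10)

    def test_window_partition_invariant(self, rng):
        shape = (14, 14, 14)
        phi = rng.normal(0, 2, shape)
        vol = drls.ScalarVolume(rng.normal(0, 1, shape))
        st = drls.local_window_stats(vol, phi, (7, 7, 7), 3)
        assert st.a_in + st.a_out == pytest.approx(7**3, abs=1e-9)

    def test_degenerate_window_falls_back_to_full_mean(self):
        vol = drls.ScalarVolume(np.arange(27.0).reshape(3, 3, 3))
        phi = np.full((3, 3, 3), 10.0)  # everything far outside
        st = drls.local_window_stats(vol, phi, (1, 1, 1), 1)
        assert st.degenerate
        assert st.u_x == pytest.approx(vol.data.mean())


def brute_force_speed(intensity, phi, center, rad, lam1, lam2, eps, normalized):
    """Direct evaluation of the surface-localized window speed at one voxel."""
    u, v, ain, aout = brute_force_local_stats(intensity, phi, center, rad, eps)
    shape = intensity.shape
    t_in = t_out = 0.0
    for dx in range(-rad, rad + 1):
        for dy in range(-rad, rad + 1):
            for dz in range(-rad, rad + 1):
                x, y, z = center[0] + dx, center[1] + dy, center[2] + dz
                if not (0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]):
                    continue
                d = float(drls.smoothed_dirac(np.array(phi[x, y, z]), eps))
                t_in += d * (intensity[x, y, z] - u) ** 2
                t_out += d * (intensity[x, y, z] - v) ** 2
    if normalized:
        g = lam1 * t_in / max(ain, 1e-9) - lam2 * t_out / max(aout, 1e-9)
    else:
        g = lam1 * t_in - lam2 * t_out
    return float(drls.smoothed_dirac(np.array(phi[center]), eps)) * g


class TestForces:
    def test_constant_image_zero_speed(self):
        shape = (20, 20, 20)
        vol = drls.ScalarVolume(np.full(shape, 3.0))
        phi = drls.init_sdf_ball(shape, (9.5,) * 3, 5)
        for f in (ms_force, um_force):
            speed = f(vol, phi, 4, 1.0, 1.0)
            assert np.allclose(speed, 0.0, atol=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        shape = (15, 15, 15)
        intensity = rng.normal(50, 20, shape)
        phi = drls.init_sdf_ball(shape, (7, 7, 7), 4).phi + rng.normal(0, 0.3, shape)
        vol = drls.ScalarVolume(intensity)
        ms = ms_force(vol, phi, 3, 1.3, 0.7)
        um = um_force(vol, phi, 3, 1.3, 0.7)
        for center in [(11, 7, 7), (7, 11, 7), (4, 7, 7)]:
            ref_ms = brute_force_speed(intensity, phi, center, 3, 1.3, 0.7, 1.5, True)
            ref_um = brute_force_speed(intensity, phi, center, 3, 1.3, 0.7, 1.5, False)
            assert ms[center] == pytest.approx(ref_ms, abs=1e-8 * max(1, abs(ref_ms)))
            assert um[center] == pytest.approx(ref_um, abs=1e-8 * max(1, abs(ref_um)))

    def test_near_zero_speed_at_true_edge_with_equal_weights(self):
        # planar two-level step split exactly by the zero level set (the
        # interface sits halfway between voxel planes, so the window
        # statistics are symmetric about the edge and the fit terms cancel);
        # a contour offset by 2 voxels feels a strong restoring force
        shape = (24, 24, 24)
        z = np.arange(24, dtype=float) - 11.5
        phi = np.broadcast_to(z, shape).copy()
        img = np.where(phi < 0, 40.0, 100.0)
        vol = drls.ScalarVolume(img)
        core = (slice(8, 16), slice(8, 16))
        f_edge = ms_force(vol, phi, 4, 1.0, 1.0)
        # the speed crosses zero at the interface: the tumor-side plane is
        # pulled inward (negative = grow interior), the background-side plane
        # pushed outward, i.e. the edge is a stable equilibrium...
        assert np.all(f_edge[core + (11,)] < 0)
        assert np.all(f_edge[core + (12,)] > 0)
        # ...and the residual magnitudes there are well below the force on a
        # contour displaced 2 voxels from the edge
        offset = np.abs(ms_force(vol, phi + 2.0, 4, 1.0, 1.0)[core + (slice(9, 11),)])
        assert np.abs(f_edge[core + (slice(11, 13),)]).max() < 0.5 * offset.max()

    def test_lambda1_scales_interior_term_linearly(self, rng):
        shape = (14, 14, 14)
        vol = drls.ScalarVolume(rng.normal(0, 1, shape))
        phi = drls.init_sdf_ball(shape, (6.5,) * 3, 4).phi
        f_base = um_force(vol, phi, 3, 1.0, 0.0)
        f_double = um_force(vol, phi, 3, 2.0, 0.0)
        assert np.allclose(f_double, 2 * f_base, rtol=1e-12)

    def test_um_equals_ms_times_area_when_sides_balanced(self):
        # symmetric two-level plane interface: A_in = A_out in interior windows
        shape = (20, 20, 21)
        z = np.arange(21, dtype=float) - 10.0
        phi = np.broadcast_to(z, shape).copy()
        img = np.where(phi < 0, 1.0, 5.0)
        vol = drls.ScalarVolume(img)
        stats = window_stat_fields(img, phi, 3, 1.5)
        ms = ms_force(vol, phi, 3, 1.0, 2.0)
        um = um_force(vol, phi, 3, 1.0, 2.0)
        # side volumes balance only on the central (zero level set) plane
        core = (slice(5, 15), slice(5, 15), slice(10, 11))
        a = stats["a_in"][core]
        assert np.allclose(a, stats["a_out"][core], atol=1e-9)
        assert np.allclose(um[core], ms[core] * a, rtol=1e-9)


class TestCurvature:
    def test_ball_curvature_matches_2_over_r(self):
        for r in (8, 12):
            shape = (2 * r + 21,) * 3
            c = ((shape[0] - 1) / 2,) * 3
            phi = drls.init_sdf_ball(shape, c, r).phi
            kappa = mean_curvature(phi)
            shell = np.abs(phi) < 0.5
            assert np.median(kappa[shell]) == pytest.approx(2.0 / r, rel=0.15)

    def test_planar_field_zero(self):
        x = np.arange(20.0)
        phi = np.broadcast_to(x[:, None, None], (20, 20, 20)).copy()
        term = drls.curvature_term(phi, mu=0.5)
        assert np.abs(term).max() < 1e-6

    def test_mu_zero_identically_zero(self, rng):
        phi = rng.normal(0, 2, (10, 10, 10))
        assert np.all(drls.curvature_term(phi, 0.0) == 0)


class TestRdStabilize:
    def test_linear_profile_unchanged(self):
        # a unit-slope linear field is harmonic with flat level sets, so the
        # diffusion and reaction terms both vanish (away from the grid
        # border, whose one-sided stencils leak inward one voxel per substep)
        x = np.arange(30.0) - 15
        phi = np.broadcast_to(x[:, None, None], (30, 30, 30)).copy()
        out = drls.rd_stabilize(phi, nu=1.0, substeps=3).phi
        inner = (slice(4, -4),) * 3
        assert np.allclose(out[inner], phi[inner], atol=1e-8)

    def test_steep_interface_max_gradient_decreases(self):
        # a cliff-like profile (slope ~2.5 at the interface) relaxes toward
        # unit slope: the peak gradient magnitude strictly decreases
        x = np.arange(30.0) - 15
        phi = np.broadcast_to(5.0 * np.tanh(x / 2.0)[:, None, None],
                              (30, 30, 30)).copy()
        out = drls.rd_stabilize(phi, nu=1.0, substeps=5).phi
        def max_grad(f):
            g = np.gradient(f)
            return np.sqrt(sum(a**2 for a in g)).max()
        assert max_grad(out) < max_grad(phi)

    def test_ball_sdf_zero_set_preserved(self):
        phi = drls.init_sdf_ball((40, 40, 40), (19.5,) * 3, 12).phi
        out = drls.rd_stabilize(phi, nu=1.0, substeps=2).phi
        a, b = phi < 0, out < 0
        dice = 2 * np.count_nonzero(a & b) / (np.count_nonzero(a) + np.count_nonzero(b))
        assert dice >= 0.99

    def test_stability_bound_enforced(self):
        phi = np.zeros((5, 5, 5))
        with pytest.raises(ValueError):
            drls.rd_stabilize(phi, nu=2.0, dtau=0.2)
        with pytest.raises(ValueError):
            drls.rd_stabilize(phi, nu=-1.0)
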