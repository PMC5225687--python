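import numpy as np
import pytest

from thermofac import snake
from thermofac.nasta_features import FeatureImage, StaWindowSpec, nasta
from thermofac.snake import (RegionStats, SnakeParams, edge_energy_force,
                             evolve_core, evolve_edge, internal_force,
                             nasta_pressure_force, outward_normals,
                             pressure_gate, resample_contour, spring_force,
                             texture_pressure_force)
from thermofac.texture_features import TextureSpec, texture_descriptor
from thermofac.thermio import (Contour, ContourInversionError,
                               DegenerateContourError,
                               DegenerateStatisticsError, GeometryError,
                               ThermalImage, ValidationError)

from conftest import circle_contour


def star_contour(center, n=32, seed=0):
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    radii = 10.0 + rng.uniform(-1.5, 1.5, size=n)
    return Contour(points=np.stack([center[0] + radii * np.cos(theta),
                                    center[1] + radii * np.sin(theta)],
                                   axis=1))


def discrete_internal_energy(pts, alpha, beta):
    d1 = np.roll(pts, -1, axis=0) - pts
    d2 = np.roll(pts, -1, axis=0) - 2.0 * pts + np.roll(pts, 1, axis=0)
    return 0.5 * (alpha * np.sum(d1 * d1) + beta * np.sum(d2 * d2))


class TestSnakeParams:
    def test_negative_weights_rejected(self):
        with pytest.raises(ValidationError):
            SnakeParams(alpha=-0.1)
        with pytest.raises(ValidationError):
            SnakeParams(rho=0.0)

    def test_texture_weight_defaults_are_positive(self):
        p = SnakeParams()
        assert p.q_T > 0

    def test_minimum_point_count(self):
        with pytest.raises(ValidationError):
            SnakeParams(n_points=8)


class TestInternalForce:
    def test_circle_tension_points_to_centroid(self):
        c = circle_contour((0.0, 0.0), 10.0, n=64)
        f = internal_force(c, alpha=1.0, beta=0.0)
        # all force vectors point radially inward with equal magnitude
        inward = -c.points / np.linalg.norm(c.points, axis=1, keepdims=True)
        cosine = np.sum(f * inward, axis=1) / np.linalg.norm(f, axis=1)
        np.testing.assert_allclose(cosine, 1.0, atol=1e-9)
        assert np.ptp(np.linalg.norm(f, axis=1)) < 1e-9

    def test_zero_weights_give_zero_force(self):
        c = circle_contour((0.0, 0.0), 5.0, n=32)
        np.testing.assert_array_equal(internal_force(c, 0.0, 0.0),
                                      np.zeros((32, 2)))

    def test_matches_numeric_gradient_of_discrete_energy(self):
        rng = np.random.default_rng(7)
        c = circle_contour((0.0, 0.0), 10.0, n=32)
        pts = c.points + rng.normal(scale=0.3, size=c.points.shape)
        contour = Contour(points=pts)
        alpha, beta = 0.8, 0.4
        f = internal_force(contour, alpha, beta)
        eps = 1e-6
        num = np.zeros_like(pts)
        for i in range(len(pts)):
            for j in range(2):
                p_hi, p_lo = pts.copy(), pts.copy()
                p_hi[i, j] += eps
                p_lo[i, j] -= eps
                num[i, j] = -(discrete_internal_energy(p_hi, alpha, beta)
                              - discrete_internal_energy(p_lo, alpha, beta)
                              ) / (2 * eps)
        np.testing.assert_allclose(f, num, rtol=1e-6, atol=1e-6)


class TestPressureGate:
    def test_gate_anchor_points(self):
        stats = RegionStats(mu=100.0, sigma=10.0)
        assert pressure_gate(100.0, stats, k=2.0) == 1.0
        assert pressure_gate(120.0, stats, k=2.0) == pytest.approx(0.0)
        assert pressure_gate(160.0, stats, k=2.0) == -1.0

    def test_gate_is_clamped_to_unit_interval(self):
        stats = RegionStats(mu=0.0, sigma=1.0)
        v = np.linspace(-50, 50, 101)
        g = pressure_gate(v, stats, k=1.0)
        assert np.all(g >= -1.0) and np.all(g <= 1.0)

    def test_zero_sigma_is_degenerate(self):
        with pytest.raises(DegenerateStatisticsError):
            pressure_gate(1.0, RegionStats(mu=0.0, sigma=0.0), k=1.0)


class TestPressureForces:
    def test_uniform_map_at_mu_gives_pure_inflation(self):
        vals = np.full((64, 64), 42.0)
        fmap = FeatureImage(values=vals, kind="nasta")
        c = circle_contour((32.0, 32.0), 10.0, n=48)
        f = nasta_pressure_force(c, fmap, RegionStats(42.0, 5.0),
                                 q=0.7, k=1.5)
        np.testing.assert_allclose(f, 0.7 * outward_normals(c.points),
                                   atol=1e-12)

    def test_far_from_mu_gives_pure_deflation(self):
        fmap = FeatureImage(values=np.full((64, 64), 200.0), kind="nasta")
        c = circle_contour((32.0, 32.0), 10.0, n=48)
        f = nasta_pressure_force(c, fmap, RegionStats(10.0, 5.0),
                                 q=0.7, k=1.5)
        np.testing.assert_allclose(f, -0.7 * outward_normals(c.points),
                                   atol=1e-12)

    def test_half_plane_map_splits_force_sign(self):
        vals = np.full((64, 64), 100.0)
        vals[:, 32:] = 140.0          # mu + 2*k*sigma on the right half
        fmap = FeatureImage(values=vals, kind="nasta")
        c = circle_contour((32.0, 32.0), 12.0, n=72)
        f = nasta_pressure_force(c, fmap, RegionStats(100.0, 10.0),
                                 q=1.0, k=2.0)
        radial = np.sum(f * outward_normals(c.points), axis=1)
        cols = c.points[:, 1]
        assert np.all(radial[cols < 30.0] > 0.99)
        assert np.all(radial[cols > 34.0] < -0.99)

    def test_pressure_is_perpendicular_to_tangent(self):
        fmap = FeatureImage(
            values=np.random.default_rng(0).uniform(0, 255, (64, 64)),
            kind="nasta")
        c = star_contour((32.0, 32.0), n=40, seed=1)
        f = nasta_pressure_force(c, fmap, RegionStats(100.0, 30.0),
                                 q=1.0, k=2.0)
        tangent = (np.roll(c.points, -1, axis=0)
                   - np.roll(c.points, 1, axis=0)) / 2.0
        tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
        assert np.max(np.abs(np.sum(f * tangent, axis=1))) < 1e-9

    def test_point_outside_map_is_bounds_error(self):
        fmap = FeatureImage(values=np.zeros((20, 20)), kind="nasta")
        c = circle_contour((10.0, 10.0), 15.0, n=32)
        with pytest.raises(GeometryError):
            nasta_pressure_force(c, fmap, RegionStats(0.0, 1.0), 1.0, 1.0)

    def test_kind_mismatch_rejected(self):
        tex = FeatureImage(values=np.zeros((20, 20)), kind="texture")
        c = circle_contour((10.0, 10.0), 5.0, n=16)
        with pytest.raises(ValidationError):
            nasta_pressure_force(c, tex, RegionStats(0.0, 1.0), 1.0, 1.0)
        nas = FeatureImage(values=np.zeros((20, 20)), kind="nasta")
        with pytest.raises(ValidationError):
            texture_pressure_force(c, nas, RegionStats(0.0, 1.0), 1.0, 1.0)

    def test_texture_half_plane_sign_split(self):
        vals = np.full((64, 64), 0.5)
        vals[:, 32:] = 0.1
        fmap = FeatureImage(values=vals, kind="texture")
        c = circle_contour((32.0, 32.0), 12.0, n=72)
        f = texture_pressure_force(c, fmap, RegionStats(0.5, 0.05),
                                   k_T=2.0, q_T=1.0)
        radial = np.sum(f * outward_normals(c.points), axis=1)
        cols = c.points[:, 1]
        assert np.all(radial[cols < 30.0] > 0.99)
        assert np.all(radial[cols > 34.0] < -0.99)


class TestEdgeEnergyForce:
    def test_constant_image_has_zero_force(self):
        img = ThermalImage(temps=np.full((32, 32), 31.0))
        c = circle_contour((16.0, 16.0), 8.0, n=32)
        np.testing.assert_array_equal(
            edge_energy_force(img, c, gamma=2.0, sigma_g=1.5),
            np.zeros((32, 2)))

    def test_step_edge_attracts_from_the_left(self):
        temps = np.full((32, 32), 30.0)
        temps[:, 16:] = 34.0
        img = ThermalImage(temps=temps)
        c = circle_contour((16.0, 13.0), 2.0, n=16)  # left of the step
        f = edge_energy_force(img, c, gamma=1.0, sigma_g=1.5)
        assert f[:, 1].mean() > 0.0  # net pull toward larger columns

    def test_linear_in_gamma(self):
        rng = np.random.default_rng(2)
        img = ThermalImage(temps=rng.uniform(29, 37, (32, 32)))
        c = circle_contour((16.0, 16.0), 6.0, n=24)
        f1 = edge_energy_force(img, c, gamma=1.5, sigma_g=1.5)
        f2 = edge_energy_force(img, c, gamma=3.0, sigma_g=1.5)
        np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-12)


class TestSpringForce:
    def test_rest_position_has_zero_force(self):
        c = circle_contour((16.0, 16.0), 6.0, n=24)
        np.testing.assert_array_equal(spring_force(c, c, lam=1.0),
                                      np.zeros((24, 2)))

    def test_hooke_law_on_displaced_point(self):
        anchor = circle_contour((16.0, 16.0), 6.0, n=24)
        pts = anchor.points.copy()
        pts[5] += (3.0, 4.0)
        f = spring_force(Contour(points=pts), anchor, lam=1.0)
        np.testing.assert_allclose(f[5], (-3.0, -4.0))
        assert np.linalg.norm(f[5]) == pytest.approx(5.0)

    def test_linear_in_spring_constant(self):
        anchor = circle_contour((16.0, 16.0), 6.0, n=24)
        moved = Contour(points=anchor.points + 0.5)
        np.testing.assert_allclose(spring_force(moved, anchor, 2.0),
                                   2.0 * spring_force(moved, anchor, 1.0))

    def test_point_count_mismatch_rejected(self):
        a = circle_contour((16.0, 16.0), 6.0, n=24)
        b = circle_contour((16.0, 16.0), 6.0, n=32)
        with pytest.raises(ValidationError):
            spring_force(a, b, lam=1.0)


class TestResampling:
    def test_resample_preserves_circle_geometry(self):
        c = circle_contour((0.0, 0.0), 10.0, n=37)
        r = resample_contour(c, 64)
        radii = np.linalg.norm(r.points, axis=1)
        np.testing.assert_allclose(radii, 10.0, atol=0.05)

    def test_resample_enforces_ccw_orientation(self):
        from thermofac.thermio import signed_polygon_area

        cw = Contour(points=circle_contour((0.0, 0.0), 5.0, n=32).points[::-1])
        out = resample_contour(cw, 32)
        assert signed_polygon_area(out.points) > 0


class TestEvolveCore:
    def test_recovers_core_boundary_on_noiseless_phantom(
            self, noiseless_phantom):
        from thermofac.contour_metrics import hausdorff_distance

        img = noiseless_phantom.image
        nmap = nasta(img, StaWindowSpec(L=5))
        init = circle_contour(noiseless_phantom.spec.center, 5.0, n=64)
        res = evolve_core(img, nmap, init, SnakeParams(), controller=None)
        assert res.converged
        assert hausdorff_distance(res.contour,
                                  noiseless_phantom.core_contour) <= 2.0

    def test_pure_tension_shrinks_area_monotonically(self):
        img = ThermalImage(temps=np.full((32, 32), 31.0))
        nmap = FeatureImage(values=np.zeros((32, 32)), kind="nasta")
        init = circle_contour((16.0, 16.0), 6.0, n=16)
        areas = []
        for m in range(1, 9):
            p = SnakeParams(q=0.0, alpha=1.0, beta=0.0, n_points=16,
                            max_iter=m)
            areas.append(evolve_core(img, nmap, init, p, None).contour.area)
        assert np.all(np.diff(areas) < 0)

    def test_pure_tension_ends_in_collapse_error(self):
        img = ThermalImage(temps=np.full((32, 32), 31.0))
        nmap = FeatureImage(values=np.zeros((32, 32)), kind="nasta")
        init = circle_contour((16.0, 16.0), 6.0, n=16)
        with pytest.raises(DegenerateContourError):
            evolve_core(img, nmap, init,
                        SnakeParams(q=0.0, alpha=1.0, beta=0.0, n_points=16),
                        None)

    def test_forced_stop_returns_state_at_first_consultation(
            self, noiseless_phantom):
        from thermofac.fuzzy_control import FuzzyAssessment

        img = noiseless_phantom.image
        nmap = nasta(img, StaWindowSpec(L=5))
        init = circle_contour(noiseless_phantom.spec.center, 5.0, n=64)
        params = SnakeParams()

        def stopper(now, prev, alpha, beta):
            return FuzzyAssessment(inputs=(0, 0, 0), memberships={},
                                   cls="Normal", alpha_new=None,
                                   beta_new=None, stop=True)

        stopped = evolve_core(img, nmap, init, params, stopper)
        ref = evolve_core(img, nmap, init,
                          SnakeParams(max_iter=params.fuzzy_every), None)
        assert stopped.stopped_by == "fuzzy"
        assert stopped.iterations == params.fuzzy_every
        np.testing.assert_allclose(stopped.contour.points, ref.contour.points)

    def test_evolution_is_deterministic(self, noiseless_phantom):
        img = noiseless_phantom.image
        nmap = nasta(img, StaWindowSpec(L=5))
        init = circle_contour(noiseless_phantom.spec.center, 5.0, n=64)
        a = evolve_core(img, nmap, init, SnakeParams(), None)
        b = evolve_core(img, nmap, init, SnakeParams(), None)
        np.testing.assert_array_equal(a.contour.points, b.contour.points)

    def test_max_iter_flags_non_convergence(self, noiseless_phantom):
        img = noiseless_phantom.image
        nmap = nasta(img, StaWindowSpec(L=5))
        init = circle_contour(noiseless_phantom.spec.center, 5.0, n=64)
        res = evolve_core(img, nmap, init, SnakeParams(max_iter=3), None)
        assert not res.converged
        assert res.stopped_by == "max_iter"


class TestEvolveEdge:
    def test_recovers_outer_boundary_on_noiseless_phantom(
            self, noiseless_phantom):
        from thermofac.contour_metrics import hausdorff_distance

        img = noiseless_phantom.image
        nmap = nasta(img, StaWindowSpec(L=5))
        tmap = texture_descriptor(img, TextureSpec())
        init = circle_contour(noiseless_phantom.spec.center, 5.0, n=64)
        params = SnakeParams()
        core = evolve_core(img, nmap, init, params, None)
        edge = evolve_edge(img, tmap, core.contour, params, None)
        assert hausdorff_distance(edge.contour,
                                  noiseless_phantom.edge_contour) <= 2.0

    def test_stiff_spring_pins_result_to_anchor(self, noiseless_phantom):
        from thermofac.contour_metrics import hausdorff_distance

        img = noiseless_phantom.image
        nmap = nasta(img, StaWindowSpec(L=5))
        tmap = texture_descriptor(img, TextureSpec())
        init = circle_contour(noiseless_phantom.spec.center, 5.0, n=64)
        params = SnakeParams()
        core = evolve_core(img, nmap, init, params, None)
        stiff = SnakeParams(lam=1000.0, max_iter=60)
        edge = evolve_edge(img, tmap, core.contour, stiff, None)
        anchor = resample_contour(core.contour, stiff.n_points)
        assert hausdorff_distance(edge.contour, anchor) <= 1.0

    def test_forced_stop_returns_state_at_first_consultation(
            self, noiseless_phantom):
        from thermofac.fuzzy_control import FuzzyAssessment

        img = noiseless_phantom.image
        nmap = nasta(img, StaWindowSpec(L=5))
        tmap = texture_descriptor(img, TextureSpec())
        init = circle_contour(noiseless_phantom.spec.center, 5.0, n=64)
        params = SnakeParams()
        core = evolve_core(img, nmap, init, params, None)

        def stopper(now, prev, alpha, beta):
            return FuzzyAssessment(inputs=(0, 0, 0), memberships={},
                                   cls="Normal", alpha_new=None,
                                   beta_new=None, stop=True)

        stopped = evolve_edge(img, tmap, core.contour, params, stopper)
        ref = evolve_edge(img, tmap, core.contour,
                          SnakeParams(max_iter=params.fuzzy_every), None)
        assert stopped.stopped_by == "fuzzy"
        np.testing.assert_allclose(stopped.contour.points, ref.contour.points)

    def test_result_not_enclosing_core_is_inversion_error(
            self, noiseless_phantom, monkeypatch):
        img = noiseless_phantom.image
        tmap = texture_descriptor(img, TextureSpec())
        core = circle_contour(noiseless_phantom.spec.center, 12.0, n=64)
        # force a uniformly deflating gate so the contour retreats through
        # the anchor; the enclosure guard must flag the inversion
        monkeypatch.setattr(
            snake, "region_stats",
            lambda *a, **k: RegionStats(mu=1e3, sigma=1.0))
        with pytest.raises(ContourInversionError):
            evolve_edge(img, tmap, core,
                        SnakeParams(lam=0.0, max_iter=25, q_T=0.5), None)


class TestInitialContour:
    def test_seed_sits_inside_hot_region(self, noiseless_phantom):
        init = snake.initial_contour(noiseless_phantom.image)
        center = np.asarray(noiseless_phantom.spec.center)
        radii = np.linalg.norm(init.points - init.centroid, axis=1)
        assert np.linalg.norm(init.centroid - center) < 3.0
        assert radii.max() < noiseless_phantom.spec.r_core

    def test_flat_image_falls_back_to_seed_circle(self):
        img = ThermalImage(temps=np.full((64, 64), 31.0))
        init = snake.initial_contour(img)
        radii = np.linalg.norm(init.points - init.centroid, axis=1)
        np.testing.assert_allclose(radii, 5.0, atol=1e-9)
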