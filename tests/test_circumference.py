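import numpy as np
import pytest

from bovimetry.circumference import (
    CircumferenceParams,
    bezier_bridge,
    cubic_bezier,
    fit_profile_svr,
    from_polar,
    measure_circumference,
    section_origin,
    section_plane,
    slice_and_project,
    split_and_fuse,
    to_polar,
)
from bovimetry.geometry import PointCloud
from bovimetry.synthetic import ramanujan_perimeter

from conftest import cylinder_cloud

# fast SVR settings for unit tests (full search budget is exercised in the
# acceptance suite)
FAST = CircumferenceParams(svr_iters=15, search_cap=300, fit_cap=500)


def ellipse_polar(a=0.35, b=0.30, n=2000, gap_deg=0.0, gap_at=-90.0, sigma=0.0, seed=0):
    """(theta, rho) samples of an origin-centred ellipse profile."""
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0, 2 * np.pi, n)
    if gap_deg:
        centre = np.radians(gap_at)
        keep = np.abs((phi - centre + np.pi) % (2 * np.pi) - np.pi) > np.radians(gap_deg / 2)
        phi = phi[keep]
    pts = np.column_stack([a * np.cos(phi), b * np.sin(phi)])
    if sigma:
        pts += rng.normal(0, sigma, pts.shape)
    return to_polar(pts, (0.0, 0.0)), pts


class TestSectionPlane:
    def test_axis_aligned_spine(self):
        plane = section_plane((0, 0, 1.5), (1, 0, 1.2), (1.5, 0, 1.2))
        np.testing.assert_allclose(plane.normal, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(plane.u, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(plane.v, [0, 0, -1], atol=1e-12)

    def test_hand_normalized_oblique_normal(self):
        plane = section_plane((0, 0, 0), (1.0, 0, 1.2), (1.5, 0.1, 1.21))
        np.testing.assert_allclose(plane.normal, [0.980, 0.196, 0.020], atol=5e-4)

    def test_basis_orthonormal_and_back_up(self):
        plane = section_plane((0, 0, 0), (1.0, 0.2, 1.2), (1.6, 0.05, 1.25))
        for a, b in ((plane.u, plane.v), (plane.u, plane.normal), (plane.v, plane.normal)):
            assert abs(a @ b) < 1e-12
        assert plane.v[2] < 0  # v points up (towards smaller z)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(ValueError, match="degenerate spine"):
            section_plane((0, 0, 0), (1, 0, 1.2), (1.0002, 0, 1.2))


class TestSliceAndProject:
    def test_slab_membership_matches_brute_force(self, rng):
        cloud = cylinder_cloud(n=4000, rng=rng)
        plane = section_plane((0.2, 0, 1.6), (0, 0, 1.6), (1, 0, 1.6), tau=0.05)
        sec = slice_and_project(cloud, plane)
        expected = np.abs(cloud.points[:, 0] - 0.2) <= 0.05
        assert len(sec) == expected.sum()

    def test_projection_recovers_ellipse_ring(self, rng):
        cloud = cylinder_cloud(radius_y=0.35, radius_z=0.30, n=6000, rng=rng)
        plane = section_plane((0, 0, 1.6), (0, 0, 1.6), (1, 0, 1.6), tau=0.05)
        sec = slice_and_project(cloud, plane)
        # chart coords are relative to the reference point on the axis
        r = np.sqrt((sec[:, 0] / 0.35) ** 2 + (sec[:, 1] / 0.30) ** 2)
        np.testing.assert_allclose(r, 1.0, atol=1e-9)

    def test_full_width_slab_keeps_everything(self, rng):
        cloud = cylinder_cloud(n=500, rng=rng)
        plane = section_plane((0, 0, 1.6), (0, 0, 1.6), (1, 0, 1.6), tau=10.0)
        assert len(slice_and_project(cloud, plane)) == 500

    def test_empty_slab_raises(self, rng):
        cloud = cylinder_cloud(n=500, rng=rng)
        plane = section_plane((50.0, 0, 1.6), (0, 0, 1.6), (1, 0, 1.6), tau=0.01)
        with pytest.raises(ValueError, match="insufficient section support"):
            slice_and_project(cloud, plane)

    def test_detached_ground_band_removed(self, rng):
        cloud = cylinder_cloud(n=3000, rng=rng, axis_z=1.6)
        ground = np.column_stack(
            [rng.uniform(-1, 1, 800), rng.uniform(-1, 1, 800), np.full(800, 2.48)]
        )
        both = PointCloud(np.vstack([cloud.points, ground]))
        plane = section_plane((0, 0, 1.6), (0, 0, 1.6), (1, 0, 1.6), tau=0.05)
        sec = slice_and_project(both, plane)
        # ground sits at v = -(2.48) + ref v; all body v >= -(1.9)
        assert sec[:, 1].min() > -(1.95 - 1.6) - 0.01


class TestPolarTransform:
    def test_hand_evaluated_axis_points(self):
        sec = np.array([[1.0, 0.0], [0.0, 1.0], [-1, 0], [0, -1], [0.6, 0.6]])
        theta, rho = to_polar(sec, (0.0, 0.0))
        assert theta[0] == pytest.approx(180.0)  # +x maps to 180deg
        assert theta[1] == pytest.approx(270.0)
        assert theta[2] == pytest.approx(0.0)
        assert theta[3] == pytest.approx(90.0)
        assert rho[0] == pytest.approx(1.0)

    def test_circle_constant_radius(self, rng):
        phi = rng.uniform(0, 2 * np.pi, 500)
        sec = 0.4 * np.column_stack([np.cos(phi), np.sin(phi)])
        _, rho = to_polar(sec, (0.0, 0.0))
        np.testing.assert_allclose(rho, 0.4, atol=1e-12)

    def test_origin_outside_hull_rejected(self, rng):
        phi = rng.uniform(0, 2 * np.pi, 200)
        sec = 0.4 * np.column_stack([np.cos(phi), np.sin(phi)])
        with pytest.raises(ValueError, match="outside"):
            to_polar(sec, (2.0, 0.0))

    def test_from_polar_inverts_to_polar(self, rng):
        sec = rng.normal(0, 0.3, (300, 2))
        origin = section_origin(sec)
        theta, rho = to_polar(sec, origin)
        back = from_polar(theta, rho, origin)
        np.testing.assert_allclose(back, sec, atol=1e-9)

    def test_section_origin_on_symmetry_axis_despite_density(self, rng):
        # left half sampled 10x denser than the right: mid-range stays centred
        phi_dense = rng.uniform(np.pi / 2, 3 * np.pi / 2, 2000)
        phi_sparse = rng.uniform(-np.pi / 2, np.pi / 2, 200)
        phi = np.concatenate([phi_dense, phi_sparse])
        sec = np.column_stack([0.35 * np.cos(phi), 0.30 * np.sin(phi)])
        origin = section_origin(sec)
        assert abs(origin[0]) < 0.01


class TestFitProfileSvr:
    def test_noiseless_circle_recovered(self):
        (theta, rho), _ = ellipse_polar(a=0.3, b=0.3, n=800)
        fit = fit_profile_svr(theta, rho, seed=0, params=FAST)
        np.testing.assert_allclose(fit.grid_rho, 0.3, rtol=0.01)

    def test_gapped_noisy_ellipse_within_two_percent(self):
        # full search budget: edge accuracy at the missing arc needs it
        (theta, rho), _ = ellipse_polar(gap_deg=40, gap_at=-90, sigma=0.005, seed=3)
        fit = fit_profile_svr(theta, rho, seed=7)
        phi = np.radians(fit.grid_theta) - np.pi
        true_rho = 1.0 / np.sqrt((np.cos(phi) / 0.35) ** 2 + (np.sin(phi) / 0.30) ** 2)
        assert np.max(np.abs(fit.grid_rho - true_rho) / true_rho) < 0.02

    def test_deterministic_under_seed(self):
        (theta, rho), _ = ellipse_polar(sigma=0.004, seed=5)
        f1 = fit_profile_svr(theta, rho, seed=42, params=FAST)
        f2 = fit_profile_svr(theta, rho, seed=42, params=FAST)
        assert f1.best_params == f2.best_params
        np.testing.assert_array_equal(f1.grid_rho, f2.grid_rho)

    def test_wide_gap_left_unfitted(self):
        (theta, rho), _ = ellipse_polar(gap_deg=60, gap_at=-90)
        fit = fit_profile_svr(theta, rho, seed=0, params=FAST)
        # grid must skip the bottom arc (theta ~ 90 under the polar convention)
        assert not np.any((fit.grid_theta > 70) & (fit.grid_theta < 110))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="50"):
            fit_profile_svr(np.arange(10.0), np.ones(10), seed=0)


class TestSplitAndFuse:
    @staticmethod
    def grid_profile(a=0.35, b=0.30, gap_deg=60.0):
        grid = np.arange(0.0, 360.0)
        phi = np.radians(grid) - np.pi
        rho = 1.0 / np.sqrt((np.cos(phi) / a) ** 2 + (np.sin(phi) / b) ** 2)
        keep = ~((grid > 90 - gap_deg / 2) & (grid < 90 + gap_deg / 2))
        return grid[keep], rho[keep]

    def test_symmetric_profile_is_fixed_point(self):
        gt, gr = self.grid_profile()
        ft, fr, kt, kr = split_and_fuse(gt, gr, (0.0, 0.0))
        phi = np.radians(ft % 360.0) - np.pi
        orig = 1.0 / np.sqrt((np.cos(phi) / 0.35) ** 2 + (np.sin(phi) / 0.30) ** 2)
        np.testing.assert_allclose(fr, orig, atol=1e-9)

    def test_one_sided_bump_halved(self):
        gt, gr = self.grid_profile()
        bump = 0.01 * np.exp(-((gt % 360.0 - 180.0) ** 2) / 50.0)  # +u side only
        ft, fr, kt, kr = split_and_fuse(gt, gr + bump, (0.0, 0.0))
        phi = np.radians(ft % 360.0) - np.pi
        orig = 1.0 / np.sqrt((np.cos(phi) / 0.35) ** 2 + (np.sin(phi) / 0.30) ** 2)
        fbump = 0.01 * np.exp(-((ft % 360.0 - 180.0) ** 2) / 50.0)
        np.testing.assert_allclose(fr, orig + fbump / 2, atol=1e-9)

    def test_asymmetric_noise_smoothed_by_fusion(self, rng):
        from bovimetry.metrics import smoothness

        improved = 0
        trials = 30
        for s in range(trials):
            local = np.random.default_rng(s)
            gt, gr = self.grid_profile()
            upper = (gt % 360.0 > 100) & (gt % 360.0 < 270)
            noisy = gr + np.where(upper, local.normal(0, 0.004, len(gr)), 0.0)
            ft, fr, kt, kr = split_and_fuse(gt, noisy, (0.0, 0.0))
            pre = smoothness(noisy[np.isin(gt, ft % 360.0)])
            post = smoothness(fr)
            improved += post < pre
        assert improved >= 0.9 * trials

    def test_one_sided_profile_rejected(self):
        grid = np.arange(120.0, 250.0)  # only the +u half
        rho = np.full(len(grid), 0.3)
        with pytest.raises(ValueError, match="one-sided"):
            split_and_fuse(grid, rho, (0.0, 0.0))


class TestBezier:
    def test_endpoint_interpolation(self):
        pts = bezier_bridge((0, 0), (1, -1), (4, 0), (1, 1), n_samples=10)
        np.testing.assert_allclose(pts[0], [0, 0], atol=1e-12)
        np.testing.assert_allclose(pts[-1], [4, 0], atol=1e-12)

    def test_collinear_controls_degenerate_to_chord(self):
        pts = bezier_bridge((0.0, 0.0), (1.0, 0.0), (2.0, 0.0), (1.0, 0.0))
        length = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
        assert length == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(pts[:, 1], 0.0, atol=1e-12)

    def test_hand_evaluated_midpoint(self):
        # B(0.5) = ((0.5,-0.75)) for P0=(0,0), Pc1=(0,-1), Pc2=(1,-1), P1=(1,0)
        out = cubic_bezier((0, 0), (0, -1), (1, -1), (1, 0), np.array([0.5]))
        np.testing.assert_allclose(out[0], [0.5, -0.75], atol=1e-12)

    def test_tangent_continuity_at_endpoints(self):
        # end derivatives must align with the supplied tangents (finite
        # differences at fine sampling approximate B'(0), B'(1))
        t0, t1 = np.array([1.0, -0.5]), np.array([1.0, 0.5])
        pts = bezier_bridge((0, 0), t0, (3, 0), t1, n_samples=4000)
        cross2 = lambda a, b: a[0] * b[1] - a[1] * b[0]
        for d, t in ((pts[1] - pts[0], t0), (pts[-1] - pts[-2], t1)):
            sine = abs(cross2(d, t)) / (np.linalg.norm(d) * np.linalg.norm(t))
            assert sine < 1e-3

    def test_zero_chord_rejected(self):
        with pytest.raises(ValueError, match="chord"):
            bezier_bridge((1, 1), (1, 0), (1, 1), (1, 0))


class TestMeasureCircumference:
    def keypoints(self, station=0.0):
        return {
            ("top", "aid"): np.array([station + 0.3, 0.0, 1.30]),
            ("top", "abdomen"): np.array([station, 0.0, 1.30]),
            ("right", "abdomen"): np.array([station, -0.35, 1.6]),
            ("right", "chest"): np.array([station, -0.35, 1.6]),
        }

    def test_clean_elliptic_cylinder_within_one_percent(self, rng):
        cloud = cylinder_cloud(radius_y=0.35, radius_z=0.30, n=12000, rng=rng)
        truth = ramanujan_perimeter(0.35, 0.30)
        girth, prof = measure_circumference(cloud, self.keypoints(), "abdominal", FAST, seed=0)
        assert abs(girth - truth) / truth < 0.01

    def test_circle_with_quarter_gap_within_1p5_percent(self, rng):
        cloud = cylinder_cloud(radius_y=0.3, radius_z=0.3, n=12000, rng=rng)
        # carve a 90 deg ventral gap
        phi = np.arctan2(1.6 - cloud.points[:, 2], cloud.points[:, 1])
        keep = np.abs((phi + np.pi / 2 + np.pi) % (2 * np.pi) - np.pi) > np.radians(45)
        cloud = cloud.select(keep)
        girth, _ = measure_circumference(cloud, self.keypoints(), "abdominal", FAST, seed=0)
        truth = 2 * np.pi * 0.3  # 1.8850
        assert abs(girth - truth) / truth < 0.015

    def test_assembled_curve_closed_and_simple(self, rng):
        from shapely.geometry import LinearRing

        cloud = cylinder_cloud(radius_y=0.35, radius_z=0.30, n=10000, rng=rng, sigma=0.003)
        girth, prof = measure_circumference(cloud, self.keypoints(), "abdominal", FAST, seed=1)
        fused = from_polar(prof.fused_theta % 360.0, prof.fused_rho, prof.origin)
        kept = from_polar(prof.kept_theta % 360.0, prof.kept_rho, prof.origin)
        ring = np.vstack([fused, kept[1:], prof.bridge[1:-1] if len(prof.bridge) else np.empty((0, 2))])
        assert LinearRing(ring).is_simple
        # closure: bridge (or direct closure) ends exactly on the curve ends
        if len(prof.bridge):
            np.testing.assert_allclose(prof.bridge[0], kept[-1], atol=1e-3)
            np.testing.assert_allclose(prof.bridge[-1], fused[0], atol=1e-3)

    def test_stage_failures_name_the_stage(self, rng):
        cloud = cylinder_cloud(n=1000, rng=rng)
        kps = self.keypoints()
        kps[("top", "aid")] = kps[("top", "abdomen")] + 1e-5
        with pytest.raises(ValueError, match="section_plane"):
            measure_circumference(cloud, kps, "abdominal", FAST, seed=0)

    def test_missing_landmark_reported(self, rng):
        cloud = cylinder_cloud(n=1000, rng=rng)
        with pytest.raises(ValueError, match="missing landmark"):
            measure_circumference(cloud, {}, "chest", FAST, seed=0)
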