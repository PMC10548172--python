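"""Wall frame, cardiac angles, transmural profiles, slopes, and line fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fibrient as fb
from fibrient.wallgeom import _wrap_axial_deg


def annulus_mask(shape, inner_vox, outer_vox):
    nz, ny, nx = shape
    yy, xx = np.meshgrid(np.arange(ny) - (ny - 1) / 2,
                         np.arange(nx) - (nx - 1) / 2, indexing="ij")
    r = np.hypot(yy, xx)
    return np.broadcast_to(((r >= inner_vox) & (r <= outer_vox))[None], shape).copy()


class TestCentroid:
    def test_centered_disk(self):
        mask = annulus_mask((4, 41, 41), 0, 15)
        c, c_um = fb.estimate_centroid(mask, 2.0)
        assert np.allclose(c, [1.5, 20.0, 20.0])
        assert np.allclose(c_um, [3.0, 40.0, 40.0])

    def test_two_blobs_weighted_midpoint(self):
        mask = np.zeros((1, 10, 20), bool)
        mask[0, 4:6, 2:4] = True   # 4 voxels at x ~ 2.5
        mask[0, 4:6, 14:18] = True  # 8 voxels at x ~ 15.5
        c, _ = fb.estimate_centroid(mask, 2.0)
        assert c[2] == pytest.approx((4 * 2.5 + 8 * 15.5) / 12)

    def test_translation_equivariance(self):
        mask = np.zeros((8, 20, 20), bool)
        mask[2:5, 3:8, 4:9] = True
        c0, _ = fb.estimate_centroid(mask)
        c1, _ = fb.estimate_centroid(np.roll(mask, (1, 2, 3), axis=(0, 1, 2)))
        assert np.allclose(c1 - c0, [1, 2, 3])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fb.estimate_centroid(np.zeros((2, 2, 2), bool))


class TestWallFrame:
    @pytest.fixture(scope="class")
    def circle_frame(self):
        mask = annulus_mask((12, 101, 101), 25, 45)
        return mask, fb.build_wall_frame(mask, voxel_size_um=2.0)

    def test_penetration_points_inward(self, circle_frame):
        mask, frame = circle_frame
        # voxel at angle 0 on the outer rim: (y=50, x=50+44)
        R = frame.penetration[6, 50, 94]
        assert np.allclose(R, [-1.0, 0.0, 0.0], atol=0.02)

    def test_triad_orthonormal(self, circle_frame):
        mask, frame = circle_frame
        C, L, R = frame.circumferential, frame.longitudinal, frame.penetration
        ok = frame.valid
        for a, b in ((C, L), (C, R), (L, R)):
            assert np.abs(np.sum(a * b, axis=-1)[ok]).max() < 1e-6
        for a in (C, L, R):
            assert np.abs(np.linalg.norm(a, axis=-1)[ok] - 1).max() < 1e-6
        assert np.allclose(np.abs(L[ok][:, 2]), 1.0, atol=1e-3)

    def test_depth_increases_inward(self, circle_frame):
        mask, frame = circle_frame
        assert frame.depth_um[6, 50, 93] < frame.depth_um[6, 50, 80]
        assert frame.depth_um[mask].min() >= 0.0

    def test_ellipse_normals(self):
        nz, ny, nx = 8, 121, 161
        yy, xx = np.meshgrid(np.arange(ny) - 60.0, np.arange(nx) - 80.0, indexing="ij")
        a_out, b_out, a_in, b_in = 70.0, 50.0, 45.0, 25.0
        outer = (xx / a_out) ** 2 + (yy / b_out) ** 2 <= 1.0
        inner = (xx / a_in) ** 2 + (yy / b_in) ** 2 <= 1.0
        mask = np.broadcast_to((outer & ~inner)[None], (nz, ny, nx)).copy()
        frame = fb.build_wall_frame(mask, voxel_size_um=2.0)
        # analytic inward normal of the outer ellipse at the wall's outer skin
        shell = mask & np.broadcast_to(
            (((xx / (a_out - 3)) ** 2 + (yy / (b_out - 3)) ** 2 >= 1.0))[None],
            mask.shape) & frame.valid
        nx_an = -(xx / a_out**2)
        ny_an = -(yy / b_out**2)
        nrm = np.hypot(nx_an, ny_an)
        target = np.stack([nx_an / nrm, ny_an / nrm], -1)
        got = frame.penetration[shell][:, :2]
        tgt = np.broadcast_to(target[None], mask.shape + (2,))[shell]
        ang = np.degrees(np.arccos(np.clip(np.abs(np.sum(got * tgt, -1)), 0, 1)))
        assert np.percentile(ang, 95) < 3.0

    def test_open_boundary_warns_and_invalidates_slice(self):
        mask = annulus_mask((4, 41, 41), 10, 18)
        mask[2, :, :20] = False  # break the ring in slice 2
        with pytest.warns(UserWarning, match="not closed"):
            frame = fb.build_wall_frame(mask)
        assert not frame.valid[2].any()
        assert frame.valid[1].any()


class TestThetaPhi:
    @pytest.mark.parametrize("v,theta,phi", [
        ((1, 0, 0), 0.0, 0.0),
        ((np.sqrt(0.5), np.sqrt(0.5), 0), 45.0, 0.0),
        ((0, 1, 0), 90.0, 0.0),
    ])
    def test_examples(self, v, theta, phi):
        vv = np.array(v, float)[None, None, None]
        f = fb.OrientationField(vv, np.ones((1, 1, 1), bool), 2.0)
        tp = fb.compute_theta_phi(f)
        assert tp.theta_deg[0, 0, 0] == pytest.approx(theta, abs=1e-9)
        assert tp.phi_deg[0, 0, 0] == pytest.approx(phi, abs=1e-9)

    def test_vertical_vector_theta_undefined(self):
        vv = np.array([0.0, 0.0, 1.0])[None, None, None]
        f = fb.OrientationField(vv, np.ones((1, 1, 1), bool), 2.0)
        tp = fb.compute_theta_phi(f)
        assert tp.phi_deg[0, 0, 0] == pytest.approx(90.0)
        assert not tp.theta_valid[0, 0, 0]
        assert np.isnan(tp.theta_deg[0, 0, 0])


class TestHelixAngle:
    @pytest.fixture(scope="class")
    def simple_frame(self):
        shape = (1, 1, 2)
        C = np.zeros(shape + (3,)); C[..., 0] = 1.0
        L = np.zeros(shape + (3,)); L[..., 2] = 1.0
        R = np.zeros(shape + (3,)); R[..., 1] = 1.0
        return fb.WallFrame(np.zeros(3), C, L, R, np.zeros(shape),
                            np.ones(shape, bool), 2.0)

    def field(self, v):
        vv = np.broadcast_to(np.asarray(v, float), (1, 1, 2, 3)).copy()
        return fb.OrientationField(vv, np.ones((1, 1, 2), bool), 2.0)

    def test_circumferential_is_zero(self, simple_frame):
        ah = fb.compute_helix_angle(self.field((1, 0, 0)), simple_frame)
        assert ah.alpha_h_deg[0, 0, 0] == pytest.approx(0.0)

    def test_longitudinal_is_plus_ninety(self, simple_frame):
        ah = fb.compute_helix_angle(self.field((0, 0, 1)), simple_frame)
        assert ah.alpha_h_deg[0, 0, 0] == pytest.approx(90.0)
        ah_neg = fb.compute_helix_angle(self.field((0, 0, -1)), simple_frame)
        assert ah_neg.alpha_h_deg[0, 0, 0] == pytest.approx(90.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(angle=st.floats(-89.9, 89.9))
    def test_axial_sign_invariance(self, simple_frame, angle):
        a = np.deg2rad(angle)
        v = (np.cos(a), 0.0, np.sin(a))
        pos = fb.compute_helix_angle(self.field(v), simple_frame)
        neg = fb.compute_helix_angle(self.field(tuple(-c for c in v)), simple_frame)
        assert pos.alpha_h_deg[0, 0, 0] == pytest.approx(angle, abs=1e-4)
        assert neg.alpha_h_deg[0, 0, 0] == pytest.approx(angle, abs=1e-4)

    def test_radial_orientation_flagged(self, simple_frame):
        ah = fb.compute_helix_angle(self.field((0, 1, 0)), simple_frame)
        assert not ah.valid[0, 0, 0]

    def test_wrap_axial(self):
        assert _wrap_axial_deg(135.0) == pytest.approx(-45.0)
        assert _wrap_axial_deg(-90.0) == pytest.approx(90.0)
        assert _wrap_axial_deg(90.0) == pytest.approx(90.0)


class TestSectorProfile:
    @pytest.fixture(scope="class")
    def flat_setup(self, small_annulus, small_frame):
        """Synthetic orientation with constant helix angle 30 degrees."""
        spec, _, gt = small_annulus
        frame = small_frame
        a = np.deg2rad(30.0)
        v = (np.cos(a) * frame.circumferential
             + np.sin(a) * frame.longitudinal).astype(np.float32)
        f = fb.OrientationField(v, frame.valid.copy(), 2.0)
        ah = fb.compute_helix_angle(f, frame)
        return gt, frame, ah

    def test_constant_field_gives_flat_profiles(self, flat_setup):
        gt, frame, ah = flat_setup
        profs = fb.sector_profile(ah, frame, fb.SectorSpec(), gt.mask)
        assert len(profs) == 18
        for p in profs:
            assert np.allclose(p.mean_alpha_deg, 30.0, atol=0.5)

    def test_voxel_conservation(self, flat_setup):
        gt, frame, ah = flat_setup
        profs = fb.sector_profile(ah, frame, fb.SectorSpec(), gt.mask)
        total = sum(int(p.n_voxels.sum()) for p in profs)
        assert total == int((ah.valid & frame.valid & gt.mask).sum())

    def test_axial_mean_handles_wraparound(self):
        assert fb.axial_mean_deg([89.0, -89.0]) == pytest.approx(90.0, abs=1e-9)
        assert fb.axial_mean_deg([10.0, 20.0]) == pytest.approx(15.0, abs=1e-9)

    def test_bad_sector_spec(self):
        with pytest.raises(ValueError):
            fb.SectorSpec(wedge_width_deg=7.0)
        with pytest.raises(ValueError):
            fb.SectorSpec(wedges_combined=5)


def make_profile(y, bin_um=2.0):
    y = np.asarray(y, float)
    return fb.TransmuralProfile(0, (np.arange(y.size) + 0.5) * bin_um, y,
                                np.ones(y.size, int))


class TestRateOfChange:
    def test_linear_profile_constant_slope(self):
        prof = make_profile(np.arange(40) * 3.0)  # 1.5 deg/um at 2 um bins
        centers, slopes = fb.profile_rate_of_change(prof, 15)
        assert np.allclose(slopes, 1.5, atol=1e-9)
        # 15 samples at 2 um spacing span 30 um
        assert centers[0] - prof.depth_um[0] == pytest.approx(14.0)

    def test_flat_then_steep_transition_localized(self):
        y = np.concatenate([np.zeros(30), (np.arange(30) + 1) * 4.0])
        prof = make_profile(y)
        centers, slopes = fb.profile_rate_of_change(prof, 15)
        assert np.all(np.abs(slopes[:8]) < 1e-9)
        assert np.allclose(slopes[-8:], 2.0, atol=1e-9)
        rising = np.nonzero((slopes > 0.05) & (slopes < 1.95))[0]
        assert rising.size <= 15  # transition confined to one window

    def test_short_profile_errors(self):
        with pytest.raises(ValueError):
            fb.profile_rate_of_change(make_profile(np.zeros(10)), 15)


class TestPiecewiseFit:
    def test_exact_two_segment_input(self):
        y = np.concatenate([np.full(25, 5.0), 5.0 + (np.arange(25) + 1) * 2.0])
        fit = fb.piecewise_linear_fit(make_profile(y), 2)
        assert abs(fit["breakpoints_um"][0] - 49.0) <= 2.0
        assert fit["segment_lengths_um"][0] == pytest.approx(48.0, abs=2.0)
        assert fit["slopes_deg_per_um"][0] == pytest.approx(0.0, abs=1e-6)
        assert fit["slopes_deg_per_um"][1] == pytest.approx(1.0, abs=1e-6)

    def test_pure_line_flags_degenerate(self):
        fit = fb.piecewise_linear_fit(make_profile(np.arange(30) * 1.5), 2)
        assert fit["degenerate"]
        assert fit["slopes_deg_per_um"][0] == pytest.approx(
            fit["slopes_deg_per_um"][1], abs=1e-6)

    def test_noisy_breakpoint_within_three_bins(self):
        rng = np.random.default_rng(9)
        y = np.concatenate([np.full(25, 5.0), 5.0 + (np.arange(25) + 1) * 2.0])
        fit = fb.piecewise_linear_fit(make_profile(y + rng.normal(0, 2.0, 50)), 2)
        assert abs(fit["breakpoints_um"][0] - 49.0) <= 6.0  # 3 bins of 2 um

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            fb.piecewise_linear_fit(make_profile(np.zeros(3)), 2)
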