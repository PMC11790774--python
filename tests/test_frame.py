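"""Wall coordinates, depth, helix/sheetlet angles and transmural profiles."""

import numpy as np
import pytest

import cardiodti as cd
from cardiodti.frame import CardiacFrameField, ProfileError


def _annulus_mask(r_endo=2.0, r_epi=4.0, vox=0.15, n_slices=3):
    n = int(2 * (r_epi + 0.5) / vox)
    affine = np.diag([vox, vox, vox, 1.0])
    affine[0, 3] = affine[1, 3] = -(n - 1) / 2 * vox
    xs = affine[0, 3] + vox * np.arange(n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    rho = np.hypot(X, Y)
    sl = (rho >= r_endo) & (rho <= r_epi)
    mask = np.repeat(sl[:, :, None], n_slices, axis=2)
    return mask, affine, rho


class TestTransmuralDepth:
    def test_annulus_midwall_depth(self):
        """A voxel at r=3 mm in a 2-4 mm annulus sits at depth 0.5."""
        mask, affine, rho = _annulus_mask()
        depth, valid, wall = cd.depth_from_mask(mask, affine)
        mid = mask & (np.abs(rho[:, :, None] - 3.0) < 0.05)
        assert abs(np.nanmedian(depth[mid]) - 0.5) < 0.15 / 2.0  # half-voxel
        assert np.nanmin(depth[valid]) >= 0.0 and np.nanmax(depth[valid]) <= 1.0
        wall_mm = np.average(wall.wall_thickness_mm, weights=wall.n_voxels)
        assert wall_mm == pytest.approx(2.0, rel=0.08)

    def test_endo_adjacent_voxels_near_zero(self):
        mask, affine, rho = _annulus_mask()
        depth, _, _ = cd.depth_from_mask(mask, affine)
        inner = mask & (rho[:, :, None] < 2.0 + 0.16)
        assert np.nanmax(depth[inner]) < 0.15 / 2.0 * 2  # < voxel/wall

    def test_contour_version_matches_annulus(self):
        mask, affine, rho = _annulus_mask()
        th = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        contours = {
            sl: {
                "endo": np.column_stack([2.0 * np.cos(th), 2.0 * np.sin(th)]),
                "epi": np.column_stack([4.0 * np.cos(th), 4.0 * np.sin(th)]),
            }
            for sl in range(mask.shape[2])
        }
        depth, valid, wall, n_excl = cd.transmural_depth(mask, contours, affine)
        mid = valid & (np.abs(rho[:, :, None] - 3.0) < 0.05)
        assert abs(np.nanmedian(depth[mid]) - 0.5) < 0.15 / 2.0
        assert n_excl < 0.02 * mask.sum()

    def test_depth_monotone_along_radius(self, noiseless_phantom):
        ds = noiseless_phantom
        depth, valid, _ = cd.depth_from_mask(ds.mask, ds.affine)
        sl = ds.mask.shape[2] // 2  # mid-ventricular slice
        row = depth[:, ds.mask.shape[1] // 2, sl]
        ok = np.isfinite(row)
        idx = np.nonzero(ok)[0]
        # walk outward from the cavity on the +x side: depth must not decrease
        right = idx[idx > len(row) // 2]
        diffs = np.diff(row[right])
        assert (diffs >= -1e-9).all()


class TestLocalFrame:
    def test_canonical_cylinder_directions(self):
        mask, affine, rho = _annulus_mask()
        fr = cd.local_frame(mask, affine)
        # voxel on the +x axis: radial = +x, longitudinal = +z, circ = +y
        i = np.argmin(np.abs(affine[0, 3] + 0.15 * np.arange(mask.shape[0]) - 3.0))
        j = mask.shape[1] // 2
        assert fr.valid[i, j, 1]
        np.testing.assert_allclose(fr.r_hat[i, j, 1], [1, 0, 0], atol=0.05)
        np.testing.assert_allclose(fr.l_hat[i, j, 1], [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(fr.c_hat[i, j, 1], [0, 1, 0], atol=0.05)

    def test_triads_orthonormal(self, noiseless_phantom):
        ds = noiseless_phantom
        fr = cd.local_frame(ds.mask, ds.affine)
        v = fr.valid
        for a, b in [(fr.c_hat, fr.l_hat), (fr.c_hat, fr.r_hat), (fr.l_hat, fr.r_hat)]:
            assert np.abs(np.sum(a[v] * b[v], axis=1)).max() < 1e-8
        for a in (fr.c_hat, fr.l_hat, fr.r_hat):
            np.testing.assert_allclose(np.linalg.norm(a[v], axis=1), 1.0, atol=1e-8)

    def test_frame_matches_phantom_truth(self, noiseless_phantom):
        ds = noiseless_phantom
        fr = cd.local_frame(ds.mask, ds.affine)
        both = fr.valid & ds.frame_true.valid
        dots = np.clip(np.abs(np.sum(fr.r_hat[both] * ds.frame_true.r_hat[both], axis=1)), 0, 1)
        assert np.degrees(np.arccos(np.median(dots))) < 2.0


def _flat_frame(shape=(1, 1, 1)):
    """Frame with c=+x, l=+z, r=+y at every voxel."""
    c = np.zeros(shape + (3,))
    l = np.zeros(shape + (3,))
    r = np.zeros(shape + (3,))
    c[..., 0] = 1.0
    l[..., 2] = 1.0
    r[..., 1] = 1.0
    return CardiacFrameField(c_hat=c, l_hat=l, r_hat=r, valid=np.ones(shape, bool))


class TestHelixAngle:
    def test_circumferential_fiber_is_zero(self):
        fr = _flat_frame()
        ha, _ = cd.helix_angle(fr.c_hat.copy(), fr)
        assert ha[0, 0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_oblique_fiber_is_45_degrees(self):
        fr = _flat_frame()
        e1 = (fr.c_hat + fr.l_hat) / np.sqrt(2.0)
        ha, _ = cd.helix_angle(e1, fr)
        assert ha[0, 0, 0] == pytest.approx(45.0, abs=1e-10)

    def test_antipodal_invariance(self):
        fr = _flat_frame()
        e1 = (fr.c_hat - 0.7 * fr.l_hat)
        e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
        ha_pos, _ = cd.helix_angle(e1, fr)
        ha_neg, _ = cd.helix_angle(-e1, fr)
        assert ha_pos[0, 0, 0] == pytest.approx(ha_neg[0, 0, 0], abs=1e-12)

    def test_near_radial_fiber_excluded(self):
        fr = _flat_frame()
        e1 = 0.99 * fr.r_hat + np.sqrt(1 - 0.99**2) * fr.c_hat
        ha, n_excl = cd.helix_angle(e1, fr)
        assert np.isnan(ha[0, 0, 0]) and n_excl == 1

    def test_range_is_half_open(self, noiseless_phantom, noiseless_fit):
        fr = cd.local_frame(noiseless_phantom.mask, noiseless_phantom.affine)
        ha, _ = cd.helix_angle(noiseless_fit.eigensystem.e1, fr)
        vals = ha[np.isfinite(ha)]
        assert vals.min() > -90.0 and vals.max() <= 90.0


class TestSheetletAngle:
    @pytest.mark.parametrize("weight_n,expected", [(0.0, 0.0), (1.0, 90.0), (None, 45.0)])
    def test_canonical_sheets(self, weight_n, expected):
        fr = _flat_frame()
        e1 = fr.c_hat.copy()  # fiber along c: w = r x e1 = y x x = -z... use vectors directly
        w = np.cross(fr.r_hat, e1)
        w /= np.linalg.norm(w, axis=-1, keepdims=True)
        n = np.cross(e1, w)
        n /= np.linalg.norm(n, axis=-1, keepdims=True)
        if weight_n is None:
            e2 = (w + n) / np.sqrt(2.0)
        else:
            e2 = np.sqrt(1 - weight_n**2) * w + weight_n * n
        e2a, _ = cd.sheetlet_angle(e1, e2, fr)
        assert e2a[0, 0, 0] == pytest.approx(expected, abs=1e-10)

    def test_phantom_e2a_recovery(self, noiseless_phantom, noiseless_fit):
        ds = noiseless_phantom
        fr = cd.local_frame(ds.mask, ds.affine)
        eigs = noiseless_fit.eigensystem
        e2a, _ = cd.sheetlet_angle(eigs.e1, eigs.e2, fr)
        err = np.abs(e2a - ds.e2a_true)
        assert np.nanmedian(err[np.isfinite(err)]) < 5.0


class TestTransmuralProfile:
    def test_exact_ramp_slopes(self):
        rng = np.random.default_rng(0)
        depth = rng.uniform(0, 1, 20000)
        ha = 60.0 - 120.0 * depth
        prof = cd.transmural_profile(ha, depth, wall_thickness_mm=1.0)
        assert prof.slope_mm == pytest.approx(-120.0, rel=1e-6)
        assert prof.slope_pct == pytest.approx(-1.2, rel=1e-6)

    def test_constant_field_zero_slope(self):
        rng = np.random.default_rng(1)
        depth = rng.uniform(0, 1, 5000)
        prof = cd.transmural_profile(np.full_like(depth, 30.0), depth, 1.0)
        assert prof.slope_mm == pytest.approx(0.0, abs=1e-9)
        assert prof.slope_pct == pytest.approx(0.0, abs=1e-9)

    def test_wall_thickness_normalization(self):
        """Halving the wall doubles deg/mm but leaves deg/% unchanged."""
        rng = np.random.default_rng(2)
        depth = rng.uniform(0, 1, 20000)
        ha = 60.0 - 120.0 * depth
        thick = cd.transmural_profile(ha, depth, wall_thickness_mm=1.0)
        thin = cd.transmural_profile(ha, depth, wall_thickness_mm=0.5)
        assert thin.slope_mm == pytest.approx(2 * thick.slope_mm, rel=1e-9)
        assert thin.slope_pct == pytest.approx(thick.slope_pct, rel=1e-9)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ProfileError):
            cd.transmural_profile(np.array([1.0, 2.0]), np.array([0.5, 0.52]), 1.0)


class TestHAProportions:
    def test_all_neutral(self):
        fr = cd.ha_proportions(np.zeros((10, 10)))
        assert fr["neutral"] == 1.0

    def test_uniform_distribution_thirds(self):
        rng = np.random.default_rng(3)
        n = 30000
        ha = rng.uniform(-90, 90, n)
        fr = cd.ha_proportions(ha, neutral_band=30.0)
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(fr["neutral"] - 1 / 3) < 3 * se

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        ha = rng.uniform(-90, 90, 999)
        fr = cd.ha_proportions(ha)
        assert fr["negative"] + fr["neutral"] + fr["positive"] == pytest.approx(1.0, abs=1e-12)
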