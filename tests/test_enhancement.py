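import numpy as np
import pytest
from scipy import ndimage

from bonesep import enhancement as enh
from oracles import brute_closing_minus_image, stick_vote_sum


class TestBlackTopHat:
    def test_constant_volume_zero_response(self):
        assert not enh.black_top_hat(np.full((8, 8, 8), 4000.0), 2).data.any()

    def test_embedded_dark_plane(self):
        vol = np.full((13, 13, 13), 8000.0)
        vol[:, 6, :] = 0.0
        r = enh.black_top_hat(vol, 2).data
        assert r[6, 6, 6] == pytest.approx(8000.0)
        assert r[6, 2, 6] == pytest.approx(0.0)

    def test_nonnegative_on_random(self, rng):
        vol = rng.uniform(0, 10000, size=(10, 10, 10))
        assert enh.black_top_hat(vol, 1).data.min() >= 0

    def test_agrees_with_brute_force(self, rng):
        for _ in range(5):
            vol = rng.uniform(0, 10000, size=(9, 9, 9))
            got = enh.black_top_hat(vol, 2).data
            want = brute_closing_minus_image(vol, 2)
            np.testing.assert_allclose(got, want)

    def test_radius_validated(self):
        with pytest.raises(ValueError):
            enh.black_top_hat(np.zeros((4, 4, 4)), 0)


def _plate_volume(thickness=2, size=28, value=8000.0):
    vol = np.full((size, size, size), value)
    mid = size // 2
    vol[:, mid : mid + thickness, :] = 0.0
    return vol


def _ball_volume(radius=4, size=28, value=8000.0):
    vol = np.full((size, size, size), value)
    zz, yy, xx = np.mgrid[:size, :size, :size]
    c = size // 2
    vol[(zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2] = 0.0
    return vol


class TestSheetness:
    def test_constant_volume_zero(self):
        assert not enh.sheetness(np.full((10, 10, 10), 5000.0)).data.any()

    def test_plate_beats_ball(self):
        # a dark plate should out-score a dark ball at matched scales
        sp = enh.sheetness(_plate_volume()).data
        sb = enh.sheetness(_ball_volume()).data
        c = 14
        assert sp[c, c, c] > sb[c, c, c] * 3

    def test_plate_hessian_signature(self):
        # independent check of the eigenvalue structure the score relies on:
        # at the dark mid-plane, the blurred Hessian has one dominant
        # positive eigenvalue (across the plate) and two near-zero ones
        vol = ndimage.gaussian_filter(_plate_volume(), 1.5)
        c = 14
        d2_across = vol[c, c + 1, c] - 2 * vol[c, c, c] + vol[c, c - 1, c]
        d2_in_plane = vol[c, c, c + 1] - 2 * vol[c, c, c] + vol[c, c, c - 1]
        assert d2_across > 100
        assert abs(d2_in_plane) < 0.05 * d2_across

    def test_dark_selective_polarity(self):
        inverted = 8000.0 - _plate_volume()  # bright sheet in dark surround
        resp = enh.sheetness(inverted).data
        c = 14
        assert resp[c, c, c] < 1e-3
        assert resp[c, c + 1, c] < 1e-3

    def test_shift_invariance(self, rng):
        vol = rng.uniform(0, 8000, (12, 12, 12))
        a = enh.sheetness(vol).data
        b = enh.sheetness(vol + 1234.5).data
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_scales_validated(self):
        with pytest.raises(ValueError):
            enh.sheetness(np.zeros((4, 4, 4)), scales=[])


class TestTensorVoting:
    def test_empty_input_empty_output(self):
        out = enh.tensor_voting(np.zeros((8, 8, 8)), sigma_v=2.0, threshold=0.1)
        assert not out.data.any()

    def test_bridges_plane_hole(self):
        size = 24
        sal = np.zeros((size, size, size))
        sal[12] = 1.0
        yy, xx = np.mgrid[:size, :size]
        hole = (yy - 12) ** 2 + (xx - 12) ** 2 <= 4  # diameter-4 hole
        sal[12][hole] = 0.0
        out = enh.tensor_voting(sal, sigma_v=6.0, threshold=0.5).data
        on_plane = np.median(out[12][~hole & (out[12] > 0)])
        assert out[12, 12, 12] > 0.5 * on_plane

    def test_matches_direct_summation_at_hole_center(self):
        # oracle: sum stick votes over tokens explicitly at one voxel
        size = 20
        sal = np.zeros((size, size, size))
        sal[10] = 1.0
        yy, xx = np.mgrid[:size, :size]
        hole = (yy - 10) ** 2 + (xx - 10) ** 2 <= 4
        sal[10][hole] = 0.0
        sigma_v = 5.0
        out = enh.tensor_voting(sal, sigma_v=sigma_v, threshold=0.5).data
        tokens = np.argwhere(sal > 0.5)
        normals = np.tile([1.0, 0.0, 0.0], (len(tokens), 1))  # plane normal = z
        acc = stick_vote_sum(tokens, normals, np.ones(len(tokens)), (10, 10, 10), sigma_v)
        ev = np.linalg.eigvalsh(acc)
        expected = ev[2] - ev[1]
        assert out[10, 10, 10] == pytest.approx(expected, rel=0.05)

    def test_equivariant_under_axis_rotations(self, rng):
        sal = rng.uniform(0, 1, size=(14, 14, 14))
        sal[sal < 0.8] = 0.0
        base = enh.tensor_voting(sal, sigma_v=2.0, threshold=0.5).data
        for k in (1, 2, 3):
            rot = np.rot90(sal, k=k, axes=(1, 2))
            out = enh.tensor_voting(rot, sigma_v=2.0, threshold=0.5).data
            np.testing.assert_allclose(
                out, np.rot90(base, k=k, axes=(1, 2)), atol=1e-6 * max(base.max(), 1)
            )

    def test_saliency_nonnegative_and_local(self, rng):
        sal = np.zeros((20, 20, 20))
        sal[3, 3, 3] = 5.0
        sigma_v = 1.5
        out = enh.tensor_voting(sal, sigma_v=sigma_v, threshold=1.0).data
        assert out.min() >= 0
        # vanishes outside the kernel's effective support
        zz, yy, xx = np.mgrid[:20, :20, :20]
        far = np.sqrt((zz - 3) ** 2 + (yy - 3) ** 2 + (xx - 3) ** 2) > 4 * sigma_v
        assert not out[far].any()

    def test_sigma_validated(self):
        with pytest.raises(ValueError):
            enh.tensor_voting(np.zeros((4, 4, 4)), sigma_v=0.0)


class TestDilateMask:
    def test_single_voxel_becomes_cube(self):
        m = np.zeros((9, 9, 9), dtype=bool)
        m[4, 4, 4] = True
        out = enh.dilate_mask(m, 2)
        assert out.sum() == 125
        assert out[2:7, 2:7, 2:7].all()

    def test_empty_stays_empty(self):
        assert not enh.dilate_mask(np.zeros((5, 5, 5), bool), 2).any()

    def test_extensive(self, rng):
        m = rng.random((8, 8, 8)) > 0.7
        out = enh.dilate_mask(m, 1)
        assert (m & ~out).sum() == 0

    def test_ball_variant_smaller_than_cube(self):
        m = np.zeros((9, 9, 9), dtype=bool)
        m[4, 4, 4] = True
        assert enh.dilate_mask(m, 2, "ball").sum() < enh.dilate_mask(m, 2, "cube").sum()


class TestCombineResponses:
    def _resp(self, data, tag="bth"):
        return enh.ResponseVolume(np.asarray(data, float), tag)

    def test_all_zero_sources_empty_mask(self):
        z = self._resp(np.zeros((6, 6, 6)))
        out = enh.combine_responses(z, None, None, thresholds={"bth": 0.5})
        assert not out.any()

    def test_single_dl_voxel_dilates_to_cube(self):
        prob = np.zeros((9, 9, 9))
        prob[4, 4, 4] = 0.9
        out = enh.combine_responses(dl_prob=prob)
        assert out.sum() == 125

    def test_union_monotone(self, rng):
        a = self._resp(rng.uniform(0, 1, (7, 7, 7)))
        b = self._resp(rng.uniform(0, 1, (7, 7, 7)), "sheetness")
        just_a = enh.combine_responses(a, None, None, thresholds={"bth": 0.5})
        both = enh.combine_responses(a, b, None, thresholds={"bth": 0.5, "sef": 0.5})
        assert not (just_a & ~both).any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            enh.combine_responses(
                self._resp(np.zeros((4, 4, 4))),
                self._resp(np.zeros((5, 5, 5)), "sheetness"),
                None,
                thresholds={"bth": 0.5, "sef": 0.5},
            )

    def test_joint_mask_quality_on_default_phantom(self, default_phantom):
        # regression: covers >= 95% of true gap voxels, < 5% of the bone
        # interior deeper than the half-kernel-2 cube dilation reach (2*sqrt(3))
        spec = default_phantom.spec
        vol = default_phantom.volume.data
        bth = enh.black_top_hat(vol, 3)
        sef = enh.sheetness(vol)
        mef = enh.tensor_voting(sef, sigma_v=3.0)
        joint = enh.combine_responses(bth, sef, mef)

        labels = default_phantom.truth.labels
        coverage = np.zeros(labels.shape, dtype=np.int16)
        for i in default_phantom.truth.ids():
            coverage += ndimage.binary_dilation(
                labels == i, iterations=spec.gap_vox
            ).astype(np.int16)
        gap_true = (coverage >= 2) & (labels == 0)
        depth = ndimage.distance_transform_edt(labels > 0)
        interior = depth > 2 * np.sqrt(3.0)
        assert (joint & gap_true).sum() / gap_true.sum() >= 0.95
        assert (joint & interior).sum() / max(interior.sum(), 1) < 0.05
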