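"""Feature catalog: discretization, GLCM/GLRLM/LBP/first-order/shape, and
brute-force oracle equivalence on small integer phantoms."""

import numpy as np
import pytest

from deltarad.features import (
    DIRECTIONS_3D,
    DiscretizedRoi,
    catalog_feature_names,
    discretize,
    extract_all,
    first_order_features,
    glcm_features,
    glcm_matrices,
    glrlm_features,
    glrlm_matrix,
    lbp_features,
    shape_features,
)
from deltarad.images import DegenerateRoiError, ImageVolume, RoiMask
from deltarad.preprocessing import wavelet_bank

from conftest import make_phantom, make_sphere_mask


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_glcm(levels, mask, n_levels, offset):
    """Enumerate every voxel pair at the offset; symmetric, normalised."""
    mat = np.zeros((n_levels, n_levels))
    shape = levels.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        nb = tuple(i + d for i, d in zip(idx, offset))
        if all(0 <= c < s for c, s in zip(nb, shape)) and mask[nb]:
            mat[levels[idx] - 1, levels[nb] - 1] += 1
    mat = mat + mat.T
    return mat / mat.sum() if mat.sum() else mat


def brute_glrlm(levels, mask, n_levels, offset):
    """Walk every maximal line in the direction, collecting run lengths."""
    shape = levels.shape
    runs = []
    for idx in np.ndindex(shape):
        prev = tuple(i - d for i, d in zip(idx, offset))
        prev_in = all(0 <= c < s for c, s in zip(prev, shape))
        if prev_in:
            continue  # not a line start
        # walk the line
        line = []
        cur = idx
        while all(0 <= c < s for c, s in zip(cur, shape)):
            line.append(cur)
            cur = tuple(i + d for i, d in zip(cur, offset))
        run_level, run_len = None, 0
        for vox in line:
            if mask[vox] and levels[vox] == run_level:
                run_len += 1
            else:
                if run_level is not None and run_len:
                    runs.append((run_level, run_len))
                run_level = levels[vox] if mask[vox] else None
                run_len = 1 if mask[vox] else 0
        if run_level is not None and run_len:
            runs.append((run_level, run_len))
    max_len = max((l for _, l in runs), default=1)
    mat = np.zeros((n_levels, max_len))
    for lev, ln in runs:
        mat[lev - 1, ln - 1] += 1
    return mat


def brute_lbp_code(image, i, j):
    """Rotation-invariant uniform LBP code of one interior pixel (P=8, R=1).

    Circle samples at angles 2*pi*k/8 are read by bilinear interpolation
    (diagonal samples fall between pixels), thresholded at the centre value.
    """
    center = image[i, j]

    def sample(di, dj):
        r0, c0 = i + di, j + dj
        rb, cb = int(np.floor(r0)), int(np.floor(c0))
        fr, fc = r0 - rb, c0 - cb
        val = 0.0
        for dr in (0, 1):
            for dc in (0, 1):
                w = (fr if dr else 1 - fr) * (fc if dc else 1 - fc)
                if w:
                    val += w * image[rb + dr, cb + dc]
        return val

    bits = []
    for k in range(8):
        theta = 2 * np.pi * k / 8
        di, dj = -np.sin(theta), np.cos(theta)
        bits.append(1 if sample(di, dj) - center >= 0 else 0)
    transitions = sum(bits[k] != bits[(k + 1) % 8] for k in range(8))
    if transitions <= 2:
        return sum(bits)
    return 9


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

class TestDiscretize:
    def test_bijective_on_integer_ramp(self):
        vals = np.arange(32, dtype=float).reshape(2, 4, 4)
        d = discretize(ImageVolume(vals), RoiMask(np.ones((2, 4, 4), bool)), 32)
        np.testing.assert_array_equal(np.sort(d.gray_levels.ravel()), np.arange(1, 33))

    def test_constant_roi_single_level(self):
        d = discretize(ImageVolume(np.full((3, 3, 3), 5.0)), RoiMask(np.ones((3, 3, 3), bool)))
        assert d.single_level
        assert set(d.gray_levels[d.mask]) == {1}

    def test_bin_counts_match_histogram_oracle(self, rng):
        vals = rng.uniform(0, 1, size=(5, 5, 5))
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        d = discretize(ImageVolume(vals), RoiMask(mask), 8)
        counts = np.bincount(d.gray_levels[mask], minlength=9)[1:]
        roi = vals[mask]
        edges = np.linspace(roi.min(), roi.max(), 9)
        expect, _ = np.histogram(roi, bins=edges)
        np.testing.assert_array_equal(counts, expect)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

class TestGlcm:
    def test_constant_roi_contrast_zero_energy_one(self):
        d = discretize(ImageVolume(np.full((3, 3, 3), 1.0)), RoiMask(np.ones((3, 3, 3), bool)))
        f = glcm_features(d)
        assert f["Contrast"] == 0.0
        assert f["Joint_Energy"] == 1.0

    def test_two_by_two_matches_pair_count_oracle(self):
        vals = np.array([[1.0, 2.0], [1.0, 2.0]]).reshape(2, 2, 1)
        mask = RoiMask(np.ones((2, 2, 1), bool))
        d = discretize(ImageVolume(vals), mask, 2)
        mats = glcm_matrices(d)
        oracle = [
            brute_glcm(d.gray_levels, d.mask, 2, off)
            for off in DIRECTIONS_3D
            if brute_glcm(d.gray_levels, d.mask, 2, off).sum() > 0
        ]
        assert len(mats) == len(oracle)
        for got, exp in zip(mats, oracle):
            np.testing.assert_allclose(got, exp, atol=1e-12)

    def test_matrices_symmetric(self, phantom_4):
        vol, mask = phantom_4
        d = discretize(vol, mask, 4)
        for mat in glcm_matrices(d):
            np.testing.assert_allclose(mat, mat.T, atol=0)

    def test_rotation_invariance_of_aggregate(self, phantom_4):
        vol, mask = phantom_4
        f0 = glcm_features(discretize(vol, mask, 4))
        rot = ImageVolume(np.rot90(vol.intensities, axes=(0, 1)).copy())
        f1 = glcm_features(discretize(rot, RoiMask(np.ones(rot.shape, bool)), 4))
        for k in f0:
            assert f0[k] == pytest.approx(f1[k], abs=1e-9), k


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

class TestGlrlm:
    def test_single_run_long_run_emphasis(self):
        # one 1x1xL line of identical levels along z
        L = 6
        vals = np.ones((1, 1, L))
        mask = RoiMask(np.ones((1, 1, L), bool))
        d = discretize(ImageVolume(vals), mask)
        mat = glrlm_matrix(d, (0, 0, 1))
        assert mat.shape[1] == L and mat[0, L - 1] == 1
        from deltarad.features import _glrlm_features_single

        f = _glrlm_features_single(mat, L)
        assert f["Long_Run_Emphasis"] == pytest.approx(L**2)

    def test_alternating_levels_short_runs(self):
        vals = np.array([1.0, 2.0] * 4).reshape(1, 1, 8)
        d = discretize(ImageVolume(vals), RoiMask(np.ones((1, 1, 8), bool)), 2)
        mat = glrlm_matrix(d, (0, 0, 1))
        from deltarad.features import _glrlm_features_single

        f = _glrlm_features_single(mat, 8)
        assert f["Short_Run_Emphasis"] == pytest.approx(1.0)

    def test_random_phantom_matches_brute_oracle(self):
        vol, mask = make_phantom((4, 4, 4), seed=9, n_levels=3)
        d = discretize(vol, mask, 3)
        for off in DIRECTIONS_3D:
            got = glrlm_matrix(d, off)
            exp = brute_glrlm(d.gray_levels, d.mask, 3, off)
            width = max(got.shape[1], exp.shape[1])
            g = np.zeros((3, width)); g[:, : got.shape[1]] = got
            e = np.zeros((3, width)); e[:, : exp.shape[1]] = exp
            np.testing.assert_allclose(g, e, atol=0, err_msg=str(off))

    def test_masked_voxels_break_runs(self):
        vals = np.ones((1, 1, 5))
        mask = np.ones((1, 1, 5), bool)
        mask[0, 0, 2] = False
        d = discretize(ImageVolume(vals), RoiMask(np.ones((1, 1, 5), bool)))
        d.mask = mask
        d.gray_levels = d.gray_levels * mask
        mat = glrlm_matrix(d, (0, 0, 1))
        assert mat[0, 1] == 2  # two runs of length 2


# ---------------------------------------------------------------------------
# LBP
# ---------------------------------------------------------------------------

class TestLbp:
    def test_constant_image_all_zero_pattern(self):
        vol = ImageVolume(np.full((6, 6, 2), 4.0))
        mask = RoiMask(np.ones((6, 6, 2), bool))
        f = lbp_features(vol, mask)
        # all neighbours >= centre: full 'all ones' uniform pattern, code 8
        assert f["LBP_Bin_8"] == pytest.approx(1.0)
        assert f["LBP_Entropy"] == pytest.approx(0.0)

    def test_histogram_sums_to_one(self, rng):
        vol = ImageVolume(rng.normal(size=(8, 8, 3)))
        mask = RoiMask(np.ones((8, 8, 3), bool))
        f = lbp_features(vol, mask)
        assert sum(f[f"LBP_Bin_{k}"] for k in range(10)) == pytest.approx(1.0)

    def test_checkerboard_codes_match_neighborhood_oracle(self):
        board = np.indices((8, 8)).sum(axis=0) % 2 * 1.0
        vol = ImageVolume(board[:, :, None])
        mask = np.zeros((8, 8, 1), bool)
        mask[1:7, 1:7, 0] = True  # interior only: oracle needs full neighbourhoods
        f = lbp_features(vol, RoiMask(mask))
        codes = [brute_lbp_code(board, i, j) for i in range(1, 7) for j in range(1, 7)]
        expect = np.bincount(codes, minlength=10) / len(codes)
        got = np.array([f[f"LBP_Bin_{k}"] for k in range(10)])
        np.testing.assert_allclose(got, expect, atol=1e-12)


# ---------------------------------------------------------------------------
# first order + shape
# ---------------------------------------------------------------------------

class TestFirstOrderShape:
    def test_four_values_arithmetic(self):
        vol = ImageVolume(np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1))
        f = first_order_features(vol, RoiMask(np.ones((4, 1, 1), bool)))
        assert f["Mean"] == 2.5 and f["Range"] == 3.0 and f["Median"] == 2.5

    def test_single_voxel_volume_and_variance(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        vol = ImageVolume(np.ones((5, 5, 5)))
        f = first_order_features(vol, RoiMask(mask))
        assert f["Variance"] == 0.0
        s = shape_features(RoiMask(mask))
        assert s["Shape_Volume"] == pytest.approx(1.0)

    def test_moments_match_numpy_oracle(self, rng):
        vals = rng.normal(size=(4, 4, 4))
        vol = ImageVolume(vals)
        f = first_order_features(vol, RoiMask(np.ones((4, 4, 4), bool)))
        from scipy import stats

        flat = vals.ravel()
        assert f["Skewness"] == pytest.approx(stats.skew(flat), abs=1e-9)
        assert f["Kurtosis"] == pytest.approx(stats.kurtosis(flat, fisher=False), abs=1e-9)
        assert f["Energy"] == pytest.approx(np.sum(flat**2))

    def test_sphere_sphericity_near_one(self):
        mask = make_sphere_mask((64, 64, 64), radius=25)
        f = shape_features(mask)
        assert f["Shape_Sphericity"] == pytest.approx(1.0, abs=0.02)

    def test_elongation_of_anisotropic_mask(self):
        mask = np.zeros((20, 8, 8), bool)
        mask[2:18, 3:5, 3:5] = True
        f = shape_features(RoiMask(mask))
        assert f["Shape_Elongation"] < 0.5
        assert f["Shape_Flatness"] <= f["Shape_Elongation"] + 1e-12


# ---------------------------------------------------------------------------
# full catalog
# ---------------------------------------------------------------------------

class TestExtractAll:
    def test_exactly_593_named_features(self, rng):
        vol = ImageVolume(rng.normal(size=(12, 12, 12)))
        mask = make_sphere_mask((12, 12, 12), radius=4)
        feats = extract_all(wavelet_bank(vol), mask)
        assert len(feats) == 593
        assert list(feats) == catalog_feature_names()

    def test_catalog_contains_published_signature_names(self):
        names = catalog_feature_names()
        for key in ("LHL_Run_Length_Nonuniformity", "LHH_Long_Run_Emphasis", "HLL_Variance"):
            assert key in names

    def test_deterministic(self, rng):
        vol = ImageVolume(rng.normal(size=(10, 10, 10)))
        mask = make_sphere_mask((10, 10, 10), radius=3)
        bank = wavelet_bank(vol)
        f1 = extract_all(bank, mask)
        f2 = extract_all(bank, mask)
        assert f1 == f2

    def test_intensity_rescale_invariance_of_texture(self, rng):
        """Positive affine rescaling leaves discretized levels, hence GLCM/GLRLM,
        unchanged (bin edges rescale with the data)."""
        vol, mask = make_phantom((4, 4, 4), seed=5)
        d0 = discretize(vol, mask, 8)
        d1 = discretize(ImageVolume(3.0 * vol.intensities + 11.0), mask, 8)
        np.testing.assert_array_equal(d0.gray_levels, d1.gray_levels)
        f0, f1 = glcm_features(d0), glcm_features(d1)
        for k in f0:
            assert f0[k] == pytest.approx(f1[k], abs=1e-12)

    def test_empty_mask_rejected(self, rng):
        vol = ImageVolume(rng.normal(size=(4, 4, 4)))
        with pytest.raises(DegenerateRoiError):
            extract_all(wavelet_bank(vol), RoiMask(np.zeros((4, 4, 4), bool)))
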