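import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy import stats

from deltarad.features import (
    ALL_FEATURES,
    FAMILIES,
    N_FEATURES,
    extract_all,
    first_order_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    roi_size,
)
from deltarad.features import matrices as tm
from deltarad.features.families import COARSENESS_CAP, _rl_zone_features
from deltarad.features.registry import GLRLM_FEATURES
from deltarad.types import QuantizedROI

from conftest import random_quantized_roi
from oracles import all_offsets, naive_glcm, naive_glrlm, naive_glszm, naive_ngtdm


def _roi_2d(levels, mask=None):
    levels = np.asarray(levels)
    if mask is None:
        mask = levels > 0
    return levels, np.asarray(mask, dtype=bool)


class TestRegistry:
    def test_55_features_partitioned(self):
        assert N_FEATURES == 55
        counts = {fam: len(names) for fam, names in FAMILIES.items()}
        assert counts == {
            "size": 1,
            "first_order": 8,
            "glcm": 15,
            "glrlm": 13,
            "glszm": 13,
            "ngtdm": 5,
        }

    def test_signature_names_present(self):
        for name in (
            "Int_Energy",
            "GLCM_SumAverage",
            "GLCM_SumVariance",
            "GLCM_Autocorrelation",
            "GLRLM_SRLGLE",
            "GLRLM_LRLGLE",
            "GLRLM_LRHGLE",
            "GLSZM_LZLGLE",
            "GLSZM_LZHGLE",
            "NGTDM_Coarseness",
            "Volume",
        ):
            assert name in ALL_FEATURES


class TestRoiSize:
    def test_10_voxels_1mm(self):
        mask = np.zeros((3, 3, 3), bool)
        mask.ravel()[:10] = True
        assert roi_size(mask, (1, 1, 1)) == 10.0

    def test_2d_area(self):
        mask = np.ones((5, 5), bool)
        assert roi_size(mask, (1, 1)) == 25.0

    def test_sphere_volume(self):
        r = 5.0
        zz, yy, xx = np.mgrid[-7:8, -7:8, -7:8]
        mask = zz**2 + yy**2 + xx**2 <= r**2
        vol = roi_size(mask, (1, 1, 1))
        assert abs(vol - 523.6) / 523.6 < 0.15

    def test_empty_error(self):
        with pytest.raises(ValueError, match="empty"):
            roi_size(np.zeros((2, 2), bool), (1, 1))


class TestFirstOrder:
    def test_constant_conventions(self):
        vals = first_order_features(np.full(9, 3.0), np.full(9, 42, dtype=int), 64)
        assert vals["Int_Mean"] == 3.0
        assert vals["Int_StdDev"] == 0.0
        assert vals["Int_Energy"] == 9.0
        assert vals["Int_Skewness"] == 0.0
        assert vals["Int_Kurtosis"] == 0.0
        assert vals["Int_Uniformity"] == 1.0
        assert vals["Int_Entropy"] == 0.0

    def test_hand_arithmetic(self):
        vals = first_order_features(np.array([1.0, 3.0]), np.array([1, 2]), 64)
        assert vals["Int_Mean"] == 2.0
        assert vals["Int_StdDev"] == 1.0  # population SD
        assert vals["Int_Energy"] == 5.0
        assert vals["Int_Median"] == 2.0

    def test_returns_exactly_8(self):
        vals = first_order_features(np.array([1.0, 2.0, 3.0]), np.array([1, 2, 3]), 64)
        assert len(vals) == 8


class TestGLCM:
    def test_constant_roi(self):
        levels, mask = _roi_2d(np.full((3, 3), 5))
        vals = glcm_features(levels, mask, 8)
        assert vals["GLCM_Energy"] == pytest.approx(1.0)
        assert vals["GLCM_Contrast"] == 0.0
        assert vals["GLCM_MaximumProbability"] == pytest.approx(1.0)
        assert len(vals) == 15

    def test_alternating_strip_single_direction(self):
        # 1x4 strip [1,2,1,2]: only the (0,1) direction has pairs
        levels, mask = _roi_2d(np.array([[1, 2, 1, 2]]))
        mats = tm.glcm_matrices(levels, mask, 2)
        assert len(mats) == 1
        P = mats[0]
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == 0.0 and P[1, 1] == 0.0
        from deltarad.features.families import _glcm_single

        vals = _glcm_single(P)
        assert vals["GLCM_Energy"] == pytest.approx(0.5)
        assert vals["GLCM_SumAverage"] == pytest.approx(3.0)

    def test_no_valid_pairs_error(self):
        levels = np.zeros((3, 3, 3), dtype=int)
        mask = np.zeros((3, 3, 3), bool)
        levels[0, 0, 0] = 1
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="GLCM"):
            glcm_features(levels, mask, 4)

    def test_returns_exactly_15(self, rng):
        levels, mask, L = random_quantized_roi(rng)
        assert len(glcm_features(levels, mask, L)) == 15


class TestGLRLM:
    def test_strip_single_direction_sre(self):
        levels, mask = _roi_2d(np.array([[1, 1, 2]]))
        mats = tm.glrlm_matrices(levels, mask, 2)
        # direction (0,1) is the only one with runs longer than 1
        by_dir = dict(zip(tm.unique_directions(2), mats))
        R = by_dir[(0, 1)]
        vals = _rl_zone_features(R, 3, "GLRLM", GLRLM_FEATURES)
        assert vals["GLRLM_SRE"] == pytest.approx((1.0 / 1 + 1.0 / 4) / 2)

    def test_lre_grows_with_row_length(self):
        prev = 0.0
        for L in (4, 8, 16):
            levels, mask = _roi_2d(np.full((1, L), 3))
            mats = dict(zip(tm.unique_directions(2), tm.glrlm_matrices(levels, mask, 4)))
            vals = _rl_zone_features(mats[(0, 1)], L, "GLRLM", GLRLM_FEATURES)
            assert vals["GLRLM_LRE"] == pytest.approx(L**2)
            assert vals["GLRLM_LRE"] > prev
            prev = vals["GLRLM_LRE"]

    def test_returns_exactly_13(self, rng):
        levels, mask, L = random_quantized_roi(rng)
        assert len(glrlm_features(levels, mask, L)) == 13


class TestGLSZM:
    def test_constant_roi_single_zone(self):
        levels, mask = _roi_2d(np.full((2, 3), 4))
        n = 6
        vals = glszm_features(levels, mask, 8)
        assert vals["GLSZM_SAE"] == pytest.approx(1.0 / n**2)
        assert vals["GLSZM_LAE"] == pytest.approx(float(n**2))

    def test_checkerboard_two_zones(self):
        yy, xx = np.mgrid[0:4, 0:4]
        levels = 1 + (yy + xx) % 2
        mask = np.ones_like(levels, bool)
        Z = tm.glszm_matrix(levels, mask, 2)
        # 8-connectivity joins diagonal same-level cells -> one zone per level
        assert Z.sum() == 2
        assert Z[0, 7] == 1 and Z[1, 7] == 1  # two zones of 8 voxels each

    def test_returns_exactly_13(self, rng):
        levels, mask, L = random_quantized_roi(rng)
        assert len(glszm_features(levels, mask, L)) == 13


class TestNGTDM:
    def test_constant_roi_cap(self):
        levels, mask = _roi_2d(np.full((3, 3), 2))
        vals = ngtdm_features(levels, mask, 4)
        assert vals["NGTDM_Coarseness"] == COARSENESS_CAP
        assert vals["NGTDM_Contrast"] == 0.0

    def test_deviant_center_hand_oracle(self):
        levels = np.array([[1, 1, 1], [1, 3, 1], [1, 1, 1]])
        mask = np.ones_like(levels, bool)
        n_i, p_i, s_i = tm.ngtdm_table(levels, mask, 4)
        on, op, os_ = naive_ngtdm(levels, mask, 4)
        np.testing.assert_allclose(n_i, on)
        np.testing.assert_allclose(s_i, os_)
        # center: |3 - 1| = 2 ; each edge/corner neighbor sees the 3 once
        assert s_i[2] == pytest.approx(2.0)

    def test_isolated_voxel_error(self):
        levels = np.array([[1]])
        with pytest.raises(ValueError, match="neighbor"):
            ngtdm_features(levels, np.ones((1, 1), bool), 2)

    def test_returns_exactly_5(self, rng):
        levels, mask, L = random_quantized_roi(rng)
        assert len(ngtdm_features(levels, mask, L)) == 5


class TestOracleEquivalence:
    """Package texture matrices equal independent naive enumeration exactly."""

    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("ndim", [2, 3])
    def test_all_families(self, seed, ndim):
        rng = np.random.default_rng(seed)
        shape = (6, 6) if ndim == 2 else (5, 5, 5)
        levels, mask, L = random_quantized_roi(rng, shape=shape, n_levels=8)
        dirs = tm.unique_directions(ndim)
        assert sorted(dirs) == sorted(all_offsets(ndim))

        # GLCM per direction (skip directions without pairs, as the builder does)
        built = tm.glcm_matrices(levels, mask, L)
        expected = [naive_glcm(levels, mask, L, off) for off in dirs]
        expected = [e for e in expected if e.sum() > 0]
        assert len(built) == len(expected)
        for B, E in zip(built, expected):
            np.testing.assert_array_equal(B, E)

        # GLRLM
        for off, R in zip(dirs, tm.glrlm_matrices(levels, mask, L)):
            E = naive_glrlm(levels, mask, L, off, R.shape[1])
            np.testing.assert_array_equal(R, E)

        # GLSZM
        Z = tm.glszm_matrix(levels, mask, L)
        E = naive_glszm(levels, mask, L, Z.shape[1])
        np.testing.assert_array_equal(Z, E)

        # NGTDM
        n_i, p_i, s_i = tm.ngtdm_table(levels, mask, L)
        on, op, os_ = naive_ngtdm(levels, mask, L)
        np.testing.assert_array_equal(n_i, on)
        np.testing.assert_allclose(s_i, os_, atol=1e-10)


class TestProperties:
    def test_glcm_probability_conservation_and_symmetry(self, rng):
        levels, mask, L = random_quantized_roi(rng, shape=(6, 6, 6), n_levels=8)
        for P in tm.glcm_matrices(levels, mask, L):
            assert P.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(P, P.T)

    @pytest.mark.parametrize("axes", [(1, 2), (0, 1), (0, 2)])
    def test_rotation_consistency_3d(self, axes):
        rng = np.random.default_rng(9)
        levels, mask, L = random_quantized_roi(rng, shape=(6, 6, 6), n_levels=6)
        rot_levels = np.rot90(levels, k=1, axes=axes)
        rot_mask = np.rot90(mask, k=1, axes=axes)
        for fn in (glcm_features, glrlm_features):
            a = fn(levels, mask, L)
            b = fn(rot_levels, rot_mask, L)
            for name in a:
                assert a[name] == pytest.approx(b[name], abs=1e-10), name

    def test_coarseness_increases_with_correlation_length(self):
        """Rank test over 3 correlation lengths x 20 noise seeds on the
        synthetic texture model."""
        lengths = [0.5, 1.5, 3.0]
        means = []
        for corr in lengths:
            vals = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                field = ndi.gaussian_filter(rng.standard_normal((24, 24)), corr, mode="wrap")
                field = 0.5 + 0.15 * field / field.std()
                levels = np.clip(np.ceil(64 * field).astype(int), 1, 64)
                mask = np.ones_like(levels, bool)
                vals.append(ngtdm_features(levels, mask, 64)["NGTDM_Coarseness"])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
        tau = stats.kendalltau(lengths, means).statistic
        assert tau == 1.0


class TestExtractAll:
    def test_exactly_55_in_registry_order(self, preprocessed):
        fv = extract_all(preprocessed["before"]["3D"], patient_id="P0", timepoint="before")
        assert tuple(fv.values) == ALL_FEATURES
        assert len(fv.values) == 55
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_2d_route(self, preprocessed):
        fv = extract_all(preprocessed["before"]["2D"])
        assert len(fv.values) == 55
        assert fv.dimensionality == "2D"

    def test_deterministic(self, preprocessed):
        a = extract_all(preprocessed["after"]["3D"])
        b = extract_all(preprocessed["after"]["3D"])
        assert a.values == b.values

    def test_family_error_is_named(self):
        # single in-mask voxel: GLCM has no pairs
        levels = np.zeros((3, 3, 3), dtype=int)
        mask = np.zeros((3, 3, 3), bool)
        levels[1, 1, 1] = 2
        mask[1, 1, 1] = True
        q = QuantizedROI(levels, mask, 64, (1, 1, 1), "3D", intensities=np.full((3, 3, 3), 0.02))
        with pytest.raises(ValueError, match="glcm"):
            extract_all(q)

    def test_empty_mask_error(self):
        q_levels = np.zeros((2, 2, 2), dtype=int)
        with pytest.raises(ValueError):
            extract_all(
                QuantizedROI(q_levels, np.zeros((2, 2, 2), bool), 64, (1, 1, 1), "3D",
                             intensities=np.zeros((2, 2, 2)))
            )
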