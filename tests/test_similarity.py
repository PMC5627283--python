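import numpy as np
import pytest

from tractatlas.core_tensor import ScalarVolume, TensorVolume
from tractatlas.similarity import (MetricReport, RoiAtlas, anova_conditions,
                                   corr_fa, fa_accuracy_precision, ovl,
                                   ovl_accuracy_precision,
                                   pairwise_tensor_metrics, relative_histogram,
                                   roi_summary, summarize, wilcoxon_matched)

from conftest import random_spd_tensors, tensor_volume_from

AFF = np.eye(4)


def scalar(values, mask=None):
    return ScalarVolume(np.asarray(values, float), AFF, mask)


class TestFaAccuracyPrecision:
    def test_all_equal_gives_zero(self, rng):
        gt = scalar(rng.random((3, 3, 3)))
        acc, prec = fa_accuracy_precision([gt, gt, gt], gt)
        assert np.abs(acc.values).max() < 1e-15
        assert np.abs(prec.values).max() < 1e-30

    def test_hand_case_two_images(self):
        gt = scalar(np.full((1, 1, 1), 0.6))
        a = scalar(np.full((1, 1, 1), 0.5))
        b = scalar(np.full((1, 1, 1), 0.7))
        acc, prec = fa_accuracy_precision([a, b], gt)
        assert acc.values[0, 0, 0] == pytest.approx(0.0, abs=1e-15)
        assert prec.values[0, 0, 0] == pytest.approx(0.01, abs=1e-15)

    def test_hand_case_single_image(self):
        gt = scalar(np.full((2, 2, 2), 0.4))
        a = scalar(np.full((2, 2, 2), 0.5))
        acc, prec = fa_accuracy_precision([a], gt)
        np.testing.assert_allclose(acc.values, 0.1)
        np.testing.assert_allclose(prec.values, 0.01)

    def test_grid_mismatch_raises(self):
        gt = scalar(np.zeros((2, 2, 2)))
        other = ScalarVolume(np.zeros((2, 2, 2)), np.diag([2, 2, 2, 1.0]))
        with pytest.raises(ValueError):
            fa_accuracy_precision([other], gt)


class TestOvl:
    def test_identical_is_one(self, rng):
        tv = tensor_volume_from(random_spd_tensors(rng, 100))
        o = ovl(tv, tv)
        np.testing.assert_allclose(o.values[o.mask], 1.0, atol=1e-12)

    def test_rotated_hand_oracle(self):
        # diag(2,1,1) vs 90 deg z-rotation diag(1,2,1): num 1*... = 1+0+1 wait
        a = tensor_volume_from([np.diag([2.0, 1.0, 1.0])])
        b = tensor_volume_from([np.diag([1.0, 2.0, 1.0])])
        got = ovl(a, b).values[0, 0, 0]
        assert got == pytest.approx(1.0 / 6.0, abs=1e-12)

    def test_isotropic_different_traces(self):
        a = tensor_volume_from([np.eye(3) * 1e-3])
        b = tensor_volume_from([np.eye(3) * 2e-3])
        assert ovl(a, b).values[0, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self, rng):
        a = tensor_volume_from(random_spd_tensors(rng, 50))
        b = tensor_volume_from(random_spd_tensors(rng, 50))
        np.testing.assert_allclose(ovl(a, b).values, ovl(b, a).values,
                                   atol=1e-12)

    def test_range(self, rng):
        a = tensor_volume_from(random_spd_tensors(rng, 200))
        b = tensor_volume_from(random_spd_tensors(rng, 200))
        vals = ovl(a, b).values
        assert vals.min() >= -1e-12 and vals.max() <= 1 + 1e-12

    def test_zero_tensors_masked(self):
        a = tensor_volume_from([np.zeros((3, 3))])
        assert not ovl(a, a).mask[0, 0, 0]


class TestOvlAccuracyPrecision:
    def test_all_equal(self, rng):
        gt = tensor_volume_from(random_spd_tensors(rng, 20))
        acc, prec = ovl_accuracy_precision([gt, gt], gt)
        np.testing.assert_allclose(acc.values[acc.mask], 1.0, atol=1e-12)
        np.testing.assert_allclose(prec.values[prec.mask], 1.0, atol=1e-12)

    def test_rotation_pair_hand_value(self):
        gt = tensor_volume_from([np.diag([2.0, 1.0, 1.0])])
        rot = tensor_volume_from([np.diag([1.0, 2.0, 1.0])])
        _, prec = ovl_accuracy_precision([gt, rot], gt)
        assert prec.values[0, 0, 0] == pytest.approx((1 + 1 / 6) / 2,
                                                     abs=1e-12)

    def test_single_image_accuracy_equals_precision(self, rng):
        gt = tensor_volume_from(random_spd_tensors(rng, 20))
        a = tensor_volume_from(random_spd_tensors(rng, 20))
        acc, prec = ovl_accuracy_precision([a], gt)
        np.testing.assert_allclose(acc.values, prec.values, atol=1e-12)


class TestPairwiseTensorMetrics:
    def test_identical(self, rng):
        a = tensor_volume_from(random_spd_tensors(rng, 30))
        m = pairwise_tensor_metrics(a, a)
        assert np.abs(m["DTED"].values).max() == 0.0
        assert np.abs(m["DVED"].values).max() == 0.0
        np.testing.assert_allclose(m["AI"].values[m["AI"].mask], 0.0,
                                   atol=1e-5)
        np.testing.assert_allclose(m["COH"].values[m["COH"].mask], 1.0,
                                   atol=1e-12)

    def test_hand_frobenius_values(self):
        a = tensor_volume_from([np.eye(3) * 1e-3])
        b = tensor_volume_from([np.diag([2e-3, 1e-3, 1e-3])])
        m = pairwise_tensor_metrics(a, b)
        assert m["DTED"].values[0, 0, 0] == pytest.approx(1e-3, rel=1e-12)
        dved = np.linalg.norm(np.diag([2 / 3, -1 / 3, -1 / 3])) * 1e-3
        assert m["DVED"].values[0, 0, 0] == pytest.approx(dved, rel=1e-9)

    def test_antipodal_eigenvectors(self):
        a = tensor_volume_from([np.diag([2e-3, 1e-3, 0.5e-3])])
        R = np.diag([-1.0, -1.0, 1.0])        # maps x-hat to -x-hat
        b = tensor_volume_from([R @ np.diag([2e-3, 1e-3, 0.5e-3]) @ R.T])
        m = pairwise_tensor_metrics(a, b)
        assert m["AI"].values[0, 0, 0] == pytest.approx(0.0, abs=1e-6)
        assert m["COH"].values[0, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_excluded_from_direction_masks(self):
        iso = tensor_volume_from([np.eye(3) * 1e-3])
        m = pairwise_tensor_metrics(iso, iso)
        assert not m["AI"].mask[0, 0, 0]
        assert not m["COH"].mask[0, 0, 0]
        assert m["DTED"].mask[0, 0, 0]

    def test_symmetry_bitwise(self, rng):
        a = tensor_volume_from(random_spd_tensors(rng, 40))
        b = tensor_volume_from(random_spd_tensors(rng, 40))
        mab = pairwise_tensor_metrics(a, b)
        mba = pairwise_tensor_metrics(b, a)
        np.testing.assert_array_equal(np.abs(mab["DTED"].values),
                                      np.abs(mba["DTED"].values))
        np.testing.assert_allclose(mab["AI"].values, mba["AI"].values,
                                   atol=1e-12)
        np.testing.assert_allclose(mab["COH"].values, mba["COH"].values,
                                   atol=1e-12)

    def test_pythagorean_split(self, rng):
        # DTED^2 = DVED^2 + 3 * (delta_tr / 3)^2
        a = tensor_volume_from(random_spd_tensors(rng, 100))
        b = tensor_volume_from(random_spd_tensors(rng, 100))
        m = pairwise_tensor_metrics(a, b)
        dtr = (np.trace(a.tensors, axis1=-2, axis2=-1)
               - np.trace(b.tensors, axis1=-2, axis2=-1))
        lhs = m["DTED"].values ** 2
        rhs = m["DVED"].values ** 2 + 3 * (dtr / 3) ** 2
        np.testing.assert_allclose(lhs, rhs, atol=1e-12 * lhs.max())

    def test_rigid_motion_equivariance(self, rng):
        from scipy.stats import special_ortho_group
        a = tensor_volume_from(random_spd_tensors(rng, 50))
        b = tensor_volume_from(random_spd_tensors(rng, 50))
        R = special_ortho_group.rvs(3, random_state=11)
        ar = tensor_volume_from(R @ a.tensors[:, 0, 0] @ R.T)
        br = tensor_volume_from(R @ b.tensors[:, 0, 0] @ R.T)
        m0 = pairwise_tensor_metrics(a, b)
        m1 = pairwise_tensor_metrics(ar, br)
        for k in ("DTED", "DVED", "COH"):
            np.testing.assert_allclose(m1[k].values, m0[k].values, atol=1e-9)
        np.testing.assert_allclose(ovl(ar, br).values, ovl(a, b).values,
                                   atol=1e-9)

    def test_angle_units(self):
        a = tensor_volume_from([np.diag([2e-3, 1e-3, 0.5e-3])])
        Rz = np.array([[0, -1.0, 0], [1.0, 0, 0], [0, 0, 1.0]])
        b = tensor_volume_from(
            [Rz @ np.diag([2e-3, 1e-3, 0.5e-3]) @ Rz.T])
        deg = pairwise_tensor_metrics(a, b)["AI"].values[0, 0, 0]
        rad = pairwise_tensor_metrics(a, b, angle_units="radians")
        assert deg == pytest.approx(90.0)
        assert rad["AI"].values[0, 0, 0] == pytest.approx(np.pi / 2)


class TestCorrFa:
    def test_identical_images(self, rng):
        im = scalar(rng.random((4, 4, 4)))
        mat, mean = corr_fa([im, im])
        assert mat[0, 1] == pytest.approx(1.0)
        assert mean == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        x = scalar(rng.random((4, 4, 4)))
        y = scalar(2.0 * x.values + 0.1)
        mat, mean = corr_fa([x, y])
        assert mean == pytest.approx(1.0)

    def test_textbook_oracle_on_listed_values(self):
        region = np.zeros((5, 1, 1), bool)
        region[:, 0, 0] = True
        vals = [np.array([0.1, 0.2, 0.3, 0.4, 0.5]),
                np.array([0.2, 0.1, 0.4, 0.3, 0.5]),
                np.array([0.5, 0.4, 0.3, 0.2, 0.1])]
        ims = [scalar(v.reshape(5, 1, 1)) for v in vals]
        mat, mean = corr_fa(ims, region)
        for i in range(3):
            for j in range(3):
                expect = np.corrcoef(vals[i], vals[j])[0, 1]
                assert mat[i, j] == pytest.approx(expect, abs=1e-12)
        off = [mat[0, 1], mat[0, 2], mat[1, 2]]
        assert mean == pytest.approx(np.mean(off))

    def test_needs_two_images(self, rng):
        with pytest.raises(ValueError):
            corr_fa([scalar(rng.random((3, 3, 3)))])

    def test_zero_variance_pair_excluded(self, rng):
        flat = scalar(np.full((3, 3, 3), 0.5))
        x = scalar(rng.random((3, 3, 3)))
        y = scalar(rng.random((3, 3, 3)))
        mat, mean = corr_fa([flat, x, y])
        assert np.isnan(mat[0, 1]) and np.isnan(mat[0, 2])
        assert mean == pytest.approx(np.corrcoef(
            x.values.ravel(), y.values.ravel())[0, 1])


class TestSummaries:
    def _atlas(self):
        m1 = np.zeros((4, 4, 4), bool)
        m1[:2] = True
        m2 = ~m1
        empty = np.zeros((4, 4, 4), bool)
        return RoiAtlas({"front": m1, "back": m2, "void": empty}, AFF)

    def test_constant_map_roi_rows(self):
        vol = scalar(np.full((4, 4, 4), 0.42))
        tab = roi_summary(vol, self._atlas())
        filled = tab[tab.roi != "void"]
        np.testing.assert_allclose(filled["mean"], 0.42, atol=1e-12)
        np.testing.assert_allclose(filled["sd"], 0.0, atol=1e-12)
        void = tab[tab.roi == "void"].iloc[0]
        assert np.isnan(void["mean"]) and void["n_voxels"] == 0

    def test_histogram_fractions_sum_to_one(self, rng):
        vol = scalar(rng.random((6, 6, 6)))
        hist = relative_histogram(vol, bins=32)
        assert hist["fraction"].sum() == pytest.approx(1.0)

    def test_anova_identical_conditions(self, rng):
        x = rng.random(100)
        res = anova_conditions({"a": x, "b": x, "c": x})
        assert res["F"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_anova_detects_shift(self, rng):
        res = anova_conditions({"a": rng.normal(0, 1, 200),
                                "b": rng.normal(2, 1, 200)})
        assert res["p"] < 1e-10
        assert all(p <= 1 for p in res["pairwise_bonferroni"].values())

    def test_wilcoxon_utility(self, rng):
        a = rng.random(30)
        assert wilcoxon_matched(a, a)["p"] == 1.0
        res = wilcoxon_matched(a, a + 0.5)
        assert res["p"] < 1e-4

    def test_summarize_assembles_report(self, rng):
        maps = {"pair0": scalar(rng.random((4, 4, 4))),
                "pair1": scalar(rng.random((4, 4, 4)))}
        rep = summarize("OVL", maps, self._atlas(), bins=10,
                        condition_values={"FA": rng.random(50),
                                          "hFA": rng.random(50)})
        assert isinstance(rep, MetricReport)
        assert set(rep.roi_table["map"]) == {"pair0", "pair1"}
        assert rep.histogram["fraction"].sum() == pytest.approx(1.0)
        assert "anova" in rep.tests
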