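import numpy as np
import pytest

from radrobust.features import (
    ExtractionConfig,
    discretize,
    extract_all,
    extract_one,
    first_order,
)
from radrobust.features.discretize import DiscretizedRegion
from radrobust.features.glcm import cooccurrence_matrix, glcm_features
from radrobust.features.gldm import dependence_matrix, gldm_features
from radrobust.features.glrlm import glrlm_features, run_length_matrix, _glrlm_features_one
from radrobust.features.glszm import glszm_features, size_zone_table
from radrobust.features.ngtdm import ngtdm_features, tone_difference_table, COARSENESS_CAP
from radrobust.perturb import make_triplet
from radrobust.types import LesionRecord

from conftest import random_region
from _oracles import (
    glcm_bruteforce,
    gldm_bruteforce,
    glrlm_bruteforce,
    glszm_bruteforce,
    ngtdm_bruteforce,
)


def region_of(levels, ng):
    levels = np.asarray(levels)
    mask = levels > 0
    return DiscretizedRegion(levels=levels, mask=mask, ng=ng, bin_edges=np.array([]))


class TestDiscretize:
    def test_constant_region_single_level(self):
        img = np.full((6, 6), 42, dtype=np.int64)
        reg = discretize(img, np.ones((6, 6), bool), n_bins=32)
        assert reg.ng == 1
        assert (reg.levels[reg.mask] == 1).all()

    def test_256_values_into_64_bins(self):
        img = np.arange(256, dtype=np.int64).reshape(16, 16)
        reg = discretize(img, np.ones((16, 16), bool), n_bins=64)
        counts = np.bincount(reg.levels[reg.mask], minlength=65)[1:]
        assert (counts == 4).all()

    def test_subunit_width_levels(self):
        img = np.arange(10, 74, dtype=np.int64).reshape(8, 8)
        reg = discretize(img, np.ones((8, 8), bool), n_bins=64)
        np.testing.assert_array_equal(reg.levels[reg.mask], img.ravel() - 9)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            discretize(np.zeros((4, 4), dtype=np.int64), np.zeros((4, 4), bool))


class TestFirstOrder:
    def test_worked_example(self):
        img = np.array([[1, 2], [3, 4]], dtype=np.int64)
        mask = np.ones((2, 2), bool)
        f = first_order(img, mask)
        assert f["FO.mean"] == pytest.approx(2.5)
        assert f["FO.energy"] == pytest.approx(30)
        assert f["FO.maximum"] == 4
        assert f["FO.mad"] == pytest.approx(1.0)
        assert f["FO.variance"] == pytest.approx(1.25)
        assert f["FO.rms"] == pytest.approx(np.sqrt(7.5))
        assert f["FO.skewness"] == pytest.approx(0.0)  # symmetric sample
        assert f["FO.entropy"] == pytest.approx(2.0)  # 4 equiprobable levels

    def test_constant_region_degenerate_moments(self):
        img = np.full((3, 3), 7, dtype=np.int64)
        f = first_order(img, np.ones((3, 3), bool))
        assert f["FO.variance"] == 0
        assert f["FO.entropy"] == 0
        assert f["FO.skewness"] == 0
        assert f["FO.kurtosis"] == 0


class TestGLCM:
    def test_two_column_example(self):
        reg = region_of([[1, 2], [1, 2]], ng=2)
        counts = cooccurrence_matrix(reg, 1, 0)
        np.testing.assert_allclose(counts, [[0, 2], [2, 0]])
        f = glcm_features(reg, 1, angles=(0,))
        assert f["GLCM.contrast"] == pytest.approx(1.0)
        assert f["GLCM.joint_entropy"] == pytest.approx(1.0)
        assert f["GLCM.joint_energy"] == pytest.approx(0.5)

    def test_constant_region(self):
        reg = region_of([[1, 1], [1, 1]], ng=1)
        f = glcm_features(reg)
        assert f["GLCM.contrast"] == 0
        assert f["GLCM.joint_entropy"] == 0
        assert f["GLCM.joint_energy"] == 1
        assert f["GLCM.correlation"] == 1.0

    def test_matches_bruteforce(self, rng):
        from radrobust.features.glcm import ANGLE_OFFSETS

        for _ in range(25):
            reg = random_region(rng, max_size=16)
            for angle, off in ANGLE_OFFSETS.items():
                np.testing.assert_allclose(
                    cooccurrence_matrix(reg, 1, angle),
                    glcm_bruteforce(reg.levels, reg.mask, off, reg.ng),
                )


class TestGLRLM:
    def test_horizontal_example(self):
        reg = region_of([[1, 1, 2], [1, 1, 2]], ng=2)
        p = run_length_matrix(reg, (0, 1))
        assert p[0, 1] == 2 and p[1, 0] == 2 and p.sum() == 4
        f = _glrlm_features_one(p, reg.n_pixels)
        assert f["GLRLM.rp"] == pytest.approx(4 / 6)
        assert f["GLRLM.sre"] == pytest.approx((2 / 4 + 2 / 1) / 4)

    def test_constant_row(self):
        reg = region_of([[1, 1, 1, 1, 1]], ng=1)
        f = _glrlm_features_one(run_length_matrix(reg, (0, 1)), reg.n_pixels)
        assert f["GLRLM.lre"] == pytest.approx(25)
        assert f["GLRLM.rp"] == pytest.approx(0.2)

    def test_matches_bruteforce(self, rng):
        from radrobust.features.glrlm import DIRECTIONS

        for _ in range(25):
            reg = random_region(rng, max_size=16)
            for direction in DIRECTIONS.values():
                mine = run_length_matrix(reg, direction)
                ref = glrlm_bruteforce(reg.levels, reg.mask, direction, reg.ng)
                np.testing.assert_allclose(mine[:, : ref.shape[1]], ref[:, : mine.shape[1]])

    def test_single_pixel(self):
        reg = region_of([[3]], ng=3)
        f = glrlm_features(reg)
        assert f["GLRLM.rp"] == pytest.approx(1.0)


class TestGLSZM:
    def test_two_zone_example(self):
        reg = region_of([[1, 1, 2], [1, 1, 2]], ng=2)
        assert size_zone_table(reg) == [(1, 4), (2, 2)]
        f = glszm_features(reg)
        assert f["GLSZM.zp"] == pytest.approx(2 / 6)
        assert f["GLSZM.sae"] == pytest.approx((1 / 16 + 1 / 4) / 2)

    def test_constant_region(self):
        reg = region_of(np.ones((3, 4), dtype=int), ng=1)
        f = glszm_features(reg)
        assert f["GLSZM.zp"] == pytest.approx(1 / 12)
        assert f["GLSZM.lae"] == pytest.approx(144)

    def test_matches_bruteforce(self, rng):
        for _ in range(25):
            reg = random_region(rng, max_size=16)
            assert sorted(size_zone_table(reg)) == glszm_bruteforce(reg.levels, reg.mask)


class TestGLDM:
    def test_constant_2x2(self):
        reg = region_of(np.ones((2, 2), dtype=int), ng=1)
        p = dependence_matrix(reg, delta=1, alpha=0)
        assert p[0, 3] == 4 and p.sum() == 4
        assert gldm_features(reg)["GLDM.dep_entropy"] == 0

    def test_single_pixel(self):
        reg = region_of([[2]], ng=2)
        p = dependence_matrix(reg)
        assert p[1, 0] == 1 and p.sum() == 1

    def test_matches_bruteforce(self, rng):
        for _ in range(25):
            reg = random_region(rng, max_size=16)
            for delta, alpha in ((1, 0), (1, 1), (2, 0)):
                np.testing.assert_allclose(
                    dependence_matrix(reg, delta, alpha),
                    gldm_bruteforce(reg.levels, reg.mask, delta, alpha, reg.ng),
                )


class TestNGTDM:
    def test_constant_region_caps_coarseness(self):
        reg = region_of(np.ones((3, 3), dtype=int), ng=1)
        f = ngtdm_features(reg)
        assert f["NGTDM.contrast"] == 0
        assert f["NGTDM.coarseness"] == COARSENESS_CAP

    def test_two_pixel_example(self):
        reg = region_of([[1, 2]], ng=2)
        n, s = tone_difference_table(reg, 1)
        np.testing.assert_allclose(n, [1, 1])
        np.testing.assert_allclose(s, [1, 1])

    def test_matches_bruteforce(self, rng):
        for _ in range(25):
            reg = random_region(rng, max_size=16)
            n, s = tone_difference_table(reg, 1)
            n_ref, s_ref = ngtdm_bruteforce(reg.levels, reg.mask, 1, reg.ng)
            np.testing.assert_allclose(n, n_ref)
            np.testing.assert_allclose(s, s_ref, atol=1e-10)


class TestMaskRestriction:
    def test_out_of_mask_pixels_irrelevant(self, rng):
        img = rng.integers(0, 1000, size=(20, 20)).astype(np.int64)
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = rng.random((10, 10)) < 0.7
        mask[10, 10] = True
        before = extract_one(img, mask)
        tampered = img.copy()
        tampered[~mask] = rng.integers(0, 1000, size=int((~mask).sum()))
        after = extract_one(tampered, mask)
        assert before == after


class TestExtractAll:
    def _case(self, rng, radius=22):
        img = rng.integers(100, 900, size=(64, 64)).astype(np.int64)
        rows = np.arange(64)[:, None] - 32
        cols = np.arange(64)[None, :] - 32
        mask = np.hypot(rows, cols) <= radius
        return img, mask

    def test_three_rows_share_metadata(self, rng):
        img, mask = self._case(rng)
        rows = extract_all(img, make_triplet(mask), LesionRecord("c1", "mass", "benign", "CC"))
        assert len(rows) == 3
        assert [r["segmentation_class"] for r in rows] == ["original", "over", "under"]
        assert all(r["case_id"] == "c1" for r in rows)

    def test_degenerate_triplet_two_rows(self, rng, caplog):
        img = rng.integers(0, 255, size=(12, 12)).astype(np.int64)
        mask = np.zeros((12, 12), bool)
        mask[5:8, 5:8] = True
        rows = extract_all(img, make_triplet(mask), LesionRecord("c2", "mass", "benign", "CC"))
        assert len(rows) == 2
        assert "degenerate" in caplog.text

    def test_feature_count_and_families(self, rng):
        img, mask = self._case(rng)
        values = extract_one(img, mask, ExtractionConfig())
        families = {k.split(".")[0] for k in values}
        assert families == {"FO", "GLCM", "GLDM", "GLRLM", "GLSZM", "NGTDM"}
        assert len(values) == 40
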