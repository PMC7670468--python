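"""Texture-matrix features against hand enumerations and brute-force oracles."""

import math

import numpy as np
import pytest

from marginrad.prep import DiscretizedVolume
from marginrad.features import texture as tx

from .conftest import random_discretized
from . import oracles


def dvol_from(levels, n_levels=None):
    levels = np.asarray(levels, dtype=np.int64)
    if levels.ndim == 2:
        levels = levels[:, :, None]
    mask = levels > 0
    return DiscretizedVolume(levels, n_levels or int(levels.max()), mask)


def assert_close_dicts(got, expected, tol=1e-9):
    for k, v in expected.items():
        g = got[k]
        assert math.isclose(g, v, rel_tol=tol, abs_tol=1e-12), f"{k}: {g} vs {v}"


class TestGLCMHandExamples:
    def test_two_by_two_single_offset(self):
        d = dvol_from([[1, 1], [2, 2]])
        mats = tx.glcm_matrices(d, offsets=[(0, 1, 0)])
        assert len(mats) == 1
        assert np.allclose(mats[0], [[0.5, 0.0], [0.0, 0.5]])
        feats, flags = tx.glcm_features(d, offsets=[(0, 1, 0)])
        assert feats["Contrast"] == 0.0
        assert feats["JointEnergy"] == 0.5
        assert not flags

    def test_constant_voi(self):
        d = dvol_from(np.ones((3, 3, 2), dtype=int))
        feats, _ = tx.glcm_features(d)
        assert feats["Contrast"] == 0.0
        assert feats["Idm"] == feats["Idmn"] == feats["Idn"] == 1.0
        assert feats["JointEnergy"] == 1.0

    def test_no_pairs_flagged(self):
        levels = np.zeros((3, 3, 1), dtype=np.int64)
        levels[0, 0, 0] = 1  # a single isolated voxel: no co-occurring pair
        d = DiscretizedVolume(levels, 4, levels > 0)
        feats, flags = tx.glcm_features(d)
        assert set(flags) == set(tx.GLCM_NAMES)


class TestGLRLMHandExamples:
    def test_run_percentage_1d(self):
        d = dvol_from(np.array([1, 1, 1, 2]).reshape(4, 1, 1))
        feats, _ = tx.glrlm_features(d, directions=[(1, 0, 0)])
        assert feats["RunPercentage"] == pytest.approx(2 / 4)

    def test_single_run_long_run_emphasis(self):
        n = 6
        d = dvol_from(np.ones((n, 1, 1), dtype=int))
        feats, _ = tx.glrlm_features(d, directions=[(1, 0, 0)])
        assert feats["LongRunEmphasis"] == pytest.approx(n**2)
        assert feats["RunPercentage"] == pytest.approx(1 / n)


class TestGLSZMHandExamples:
    def test_two_disjoint_single_voxel_zones(self):
        levels = np.zeros((5, 5, 1), dtype=np.int64)
        levels[0, 0, 0] = 1
        levels[4, 4, 0] = 1
        d = DiscretizedVolume(levels, 1, levels > 0)
        mat = tx.glszm_matrix(d)
        assert mat[0, 0] == 2

    def test_checkerboard_all_singleton_zones(self):
        ii, jj = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
        levels = ((ii + jj) % 2 + 1)[:, :, None].astype(np.int64)
        d = DiscretizedVolume(levels, 2, np.ones((4, 4, 1), bool))
        # in-plane checkerboard: 26-connectivity joins diagonal same-level
        # cells, so force 3D-disconnected singletons by spacing them out
        levels2 = np.zeros((4, 4, 2), dtype=np.int64)
        levels2[::2, ::2, 0] = 1
        levels2[1::2, 1::2, 1] = 2
        d2 = DiscretizedVolume(levels2, 2, levels2 > 0)
        feats, _ = tx.glszm_features(d2)
        assert feats["ZonePercentage"] == pytest.approx(1.0)


class TestGLDMHandExamples:
    def test_single_voxel(self):
        levels = np.zeros((3, 3, 1), dtype=np.int64)
        levels[1, 1, 0] = 2
        d = DiscretizedVolume(levels, 3, levels > 0)
        mat = tx.gldm_matrix(d)
        # dependence 0 neighbours -> one entry at j = 1
        assert mat.shape[1] == 1
        assert mat[1, 0] == 1

    def test_constant_patch_dependence_extremes(self):
        d = dvol_from(np.ones((3, 3, 1), dtype=int))
        mat = tx.gldm_matrix(d)
        # centre voxel of a 3x3 slab has all 8 in-plane neighbours equal
        assert mat.shape[1] == 9  # max dependence count 8 -> j = 9
        feats, _ = tx.gldm_features(d)
        assert feats["LargeDependenceEmphasis"] > feats["SmallDependenceEmphasis"]


class TestNGTDMHandExamples:
    def test_constant_voi_hits_coarseness_cap(self):
        d = dvol_from(np.ones((3, 3, 2), dtype=int))
        feats, flags = tx.ngtdm_features(d)
        assert feats["Coarseness"] == tx.COARSENESS_CAP
        assert feats["Contrast"] == 0.0
        assert "Coarseness" in flags

    def test_alternating_line_busyness(self):
        # [1,2,1,2]: s_1 = s_2 = 2, p = (1/2, 1/2); Busyness = 2
        d = dvol_from(np.array([1, 2, 1, 2]).reshape(4, 1, 1))
        feats, _ = tx.ngtdm_features(d)
        assert feats["Busyness"] == pytest.approx(2.0)


NAME_MAPS = {
    "glrlm": tx._GLRLM_MAP,
    "glszm": tx._GLSZM_MAP,
    "gldm": tx._GLDM_MAP,
}


class TestBruteForceOracles:
    """Implementation vs independent enumeration on random small volumes."""

    N_VOLUMES = 25  # the acceptance suite runs the full 100-volume sweep

    def volumes(self):
        rng = np.random.default_rng(7)
        for i in range(self.N_VOLUMES):
            ng = int(rng.integers(2, 9))
            yield random_discretized(rng, shape=(8, 8, 4), n_levels=ng, fill=0.65), ng

    def test_glcm(self):
        for d, ng in self.volumes():
            got, flags = tx.glcm_features(d)
            expected = oracles.glcm_oracle(d.levels, d.mask, ng)
            if expected is None:
                assert flags
                continue
            assert_close_dicts(got, expected)

    def test_glrlm(self):
        for d, ng in self.volumes():
            got, _ = tx.glrlm_features(d)
            generic = oracles.glrlm_oracle(d.levels, d.mask, ng)
            expected = {fam: generic[gen] for fam, gen in tx._GLRLM_MAP.items()}
            assert_close_dicts(got, expected)

    def test_glszm(self):
        for d, ng in self.volumes():
            got, _ = tx.glszm_features(d)
            generic = oracles.glszm_oracle(d.levels, d.mask, ng)
            expected = {fam: generic[gen] for fam, gen in tx._GLSZM_MAP.items()}
            assert_close_dicts(got, expected)

    def test_gldm(self):
        for d, ng in self.volumes():
            got, _ = tx.gldm_features(d)
            generic = oracles.gldm_oracle(d.levels, d.mask, ng)
            expected = {fam: generic[gen] for fam, gen in tx._GLDM_MAP.items()}
            assert_close_dicts(got, expected)

    def test_ngtdm(self):
        for d, ng in self.volumes():
            got, _ = tx.ngtdm_features(d)
            expected = oracles.ngtdm_oracle(d.levels, d.mask, ng)
            assert_close_dicts(got, expected)


class TestMatrixInvariants:
    def test_glcm_matrices_normalized_and_symmetric(self, rng):
        for _ in range(5):
            d = random_discretized(rng, n_levels=6)
            for m in tx.glcm_matrices(d):
                assert m.sum() == pytest.approx(1.0)
                assert np.allclose(m, m.T)

    def test_counts_nonnegative_and_sizes_consistent(self, rng):
        d = random_discretized(rng, n_levels=5)
        for m in tx.glrlm_matrices(d):
            assert np.all(m >= 0)
            assert m.shape[0] == 5
        z = tx.glszm_matrix(d)
        assert np.all(z >= 0)
        assert z.sum(axis=1).sum() > 0

    def test_order_preserving_relabel_keeps_structural_features(self, rng):
        """Features that depend only on level equality (not magnitude) are
        invariant under order-preserving relabelings that keep distinct
        levels distinct."""
        d = random_discretized(rng, n_levels=4)
        relabeled = np.where(d.mask, d.levels * 2, 0)  # 1..4 -> 2,4,6,8
        d2 = DiscretizedVolume(relabeled, 8, d.mask)
        f1, _ = tx.glrlm_features(d)
        f2, _ = tx.glrlm_features(d2)
        for k in ["ShortRunEmphasis", "LongRunEmphasis", "RunPercentage",
                  "RunLengthNonUniformity", "RunVariance"]:
            assert f1[k] == pytest.approx(f2[k], rel=1e-12)
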