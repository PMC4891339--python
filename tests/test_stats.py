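"""Two-sample t, Hotelling's T2 and permutation maxT FWE control."""

import numpy as np
import pytest
from scipy import stats as sps

from svfmorph.stats import (
    GroupStudy,
    fwe_threshold_maxT,
    hotelling_t2_map,
    ttest_fwe,
    two_sample_tmap,
)


def scalar_study(group1, group2, mask=None):
    fields = [np.asarray(g, dtype=float) for g in group1 + group2]
    labels = ["a"] * len(group1) + ["b"] * len(group2)
    if mask is None:
        mask = np.ones(fields[0].shape[:3], dtype=bool)
    return GroupStudy(fields=fields, labels=labels, mask=mask)


def const_map(value, shape=(4, 4, 4)):
    return np.full(shape, float(value))


class TestTMap:
    def test_identical_groups_give_zero(self):
        maps = [const_map(v) for v in (1.0, 2.0, 3.0)]
        study = scalar_study(maps, [m.copy() for m in maps])
        np.testing.assert_array_equal(two_sample_tmap(study), 0.0)

    def test_toy_groups_match_hand_computed_pooled_t(self):
        study = scalar_study([const_map(v) for v in (1, 2, 3)],
                             [const_map(v) for v in (4, 5, 6)])
        t = two_sample_tmap(study)
        # pooled sd 1, SE sqrt(2/3) => t = -3/0.8165 = -3.674
        np.testing.assert_allclose(t, -3.674234, atol=1e-5)

    def test_null_t_follows_student_distribution(self, rng):
        n1 = n2 = 8
        fields = [rng.standard_normal((22, 22, 22)) for _ in range(n1 + n2)]
        study = GroupStudy(fields=fields, labels=["a"] * n1 + ["b"] * n2,
                           mask=np.ones((22, 22, 22), dtype=bool))
        t = two_sample_tmap(study).ravel()
        ks = sps.kstest(t, sps.t(df=n1 + n2 - 2).cdf)
        assert ks.pvalue > 0.01

    def test_label_swap_flips_sign(self, rng):
        g1 = [rng.standard_normal((5, 5, 5)) for _ in range(3)]
        g2 = [rng.standard_normal((5, 5, 5)) for _ in range(4)]
        t_ab = two_sample_tmap(scalar_study(g1, g2))
        fields = g2 + g1
        swapped = GroupStudy(fields=fields, labels=["a"] * 4 + ["b"] * 3,
                             mask=np.ones((5, 5, 5), dtype=bool))
        np.testing.assert_allclose(two_sample_tmap(swapped), -t_ab,
                                   atol=1e-12)

    def test_zero_variance_voxels_get_zero(self):
        g1 = [const_map(1.0), const_map(1.0)]
        g2 = [const_map(2.0), const_map(2.0)]
        t = two_sample_tmap(scalar_study(g1, g2))
        np.testing.assert_array_equal(t, 0.0)  # zero pooled variance


class TestMaxT:
    def test_alpha_one_returns_minimum_maximum(self, rng):
        fields = [rng.standard_normal((6, 6, 6)) for _ in range(10)]
        study = GroupStudy(fields=fields, labels=["a"] * 5 + ["b"] * 5,
                           mask=np.ones((6, 6, 6), dtype=bool))
        thr = fwe_threshold_maxT(study, n_perm=50, alpha=1.0, seed=0)
        smap = ttest_fwe(study, n_perm=50, alpha=1.0, seed=0)
        assert thr == smap.null_maxima.min()

    def test_determinism_under_seed(self, rng):
        fields = [rng.standard_normal((6, 6, 6)) for _ in range(12)]
        study = GroupStudy(fields=fields, labels=["a"] * 6 + ["b"] * 6,
                           mask=np.ones((6, 6, 6), dtype=bool))
        a = ttest_fwe(study, n_perm=100, seed=7)
        b = ttest_fwe(study, n_perm=100, seed=7)
        assert a.threshold == b.threshold
        np.testing.assert_array_equal(a.significant, b.significant)
        np.testing.assert_array_equal(a.null_maxima, b.null_maxima)

    def test_exhaustive_enumeration_when_few_relabelings(self, rng):
        fields = [rng.standard_normal((4, 4, 4)) for _ in range(6)]
        study = GroupStudy(fields=fields, labels=["a"] * 3 + ["b"] * 3,
                           mask=np.ones((4, 4, 4), dtype=bool))
        with pytest.warns(UserWarning, match="exhaustively"):
            smap = ttest_fwe(study, n_perm=1000, seed=0)
        # C(6, 3) subsets, halved because a balanced subset and its
        # complement carry the same unsigned statistic
        assert smap.n_perm == 10

    def test_planted_effect_found_with_good_dice(self, rng):
        shape = (20, 20, 20)
        cube = np.zeros(shape, dtype=bool)
        cube[6:12, 6:12, 6:12] = True
        fields = []
        for k in range(16):
            f = rng.standard_normal(shape)
            if k < 8:
                f += 5.0 * cube
            fields.append(f)
        study = GroupStudy(fields=fields, labels=["a"] * 8 + ["b"] * 8,
                           mask=np.ones(shape, dtype=bool))
        smap = ttest_fwe(study, n_perm=300, seed=3)
        sig = smap.significant
        dice = 2 * (sig & cube).sum() / (sig.sum() + cube.sum())
        assert dice > 0.5

    def test_volume_bookkeeping(self, rng):
        fields = [rng.standard_normal((6, 6, 6)) for _ in range(8)]
        study = GroupStudy(fields=fields, labels=["a"] * 4 + ["b"] * 4,
                           mask=np.ones((6, 6, 6), dtype=bool),
                           voxel_volume_mm3=1.728)
        smap = ttest_fwe(study, n_perm=60, alpha=0.5, seed=2)
        assert smap.volume_mm3 == pytest.approx(
            smap.significant.sum() * 1.728)


class TestHotelling:
    def test_identical_groups_give_zero(self, rng):
        maps = [rng.standard_normal((4, 4, 4, 3)) for _ in range(3)]
        study = GroupStudy(fields=maps + [m.copy() for m in maps],
                           labels=["a"] * 3 + ["b"] * 3,
                           mask=np.ones((4, 4, 4), dtype=bool))
        smap = hotelling_t2_map(study, n_perm=10, seed=0)
        np.testing.assert_allclose(smap.values, 0.0, atol=1e-20)

    def test_one_component_reduces_to_squared_t(self, rng):
        shape = (5, 5, 5)
        scalars = [rng.standard_normal(shape) for _ in range(10)]
        labels = ["a"] * 5 + ["b"] * 5
        mask = np.ones(shape, dtype=bool)
        t = two_sample_tmap(GroupStudy(fields=scalars, labels=labels,
                                       mask=mask))
        vecs = [s[..., None] for s in scalars]
        study1d = GroupStudy(fields=vecs, labels=labels, mask=mask)
        t2 = hotelling_t2_map(study1d, n_perm=10, seed=0).values
        np.testing.assert_allclose(t2, t ** 2, atol=1e-10)

    def test_toy_vectors_match_direct_formula(self, rng):
        g1 = [rng.standard_normal((2, 2, 2, 3)) for _ in range(5)]
        g2 = [rng.standard_normal((2, 2, 2, 3)) + 0.5 for _ in range(4)]
        study = GroupStudy(fields=g1 + g2, labels=["a"] * 5 + ["b"] * 4,
                           mask=np.ones((2, 2, 2), dtype=bool))
        smap = hotelling_t2_map(study, n_perm=10, seed=0)
        # brute-force at every voxel
        n1, n2 = 5, 4
        for vox in np.ndindex(2, 2, 2):
            X1 = np.array([g[vox] for g in g1])
            X2 = np.array([g[vox] for g in g2])
            d = X1.mean(0) - X2.mean(0)
            S = ((X1 - X1.mean(0)).T @ (X1 - X1.mean(0))
                 + (X2 - X2.mean(0)).T @ (X2 - X2.mean(0))) / (n1 + n2 - 2)
            t2 = n1 * n2 / (n1 + n2) * d @ np.linalg.solve(S, d)
            assert smap.values[vox] == pytest.approx(t2, rel=1e-8)

    def test_label_swap_leaves_t2_unchanged(self, rng):
        g1 = [rng.standard_normal((3, 3, 3, 3)) for _ in range(4)]
        g2 = [rng.standard_normal((3, 3, 3, 3)) for _ in range(4)]
        mask = np.ones((3, 3, 3), dtype=bool)
        a = hotelling_t2_map(GroupStudy(fields=g1 + g2,
                                        labels=["a"] * 4 + ["b"] * 4,
                                        mask=mask), n_perm=10, seed=0)
        b = hotelling_t2_map(GroupStudy(fields=g2 + g1,
                                        labels=["a"] * 4 + ["b"] * 4,
                                        mask=mask), n_perm=10, seed=0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            GroupStudy(fields=[rng.standard_normal((2, 2, 2, 3))] * 3,
                       labels=["a", "a", "b"],
                       mask=np.ones((2, 2, 2), dtype=bool))


class TestGroupStudy:
    def test_exactly_two_groups_required(self, rng):
        with pytest.raises(ValueError, match="two groups"):
            GroupStudy(fields=[rng.standard_normal((2, 2, 2))] * 4,
                       labels=["a", "b", "c", "a"],
                       mask=np.ones((2, 2, 2), dtype=bool))

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            GroupStudy(fields=[rng.standard_normal((2, 2, 2)),
                               rng.standard_normal((3, 3, 3))] * 2,
                       labels=["a", "a", "b", "b"],
                       mask=np.ones((2, 2, 2), dtype=bool))
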