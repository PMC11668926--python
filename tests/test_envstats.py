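import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from asvkit.core_io import DistanceMatrix, SampleMetadata
from asvkit.envstats import (
    env_distance,
    kruskal_wallis,
    mantel,
    partial_mantel,
    vpa_two_sets,
    wilcoxon_rank_sum,
)


def euclid_dm(ids, pts):
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    if pts.shape[0] != len(ids):
        pts = pts.T
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return DistanceMatrix(ids, d)


def meta_from(ids, **columns):
    frame = pd.DataFrame(columns, index=pd.Index(ids, name="sample_id"))
    frame.setdefault = None
    for col, default in (("season", "spring"), ("landform", "plain"),
                         ("dist_to_mouth_km", 0.0)):
        if col not in frame:
            frame[col] = default
    return SampleMetadata(frame)


class TestMantel:
    def test_self_correlation_one(self, rng):
        ids = [f"s{i}" for i in range(6)]
        dm = euclid_dm(ids, rng.normal(size=(6, 2)))
        res = mantel(dm, dm, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exhaustive_p_matches_enumeration(self, rng):
        ids = list("abcd")
        dm1 = euclid_dm(ids, rng.normal(size=(4, 2)))
        dm2 = euclid_dm(ids, rng.normal(size=(4, 2)))
        res = mantel(dm1, dm2, method="spearman", n_perm=10**6, seed=0)
        assert res.exhaustive and res.n_permutations == 24

        v1 = rankdata(dm1.condensed())
        iu = np.triu_indices(4, 1)

        def corr(p):
            v2 = rankdata(dm2.data[np.ix_(p, p)][iu])
            return np.corrcoef(v1, v2)[0, 1]

        r_obs = corr(list(range(4)))
        hits = sum(
            1 for p in itertools.permutations(range(4))
            if corr(list(p)) >= r_obs - 1e-12
        )
        assert res.r == pytest.approx(r_obs, abs=1e-12)
        assert res.p_value == pytest.approx(hits / 24)

    def test_spearman_equals_pearson_on_ranks(self, rng):
        ids = [f"s{i}" for i in range(7)]
        dm1 = euclid_dm(ids, rng.normal(size=(7, 2)))
        dm2 = euclid_dm(ids, rng.normal(size=(7, 2)))
        r_sp = mantel(dm1, dm2, method="spearman", n_perm=9, seed=0).r
        rank_mat = lambda dm: DistanceMatrix(
            ids,
            _square(rankdata(dm.condensed()), 7),
        )
        r_pe = mantel(rank_mat(dm1), rank_mat(dm2), method="pearson",
                      n_perm=9, seed=0).r
        assert r_sp == pytest.approx(r_pe, abs=1e-12)

    def test_constant_matrix_rejected(self):
        ids = list("abcd")
        dm1 = DistanceMatrix(ids, np.ones((4, 4)) - np.eye(4))
        dm2 = euclid_dm(ids, np.arange(4.0))
        with pytest.raises(ValueError):
            mantel(dm1, dm2, n_perm=9)

    def test_small_n_rejected(self, rng):
        ids = list("abc")
        dm = euclid_dm(ids, rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            mantel(dm, dm, n_perm=9)


def _square(vals, n):
    m = np.zeros((n, n))
    m[np.triu_indices(n, 1)] = vals
    return m + m.T


class TestPartialMantel:
    def test_control_equal_to_target_is_undefined(self, rng):
        ids = [f"s{i}" for i in range(8)]
        dm_a = euclid_dm(ids, rng.normal(size=(8, 2)))
        dm_b = euclid_dm(ids, rng.normal(size=(8, 2)))
        with pytest.raises(ValueError):
            partial_mantel(dm_a, dm_b, dm_b, n_perm=9, seed=0)

    def test_strong_control_removes_planted_signal(self):
        # A correlates with B only through C; controlling C empties the signal
        rng = np.random.default_rng(17)
        rs = []
        for _ in range(20):
            ids = [f"s{i}" for i in range(12)]
            latent = rng.normal(size=(12, 1))
            dm_a = euclid_dm(ids, latent + rng.normal(0, 0.3, (12, 1)))
            dm_b = euclid_dm(ids, latent + rng.normal(0, 0.3, (12, 1)))
            dm_c = euclid_dm(ids, latent)
            simple = mantel(dm_a, dm_b, n_perm=9, seed=0).r
            part = partial_mantel(dm_a, dm_b, dm_c, n_perm=9, seed=0).r
            rs.append((simple, part))
        simple_mean = np.mean([s for s, _ in rs])
        partial_mean = np.mean([p for _, p in rs])
        assert simple_mean > 0.5
        assert abs(partial_mean) < 0.25

    def test_identical_targets_independent_control(self, rng):
        ids = [f"s{i}" for i in range(8)]
        dm_a = euclid_dm(ids, rng.normal(size=(8, 2)))
        dm_c = euclid_dm(ids, rng.normal(size=(8, 2)))
        res = partial_mantel(dm_a, dm_a, dm_c, n_perm=9, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-6)

    def test_reduces_to_simple_mantel_without_control_signal(self):
        rng = np.random.default_rng(0)
        diffs = []
        for _ in range(20):
            ids = [f"s{i}" for i in range(10)]
            x = rng.normal(size=(10, 1))
            dm_a = euclid_dm(ids, x + rng.normal(0, 0.5, size=(10, 1)))
            dm_b = euclid_dm(ids, x + rng.normal(0, 0.5, size=(10, 1)))
            dm_c = euclid_dm(ids, rng.normal(size=(10, 1)))
            simple = mantel(dm_a, dm_b, n_perm=9, seed=1).r
            partial = partial_mantel(dm_a, dm_b, dm_c, n_perm=9, seed=1).r
            diffs.append(abs(simple - partial))
        assert np.mean(diffs) < 0.1


class TestEnvDistance:
    def test_hand_values_scaled(self):
        ids = list("abc")
        meta = meta_from(ids, TOC=[0.0, 1.0, 3.0])
        dm = env_distance(meta, "TOC")
        sd = np.std([0, 1, 3], ddof=1)
        assert dm.data[0, 1] == pytest.approx(1 / sd)
        assert dm.data[0, 2] == pytest.approx(3 / sd)
        assert dm.data[1, 2] == pytest.approx(2 / sd)

    def test_constant_factor_zero_matrix(self):
        meta = meta_from(list("abc"), TOC=[2.0, 2.0, 2.0])
        dm = env_distance(meta, "TOC")
        assert (dm.data == 0).all()

    def test_affine_invariance(self):
        ids = list("abcd")
        vals = [1.0, 4.0, 2.0, 9.0]
        m1 = env_distance(meta_from(ids, TOC=vals), "TOC")
        m2 = env_distance(
            meta_from(ids, TOC=[5 * v - 3 for v in vals]), "TOC"
        )
        np.testing.assert_allclose(m1.data, m2.data, atol=1e-12)


class TestVpa:
    def test_empty_set2_collapses(self, rng):
        y = rng.normal(size=(30, 5))
        x1 = rng.normal(size=(30, 2))
        res = vpa_two_sets(y, x1, np.empty((30, 0)), transform="none")
        assert res.b == 0.0 and res.c == 0.0
        assert res.a == pytest.approx(max(res.raw["adj_set1"], 0.0))

    def test_perfect_fit_orthogonal_sets(self, rng):
        n = 40
        x1 = rng.normal(size=(n, 2))
        x2 = rng.normal(size=(n, 2))
        y = x1 @ rng.normal(size=(2, 6))  # exactly linear in set1
        res = vpa_two_sets(y, x1, x2, transform="none")
        assert res.raw["d"] == pytest.approx(0.0, abs=1e-9)
        assert res.c == pytest.approx(0.0, abs=0.05)

    def test_raw_fractions_sum_to_one(self, rng):
        y = rng.normal(size=(25, 4))
        x1 = rng.normal(size=(25, 3))
        x2 = rng.normal(size=(25, 2))
        res = vpa_two_sets(y, x1, x2, transform="none")
        total = sum(res.raw[k] for k in "abcd")
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_swapping_sets(self, rng):
        y = rng.normal(size=(25, 4))
        x1 = rng.normal(size=(25, 3))
        x2 = rng.normal(size=(25, 2))
        r12 = vpa_two_sets(y, x1, x2, transform="none")
        r21 = vpa_two_sets(y, x2, x1, transform="none")
        assert r12.raw["a"] == pytest.approx(r21.raw["c"], abs=1e-12)
        assert r12.raw["b"] == pytest.approx(r21.raw["b"], abs=1e-12)
        assert r12.raw["d"] == pytest.approx(r21.raw["d"], abs=1e-12)

    def test_collinear_predictors_rejected(self, rng):
        y = rng.normal(size=(20, 3))
        x = rng.normal(size=(20, 1))
        x1 = np.hstack([x, 2 * x])
        with pytest.raises(ValueError):
            vpa_two_sets(y, x1, rng.normal(size=(20, 2)), transform="none")

    def test_hellinger_on_counts(self, rng):
        from asvkit.core_io import AsvTable

        counts = rng.integers(1, 50, size=(8, 6))
        table = AsvTable([f"s{i}" for i in range(8)],
                         [f"t{j}" for j in range(6)], counts)
        res = vpa_two_sets(
            table, rng.normal(size=(8, 1)), rng.normal(size=(8, 1))
        )
        assert sum(res.raw[k] for k in "abcd") == pytest.approx(1.0, abs=1e-12)


class TestWilcoxon:
    def test_identical_multisets_p_one(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_one_sided_hand_example(self):
        w, p = wilcoxon_rank_sum([1, 2], [3, 4], alternative="less")
        assert p == pytest.approx(1 / 6)

    def test_two_sided_extreme(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(2 / 6)

    def test_monotone_transform_invariance(self):
        x = [1.0, 5.0, 2.0, 8.0]
        y = [3.0, 9.0, 4.0, 7.0]
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2)

    def test_normal_approx_matches_scipy(self, rng):
        from scipy.stats import mannwhitneyu

        x = rng.normal(0, 1, 20)
        y = rng.normal(0.8, 1, 25)
        w, p = wilcoxon_rank_sum(x, y)
        sp = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                          use_continuity=False)
        assert p == pytest.approx(sp.pvalue, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestKruskal:
    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([[2, 2], [2, 2]])
        assert h == 0.0 and p == 1.0

    def test_perfect_ordering_hand_value(self):
        # H = 12/(n(n+1)) * sum n_g (rbar_g - rbar)^2 = 32/7 for (1,2)(3,4)(5,6)
        h, p = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(32 / 7)

    def test_monotone_transform_invariance(self):
        g1, g2 = [1.0, 3.0, 2.0], [5.0, 4.0, 9.0]
        h1, _ = kruskal_wallis([g1, g2])
        h2, _ = kruskal_wallis([np.log(g1), np.log(g2)])
        assert h1 == pytest.approx(h2)

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2]])
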