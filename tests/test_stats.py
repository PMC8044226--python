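"""Permutation inference, FDR, spin tests, stratification, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gradsim import stats as st
from gradsim import synthetic_cohort as syn


class TestResidualize:
    def test_orthogonal_covariate_only_demeans(self):
        y = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        cov = np.array([[1.0], [1.0], [-1.0], [-1.0]])  # orthogonal to y
        out = st.residualize(y, cov)
        np.testing.assert_allclose(out, y - y.mean(), atol=1e-12)

    def test_exact_linear_relation_gives_zero(self):
        rng = np.random.default_rng(0)
        cov = rng.normal(size=(10, 2))
        y = cov @ np.array([[2.0], [-1.0]]) + 3.0
        out = st.residualize(y, cov)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_toy_matches_normal_equations_oracle(self):
        y = np.array([[1.0], [2.0], [4.0], [8.0]])
        cov = np.array([[0.0], [1.0], [2.0], [3.0]])
        X = np.column_stack([np.ones(4), cov[:, 0]])
        beta = np.linalg.inv(X.T @ X) @ X.T @ y
        np.testing.assert_allclose(st.residualize(y, cov), y - X @ beta, atol=1e-12)

    def test_rank_deficient_rejected(self):
        with pytest.raises(st.StatsError):
            st.residualize(np.ones((4, 1)), np.ones((4, 1)))  # duplicate of intercept


class TestHotelling:
    def test_identical_groups_zero(self):
        g = np.random.default_rng(0).normal(size=(5, 3))
        assert st.hotelling_t2(g, g) == pytest.approx(0.0, abs=1e-10)

    def test_univariate_equals_squared_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(8, 1)), rng.normal(1.0, 1.0, size=(10, 1))
        t, _ = sps.ttest_ind(a[:, 0], b[:, 0], equal_var=True)
        assert st.hotelling_t2(a, b) == pytest.approx(t**2, rel=1e-10)

    def test_trivariate_matches_matrix_oracle(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(7, 3)), rng.normal(0.5, 1.0, size=(9, 3))
        na, nb = 7, 9
        diff = a.mean(0) - b.mean(0)
        sp = ((na - 1) * np.cov(a.T) + (nb - 1) * np.cov(b.T)) / (na + nb - 2)
        expected = na * nb / (na + nb) * diff @ np.linalg.inv(sp) @ diff
        assert st.hotelling_t2(a, b) == pytest.approx(expected, rel=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(10, 3)), rng.normal(0.3, 1.2, size=(12, 3))
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        shift = rng.normal(size=3)
        t1 = st.hotelling_t2(a, b)
        t2 = st.hotelling_t2(a @ A + shift, b @ A + shift)
        assert t1 == pytest.approx(t2, rel=1e-8)

    def test_map_version_matches_scalar(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(12, 5, 3))
        labels = np.array([0] * 6 + [1] * 6)
        t_map = st.hotelling_t2_map(data, labels)
        for u in range(5):
            expected = st.hotelling_t2(data[:6, u], data[6:, u])
            assert t_map[u] == pytest.approx(expected, rel=1e-6)


class TestFdrBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(st.fdr_bh([0.03]), [0.03])

    def test_stepup_hand_computation(self):
        np.testing.assert_allclose(st.fdr_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        np.testing.assert_allclose(st.fdr_bh([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_bruteforce_stepup_oracle(self):
        def oracle(p):
            p = np.asarray(p, dtype=float)
            m = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                idx = order[rank - 1]
                running = min(running, p[idx] * m / rank)
                adj[idx] = running
            return adj

        grid = [0.001, 0.01, 0.04, 0.2, 0.5, 1.0]
        rng = np.random.default_rng(0)
        for length in range(1, 9):
            for _ in range(30):
                p = rng.choice(grid, size=length)
                np.testing.assert_allclose(st.fdr_bh(p), oracle(p), atol=1e-12)


class TestPermutationTest:
    def test_separated_groups_at_floor(self):
        data = np.concatenate([np.zeros(6), np.ones(6)])[:, None, None]
        data = np.tile(data, (1, 1, 3))
        data += np.random.default_rng(0).normal(0, 0.01, data.shape)
        labels = np.array([0] * 6 + [1] * 6)

        def stat(lab):
            return st.hotelling_t2_map(data, lab)

        _, p = st.permutation_group_test(stat, labels, n_perm=99, seed=1)
        assert p[0] == pytest.approx(1 / 100)

    def test_p_never_zero_and_bounded(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(10, 4, 3))
        labels = np.array([0] * 5 + [1] * 5)

        def stat(lab):
            return st.hotelling_t2_map(data, lab)

        _, p = st.permutation_group_test(stat, labels, n_perm=49, seed=2)
        assert np.all(p >= 1 / 50) and np.all(p <= 1.0)


class TestSpinTest:
    def test_reassignment_stays_within_hemisphere(self, atlas100):
        # rotations are rigid (distance-preserving), so sources for left
        # parcels must themselves be left parcels, and likewise on the right
        spin = st.spin_rotations(atlas100, n_rot=5, seed=0)
        hemi = np.asarray(atlas100.table["hemisphere"])
        left = np.flatnonzero(hemi == "L")
        right = np.flatnonzero(hemi == "R")
        for row in spin.reassignment:
            assert set(row[left]).issubset(set(left))
            assert set(row[right]).issubset(set(right))

    def test_identity_reassignment_preserves_map(self, atlas100):
        rng = np.random.default_rng(0)
        m = rng.normal(size=atlas100.n_parcels)
        spin = st.SpinNull(n_rotations=1,
                           reassignment=np.arange(atlas100.n_parcels)[None, :])
        r, p = st.spin_test(m, m, atlas100, precomputed=spin)
        assert r == pytest.approx(1.0)

    def test_self_correlation_significant(self, atlas100):
        # a smooth map correlates with itself far better than with rotations
        m = atlas100.centroids[:, 2] + 0.1 * np.random.default_rng(1).normal(
            size=atlas100.n_parcels)
        r, p = st.spin_test(m, m, atlas100, n_rot=199, seed=3)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_calibration_for_independent_smooth_maps(self, atlas100):
        # p approximately uniform across independent smooth map pairs drawn
        # from the null's own exchangeability class: one map is an
        # independent smooth field passed through a random mirrored-rotation
        # reassignment, exactly the transformation family the null explores
        rng = np.random.default_rng(1)
        spin = st.spin_rotations(atlas100, n_rot=499, seed=101)
        cent = atlas100.centroids
        n = atlas100.n_parcels

        def smooth_field(rng):
            d = rng.normal(size=3)
            us = rng.normal(size=(3, 3))
            a = rng.normal(size=3)
            return lambda c: c @ d + (a * (c @ us.T) ** 2).sum(axis=1)

        pvals = []
        for _ in range(200):
            m1 = smooth_field(rng)(cent) + 0.3 * rng.normal(size=n)
            base = smooth_field(rng)(cent) + 0.3 * rng.normal(size=n)
            rot1 = st.spin_rotations(atlas100, n_rot=1,
                                     seed=int(rng.integers(2**31 - 1)))
            m2 = base[rot1.reassignment[0]]
            pvals.append(st.spin_test(m1, m2, atlas100, precomputed=spin)[1])
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestStratification:
    def test_constant_map(self):
        out = st.stratify_by_labels(np.ones(6), ["a", "a", "b", "b", "c", "c"])
        assert (out["mean"] == 1.0).all()
        assert (out["count"] == 2).all()

    def test_toy_means(self):
        out = st.stratify_by_labels(np.array([1.0, 3.0, 10.0]), ["a", "a", "b"])
        assert out.loc["a", "mean"] == pytest.approx(2.0)
        assert out.loc["b", "mean"] == pytest.approx(10.0)


class TestAsymmetry:
    def test_symmetric_map_zero(self, atlas20):
        n_l = atlas20.n_parcels // 2
        vals = np.concatenate([np.arange(1.0, n_l + 1), np.arange(1.0, n_l + 1)])
        out = st.hemispheric_asymmetry(vals, atlas20)
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-12)

    def test_forced_49_percent(self, atlas20):
        n_l = atlas20.n_parcels // 2
        base = np.full(n_l, 2.0)
        vals = np.concatenate([base, 1.49 * base])
        out = st.hemispheric_asymmetry(vals, atlas20)
        np.testing.assert_allclose(out.to_numpy(), 49.0, atol=1e-9)

    def test_toy_hand_computation(self, atlas20):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=atlas20.n_parcels)
        labels = np.asarray(atlas20.table["hierarchy"])
        hemi = np.asarray(atlas20.table["hemisphere"])
        out = st.hemispheric_asymmetry(vals, atlas20)
        for lab in pd.unique(labels):
            left = np.abs(vals[(labels == lab) & (hemi == "L")]).mean()
            right = np.abs(vals[(labels == lab) & (hemi == "R")]).mean()
            assert out[lab] == pytest.approx(100 * (right - left) / left)


class TestEdgeGroupTest:
    def _cohort(self, subj_seed, n_subj=8, boost_edges=None, factor=1.0, base_seed=0):
        rng = np.random.default_rng(subj_seed + 1000)
        n = 10
        iu = np.triu_indices(n, k=1)
        base = np.random.default_rng(base_seed).lognormal(1.0, 0.3, len(iu[0]))
        subs = []
        for _ in range(n_subj):
            vals = base * rng.lognormal(0.0, 0.2, len(base))
            if boost_edges is not None:
                vals[boost_edges] = vals[boost_edges] * factor
            w = np.zeros((n, n))
            w[iu] = vals
            subs.append(w + w.T)
        return subs, iu

    def test_t_antisymmetric_under_group_swap(self):
        a, iu = self._cohort(0)
        b, _ = self._cohort(1)
        mask = np.ones((10, 10), bool)
        np.fill_diagonal(mask, False)
        r1 = st.edge_group_test(a, b, mask=mask, n_perm=49, seed=0)
        r2 = st.edge_group_test(b, a, mask=mask, n_perm=49, seed=0)
        np.testing.assert_allclose(r1.t, -r2.t, atol=1e-10)

    def test_null_has_no_discoveries(self):
        a, _ = self._cohort(2, n_subj=10)
        b, _ = self._cohort(3, n_subj=10)
        mask = np.ones((10, 10), bool)
        r = st.edge_group_test(a, b, mask=mask, n_perm=199, seed=1)
        assert len(r.increased) + len(r.decreased) <= max(2, int(0.05 * len(r.t)))

    def test_planted_effect_detected(self):
        boost = np.arange(10)
        a, _ = self._cohort(4, n_subj=25, boost_edges=boost, factor=2.0)
        b, _ = self._cohort(4, n_subj=25)
        mask = np.ones((10, 10), bool)
        r = st.edge_group_test(a, b, mask=mask, n_perm=499, seed=2)
        detected = np.intersect1d(r.increased, boost)
        assert len(detected) >= 8


class TestTractLengthContrast:
    def test_means_and_floor(self):
        # fully separated sets large enough that no permutation ties the split
        dec = np.linspace(28.0, 34.0, 8)
        inc = np.linspace(5.0, 8.0, 8)
        m_dec, m_inc, p = st.tract_length_contrast(dec, inc, n_perm=99, seed=0)
        assert m_dec == pytest.approx(dec.mean())
        assert m_inc == pytest.approx(inc.mean())
        assert p == pytest.approx(1 / 100)

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(1)
        pool = rng.uniform(10, 20, 40)
        _, _, p = st.tract_length_contrast(pool[:20], pool[20:], n_perm=199, seed=2)
        assert p > 0.05

    def test_empty_set_rejected(self):
        with pytest.raises(st.StatsError):
            st.tract_length_contrast([], [1.0], n_perm=10, seed=0)


class TestOverlapRatio:
    def test_disjoint_and_subset(self):
        sets = {"a": {"g1", "g2"}, "b": {"g9", "g10"}}
        universe = {f"g{i}" for i in range(1, 11)}
        out = st.overlap_ratio_test(["g1", "g2"], sets, universe, n_perm=49, seed=0)
        out = out.set_index("celltype")
        assert out.loc["a", "overlap_ratio"] == pytest.approx(100.0)
        assert out.loc["b", "overlap_ratio"] == pytest.approx(0.0)

    def test_tiny_case_against_exhaustive_null(self):
        universe = [f"g{i}" for i in range(8)]
        gene_list = ["g0", "g1", "g2"]
        sets = {"x": {"g0", "g1"}, "y": {"g4", "g5"}}
        pool = sorted({"g0", "g1", "g4", "g5"})
        out = st.overlap_ratio_test(gene_list, sets, universe, n_perm=999, seed=1)
        row = out.set_index("celltype").loc["x"]
        assert row["overlap_ratio"] == pytest.approx(100.0)
        # exhaustive null: all 2-subsets of the pooled cell-type genes
        ratios = []
        for comb in itertools.combinations(pool, 2):
            ratios.append(100 * len(set(comb) & set(gene_list)) / 2)
        exact_exceed = np.mean([r >= 100.0 for r in ratios])
        # permutation p approximates the exhaustive tail probability
        assert row["p"] == pytest.approx((1 + 999 * exact_exceed) / 1000, abs=0.05)


class TestWeightedManifoldGroupTest:
    def test_null_and_planted_effect(self):
        rng = np.random.default_rng(42)
        n_subj, n_parcel = 12, 15
        seeds = ["thalamus", "caudate", "cerebellum"]
        wms_a = {s: rng.normal(size=(n_subj, n_parcel, 3)) for s in seeds}
        wms_b = {s: rng.normal(size=(n_subj, n_parcel, 3)) for s in seeds}
        wms_b["thalamus"] = wms_b["thalamus"] + 1.5  # planted seed-specific shift
        out = st.weighted_manifold_group_test(wms_a, wms_b, n_perm=199, seed=1)
        out = out.set_index("seed")
        assert out.loc["thalamus", "q"] < 0.05
        assert out.loc["thalamus", "p"] == out["p"].min()
        assert np.median(out.drop("thalamus")["p"]) > 0.1
        assert (out["p"] >= 1 / 200).all()
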