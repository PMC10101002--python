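import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from fermnet import (
    AbundanceTable,
    DissimilarityMatrix,
    SampleMetadata,
    TableError,
    bh_adjust,
    differential_enrichment,
    dissimilarity,
    filter_taxa,
    mantel,
    pcoa,
    permanova,
    shannon_index,
)


def _table(matrix, samples=None):
    matrix = np.asarray(matrix, dtype=float)
    idx = [f"t{i}" for i in range(matrix.shape[0])]
    cols = samples or [f"s{j}" for j in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, index=idx, columns=cols)
    return AbundanceTable(df, pd.Series("bacteria", index=idx), False)


class TestFilterTaxa:
    def test_strict_prevalence_boundary(self):
        # 5/24 samples = 0.2083 > 0.20 -> retained
        m = np.zeros((1, 24))
        m[0, :5] = 1.0
        t = _table(np.vstack([m, np.ones((1, 24))]))
        kept = filter_taxa(t, min_prevalence=0.20, min_mean_ra=0.0)
        assert "t0" in kept.taxa_ids

    def test_mean_ra_exactly_at_threshold_removed(self):
        # taxon 0 mean RA exactly 0.25 (strict > removes it at that cut)
        m = np.array([[1.0] * 10, [3.0] * 10])
        t = _table(m)
        kept = filter_taxa(t, min_prevalence=0.0, min_mean_ra=0.25)
        assert kept.taxa_ids == ["t1"]

    def test_matches_two_pass_recount_on_synthetic_fixture(self, default_dataset):
        from fermnet import merge_domains
        t = merge_domains(default_dataset.bacteria, default_dataset.fungi)
        kept = filter_taxa(t)
        # independent brute-force re-count
        ra = t.relative_abundance()
        expected = []
        for taxon in t.taxa_ids:
            prev = (t.counts.loc[taxon] > 0).sum() / t.n_samples
            if prev > 0.20 and ra.loc[taxon].mean() > 1e-4:
                expected.append(taxon)
        assert kept.taxa_ids == expected

    def test_all_filtered_is_an_error(self):
        t = _table(np.ones((2, 4)))
        with pytest.raises(TableError, match="relax"):
            filter_taxa(t, min_prevalence=1.0)


class TestShannon:
    def test_uniform_gives_log_n(self):
        t = _table(np.full((4, 1), 5.0))
        assert shannon_index(t, "s0") == pytest.approx(np.log(4), abs=1e-12)

    def test_single_taxon_gives_zero(self):
        t = _table([[7.0], [0.0], [0.0]])
        assert shannon_index(t, "s0") == 0.0

    def test_matches_direct_summation(self, rng):
        v = rng.random(10) + 0.01
        t = _table(v.reshape(-1, 1))
        p = v / v.sum()
        assert shannon_index(t, "s0") == pytest.approx(
            -(p * np.log(p)).sum(), abs=1e-12)

    def test_zero_subset_warns_and_returns_zero(self):
        t = _table([[0.0, 1.0], [5.0, 1.0]])
        with pytest.warns(UserWarning):
            assert shannon_index(t, "s0", ["t0"]) == 0.0

    def test_uniform_maximizes_over_random_compositions(self, rng):
        n = 6
        h_max = np.log(n)
        for _ in range(50):
            p = rng.dirichlet(np.ones(n))
            h = -(p[p > 0] * np.log(p[p > 0])).sum()
            assert h <= h_max + 1e-12


class TestDissimilarity:
    def test_identical_columns_zero(self):
        t = _table([[1.0, 1.0], [2.0, 2.0]])
        for metric in ("bray", "jaccard"):
            D = dissimilarity(t, metric)
            assert D.D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_one(self):
        t = _table([[1.0, 0.0], [0.0, 2.0]])
        for metric in ("bray", "jaccard"):
            assert dissimilarity(t, metric).D[0, 1] == pytest.approx(1.0)

    def test_bray_hand_value(self):
        # x=(1,1,0), y=(0,1,1): relative abundances make both sum to 1;
        # use raw vectors via a relative table to keep the hand value
        df = pd.DataFrame({"s1": [1, 1, 0], "s2": [0, 1, 1]},
                          index=["a", "b", "c"], dtype=float)
        t = AbundanceTable(df / df.sum(), pd.Series("bacteria", index=df.index),
                           True)
        # Bray = sum|x-y| / sum(x+y) on the normalized vectors
        x, y = (df / df.sum())["s1"], (df / df.sum())["s2"]
        expected = np.abs(x - y).sum() / (x + y).sum()
        assert dissimilarity(t, "bray").D[0, 1] == pytest.approx(expected)
        assert expected == pytest.approx(0.5)

    def test_ruzicka_hand_value(self):
        df = pd.DataFrame({"s1": [0.5, 0.5, 0.0], "s2": [0.0, 0.5, 0.5]},
                          index=["a", "b", "c"])
        t = AbundanceTable(df, pd.Series("bacteria", index=df.index), True)
        # 1 - sum(min)/sum(max) = 1 - 0.5/1.5
        assert dissimilarity(t, "jaccard").D[0, 1] == pytest.approx(2 / 3)

    def test_all_zero_sample_is_error(self):
        t = _table([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(TableError, match="zero"):
            dissimilarity(t)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_metric_properties_on_random_vectors(self, seed):
        r = np.random.default_rng(seed)
        X = r.random((4, 6)) * r.integers(0, 2, (4, 6))
        X[X.sum(axis=1) == 0, 0] = 0.5  # avoid empty samples
        t = _table(X.T)
        for metric in ("bray", "jaccard"):
            for weighted in (True, False):
                D = dissimilarity(t, metric, weighted).D
                assert np.allclose(D, D.T)
                assert np.allclose(np.diag(D), 0)
                assert (D >= -1e-12).all() and (D <= 1 + 1e-12).all()


class TestPcoa:
    def test_collinear_points_recovered_on_axis_one(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        D = DissimilarityMatrix(
            ["a", "b", "c"],
            squareform(pdist(pts)) / 10.0)  # scale into [0,1]
        res = pcoa(D, k=1)
        c = res.coordinates["PCo1"].to_numpy()
        got = np.abs(c[:, None] - c[None, :])
        assert np.allclose(got, D.D, atol=1e-10)

    def test_zero_matrix_gives_zero_coordinates(self):
        D = DissimilarityMatrix(["a", "b", "c"], np.zeros((3, 3)))
        with pytest.warns(UserWarning):
            res = pcoa(D, k=2)
        assert np.allclose(res.coordinates.to_numpy(), 0.0)

    def test_euclidean_cloud_distances_reconstructed(self, rng):
        pts = rng.random((7, 3))
        D = DissimilarityMatrix([f"s{i}" for i in range(7)],
                                squareform(pdist(pts)) / 5.0)
        res = pcoa(D, k=6)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rec, D.D, atol=1e-8)


class TestPermanova:
    def _random_D(self, rng, n=12):
        X = rng.lognormal(0, 1, (n, 20))
        return DissimilarityMatrix(
            [f"s{i}" for i in range(n)],
            squareform(pdist(X / X.sum(1, keepdims=True), "braycurtis")))

    def test_r2_values_sum_to_one(self, rng):
        D = self._random_D(rng)
        res = permanova(D, {"a": list("xxxyyyxxxyyy"),
                            "b": list("uuuuuuvvvvvv")}, n_perm=49, seed=0)
        assert res["R2"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_exhaustive_p_matches_brute_force(self, rng):
        X = rng.random((4, 6))
        D = DissimilarityMatrix(list("abcd"),
                                squareform(pdist(X, "braycurtis")))
        labels = ["g1", "g1", "g2", "g2"]
        res = permanova(D, labels, exhaustive=True)

        def f_stat(Dm, labs):
            n = len(labs)
            G = (np.eye(n) - 1 / n) @ (-0.5 * Dm ** 2) @ (np.eye(n) - 1 / n)
            Xd = pd.get_dummies(pd.Series(labs)).to_numpy(float)
            Xf = np.hstack([np.ones((n, 1)), Xd])
            Q, _ = np.linalg.qr(Xf)
            r = np.linalg.matrix_rank(Xf)
            H = Q[:, :r] @ Q[:, :r].T
            H0 = np.ones((n, n)) / n
            ssb = np.trace((H - H0) @ G)
            ssw = np.trace((np.eye(n) - H) @ G)
            return ssb / (ssw / (n - 2))

        f_obs = f_stat(D.D, labels)
        count = sum(
            f_stat(D.D[np.ix_(p, p)], labels) >= f_obs - 1e-12
            for p in itertools.permutations(range(4)))
        assert res.loc["factor", "p"] == pytest.approx(count / 24)

    def test_separated_clusters_reach_minimum_p(self, rng):
        X = np.vstack([rng.normal(0, 0.01, (6, 4)),
                       rng.normal(10, 0.01, (6, 4))])
        D = squareform(pdist(X))
        D = D / D.max()
        res = permanova(DissimilarityMatrix([f"s{i}" for i in range(12)], D),
                        ["a"] * 6 + ["b"] * 6, n_perm=99, seed=1)
        assert res.loc["factor", "p"] == pytest.approx(1 / 100)

    def test_matches_skbio_statistic(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova
        D = self._random_D(rng, n=10)
        labels = ["a"] * 5 + ["b"] * 5
        ours = permanova(D, labels, n_perm=9, seed=0)
        sk = sk_permanova(DistanceMatrix(D.D, D.sample_ids), grouping=labels,
                          permutations=9)
        assert ours.loc["factor", "F"] == pytest.approx(
            sk["test statistic"], rel=1e-10)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        X = rng.random((6, 4))
        D = DissimilarityMatrix([f"s{i}" for i in range(6)],
                                squareform(pdist(X)) / 10)
        assert mantel(D, D, n_perm=9, seed=0)["r"] == pytest.approx(1.0)

    def test_exhaustive_p_matches_enumeration(self, rng):
        X1, X2 = rng.random((4, 5)), rng.random((4, 5))
        D1 = DissimilarityMatrix(list("abcd"), squareform(pdist(X1)) / 10)
        D2 = DissimilarityMatrix(list("abcd"), squareform(pdist(X2)) / 10)
        res = mantel(D1, D2, exhaustive=True)
        iu = np.triu_indices(4, 1)
        r_obs = np.corrcoef(D1.D[iu], D2.D[iu])[0, 1]
        count = sum(
            abs(np.corrcoef(D1.D[iu], D2.D[np.ix_(p, p)][iu])[0, 1])
            >= abs(r_obs) - 1e-12
            for p in itertools.permutations(range(4)))
        assert res["p"] == pytest.approx(count / 24)
        assert res["r"] == pytest.approx(r_obs)

    def test_size_mismatch_is_error(self, rng):
        D1 = DissimilarityMatrix(list("abc"), np.zeros((3, 3)))
        D2 = DissimilarityMatrix(list("abcd"), np.zeros((4, 4)))
        with pytest.raises(TableError):
            mantel(D1, D2)


class TestBhAdjust:
    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 40))
    @settings(max_examples=30, deadline=None)
    def test_matches_step_up_definition(self, seed, n):
        p = np.random.default_rng(seed).random(n)
        got = bh_adjust(p)
        # brute-force BH step-up
        order = np.argsort(p)
        ranked = p[order] * n / (np.arange(n) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(adj, 1.0)
        assert np.allclose(got, expected, atol=1e-12)
        assert (got >= p - 1e-15).all()


class TestDifferentialEnrichment:
    def _meta(self, samples, groups):
        return SampleMetadata(pd.DataFrame({"group": groups}, index=samples))

    def test_clean_separation_is_detected(self, rng):
        n = 24
        base = rng.lognormal(0, 0.2, (10, 2 * n))
        base[0, n:] += 50.0  # taxon t0 much higher in group B
        t = _table(base)
        meta = self._meta(t.sample_ids, ["A"] * n + ["B"] * n)
        res = differential_enrichment(t, meta)
        assert res.loc["t0", "enriched_in"] == "B"

    def test_dominance_threshold_is_strict(self):
        m = np.vstack([np.full(6, 1.0), np.full(6, 999.0)])
        t = _table(m)
        meta = self._meta(t.sample_ids, ["A"] * 3 + ["B"] * 3)
        res = differential_enrichment(t, meta, dominance_ra=1e-3)
        assert not res.loc["t0", "dominant"]  # mean RA exactly 1e-3
        assert res.loc["t1", "dominant"]

    def test_small_group_is_error(self, tiny_table):
        meta = self._meta(tiny_table.sample_ids, ["A", "A", "B"])
        with pytest.raises(TableError, match="3 samples"):
            differential_enrichment(tiny_table, meta)

    def test_adjusted_p_never_below_raw(self, rng):
        t = _table(rng.lognormal(0, 1, (15, 12)))
        meta = self._meta(t.sample_ids, ["A"] * 6 + ["B"] * 6)
        res = differential_enrichment(t, meta)
        assert (res["p_adj"] >= res["p"] - 1e-15).all()
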