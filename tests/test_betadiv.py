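import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from plankton_assembly import (
    CommunityTable, DistanceMatrix, PhyloTree, beta_mntd_matrix,
    bray_curtis_matrix, decompose_beta, distance_decay, mantel_correlogram,
    mantel_test, niche_distance, niche_values, shannon, similarity_from,
    simulate_traits_bm, simulate_tree,
)


def table_from(rows, ids=None):
    arr = np.atleast_2d(np.asarray(rows))
    ids = ids or [f"S{i+1}" for i in range(arr.shape[0])]
    cols = [f"A{j+1}" for j in range(arr.shape[1])]
    return CommunityTable(pd.DataFrame(arr, index=ids, columns=cols))


class TestShannon:
    def test_even_two_taxa_is_ln2(self):
        assert shannon(table_from([[50, 50]]))["S1"] == pytest.approx(
            np.log(2))

    def test_single_taxon_is_zero(self):
        assert shannon(table_from([[17, 0, 0]]))["S1"] == 0.0

    def test_matches_direct_summation(self):
        counts = np.array([10, 20, 30, 40])
        q = counts / counts.sum()
        expected = -(q * np.log(q)).sum()
        assert shannon(table_from([counts]))["S1"] == pytest.approx(
            expected, abs=1e-12)

    def test_bounded_by_log_richness(self):
        rng = np.random.default_rng(0)
        t = table_from(rng.integers(1, 100, size=(5, 12)))
        h = shannon(t)
        assert ((h >= 0) & (h <= np.log(12) + 1e-12)).all()


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        bc = bray_curtis_matrix(table_from([[3, 4, 5], [3, 4, 5]]))
        assert bc.values[0, 1] == 0.0

    def test_disjoint_samples_one(self):
        bc = bray_curtis_matrix(table_from([[5, 0], [0, 7]]))
        assert bc.values[0, 1] == pytest.approx(1.0)

    def test_hand_value_on_counts(self):
        bc = bray_curtis_matrix(table_from([[6, 2, 0], [2, 6, 0]]),
                                use_relative=False)
        assert bc.values[0, 1] == pytest.approx(0.5)  # (4+4)/16


class TestBetaMNTD:
    def test_identical_communities_zero(self, cherry_tree):
        t = table_from([[1, 2, 3, 4], [1, 2, 3, 4]])
        t.counts.columns = ["ASV_1", "ASV_2", "ASV_3", "ASV_4"]
        t = CommunityTable(t.counts)
        bm = beta_mntd_matrix(t, cherry_tree)
        assert bm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_single_taxon_samples_equal_patristic(self, cherry_tree):
        counts = pd.DataFrame(
            [[5, 0, 0, 0], [0, 0, 7, 0]], index=["S1", "S2"],
            columns=["ASV_1", "ASV_2", "ASV_3", "ASV_4"])
        bm = beta_mntd_matrix(CommunityTable(counts), cherry_tree)
        d = cherry_tree.patristic_matrix(order=["ASV_1", "ASV_3"]).values
        assert bm.values[0, 1] == pytest.approx(d[0, 1])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for rep in range(5):
            tree = simulate_tree(6, seed=rep)
            labels = tree.tip_labels
            counts = pd.DataFrame(
                rng.integers(0, 10, size=(4, 6)),
                index=[f"S{i}" for i in range(4)], columns=labels)
            counts.iloc[:, 0] += 1  # no empty samples
            table = CommunityTable(counts)
            got = beta_mntd_matrix(table, tree).values
            D = tree.patristic_matrix(order=labels).values
            rel = table.relative_abundance().to_numpy()
            for a in range(4):
                for b in range(4):
                    if a == b:
                        continue
                    ia = np.flatnonzero(rel[a] > 0)
                    ib = np.flatnonzero(rel[b] > 0)
                    one = sum(rel[a][i] * min(D[i, j] for j in ib)
                              for i in ia)
                    two = sum(rel[b][j] * min(D[j, i] for i in ia)
                              for j in ib)
                    assert got[a, b] == pytest.approx(
                        0.5 * (one + two), abs=1e-12)

    def test_never_exceeds_max_patristic(self):
        tree = simulate_tree(20, seed=7)
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 5, size=(6, 20)) + 1,
                              index=[f"S{i}" for i in range(6)],
                              columns=tree.tip_labels)
        bm = beta_mntd_matrix(CommunityTable(counts), tree)
        assert bm.values.max() <= tree.patristic_matrix().values.max()


class TestDecomposition:
    def test_symmetric_replacement_pair(self):
        dec = decompose_beta(table_from([[6, 2, 0], [2, 6, 0]]),
                             use_relative=False)
        row = dec.pairs.iloc[0]
        assert row["D"] == pytest.approx(0.5)
        assert row["Repl"] == pytest.approx(0.5)
        assert row["RichDiff"] == pytest.approx(0.0)

    def test_disjoint_uneven_pair(self):
        dec = decompose_beta(table_from([[5, 0], [0, 3]]),
                             use_relative=False)
        row = dec.pairs.iloc[0]
        assert row["D"] == pytest.approx(1.0)
        assert row["Repl"] == pytest.approx(0.75)  # 2*3/8
        assert row["RichDiff"] == pytest.approx(0.25)  # 2/8

    def test_identical_pair(self):
        dec = decompose_beta(table_from([[4, 4], [4, 4]]))
        row = dec.pairs.iloc[0]
        assert (row["D"], row["Repl"], row["RichDiff"], row["S"]) == \
            (0.0, 0.0, 0.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 100), st.integers(0, 100)),
        min_size=2, max_size=30,
    ).filter(lambda v: any(a for a, _ in v) and any(b for _, b in v)))
    def test_additive_identity_property(self, pairs_counts):
        x = [a for a, _ in pairs_counts]
        y = [b for _, b in pairs_counts]
        table = table_from([x, y])
        dec = decompose_beta(table, use_relative=False)
        row = dec.pairs.iloc[0]
        assert row["D"] == pytest.approx(row["Repl"] + row["RichDiff"],
                                         abs=1e-12)
        assert row["S"] + row["Repl"] + row["RichDiff"] == pytest.approx(
            1.0, abs=1e-12)
        bc = bray_curtis_matrix(table, use_relative=False)
        assert row["D"] == pytest.approx(bc.values[0, 1], abs=1e-12)

    def test_group_summary_repl_share(self, grouped_table):
        dec = decompose_beta(grouped_table)
        assert dec.group_summary is not None
        april = dec.group_summary.set_index("group").loc["April"]
        assert 0 <= april["repl_over_d"] <= 1


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        vals = squareform(rng.uniform(0.1, 1, size=10))
        dm = DistanceMatrix(list("abcde"), vals)
        r, p = mantel_test(dm, dm, n_perm=99, seed=1)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_matches_vectorized_correlation(self):
        rng = np.random.default_rng(5)
        x = squareform(rng.uniform(0.1, 1, size=10))
        y = squareform(rng.uniform(0.1, 1, size=10))
        dm1 = DistanceMatrix(list("abcde"), x)
        dm2 = DistanceMatrix(list("abcde"), y)
        r, _ = mantel_test(dm1, dm2, n_perm=99, seed=2)
        expected = np.corrcoef(dm1.condensed(), dm2.condensed())[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_scikit_bio(self):
        import skbio
        rng = np.random.default_rng(6)
        x = squareform(rng.uniform(0.1, 1, size=45))
        y = squareform(rng.uniform(0.1, 1, size=45))
        ids = [f"o{i}" for i in range(10)]
        r, _ = mantel_test(DistanceMatrix(ids, x), DistanceMatrix(ids, y),
                           n_perm=99, seed=0)
        r_ref, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(x, ids), skbio.DistanceMatrix(y, ids),
            permutations=0)
        assert r == pytest.approx(r_ref, abs=1e-10)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(11)
        hits = 0
        trials = 200
        ids = [f"o{i}" for i in range(12)]
        for _ in range(trials):
            x = squareform(rng.uniform(0.1, 1, size=66))
            y = squareform(rng.uniform(0.1, 1, size=66))
            _, p = mantel_test(DistanceMatrix(ids, x),
                               DistanceMatrix(ids, y),
                               n_perm=99, seed=int(rng.integers(2 ** 31)))
            hits += p <= 0.05
        assert 0.02 <= hits / trials <= 0.09


class TestDistanceDecay:
    def test_constant_similarity_flat(self):
        rng = np.random.default_rng(2)
        geo = DistanceMatrix(list("abcd"),
                             squareform(rng.uniform(1, 100, 6)),
                             "geographic_km")
        sim = DistanceMatrix(list("abcd"), np.zeros((4, 4)), "similarity")
        fit = distance_decay(sim, geo, n_perm=9, seed=0)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_relationship(self):
        rng = np.random.default_rng(3)
        geo_vals = squareform(rng.uniform(10, 500, 15))
        geo = DistanceMatrix([f"s{i}" for i in range(6)], geo_vals,
                             "geographic_km")
        sim_vals = 1 - 0.001 * geo_vals
        np.fill_diagonal(sim_vals, 0)
        sim = DistanceMatrix(geo.ids, sim_vals, "similarity")
        fit = distance_decay(sim, geo, n_perm=99, seed=1)
        assert fit.slope == pytest.approx(-0.001, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


class TestNicheValues:
    def test_single_sample_asv_gets_that_environment(self, toy_env):
        counts = pd.DataFrame([[4, 0], [0, 3], [0, 3]],
                              index=["S1", "S2", "S3"],
                              columns=["A1", "A2"])
        nv = niche_values(CommunityTable(counts), toy_env)
        z = ((toy_env.data - toy_env.data.mean())
             / toy_env.data.std(ddof=0))
        np.testing.assert_allclose(nv.loc["A1"].to_numpy(),
                                   z.loc["S1"].to_numpy(), atol=1e-12)

    def test_uniform_asv_has_zero_niche(self, toy_env):
        counts = pd.DataFrame([[2], [2], [2]], index=["S1", "S2", "S3"],
                              columns=["A1"])
        nv = niche_values(CommunityTable(counts), toy_env)
        np.testing.assert_allclose(nv.loc["A1"].to_numpy(), 0.0,
                                   atol=1e-12)

    def test_weighted_mean_hand_computation(self, toy_env):
        counts = pd.DataFrame([[1], [3], [0]], index=["S1", "S2", "S3"],
                              columns=["A1"])
        nv = niche_values(CommunityTable(counts), toy_env,
                          variables=["temperature"])
        z = ((toy_env.data["temperature"]
              - toy_env.data["temperature"].mean())
             / toy_env.data["temperature"].std(ddof=0))
        expected = (1 * z["S1"] + 3 * z["S2"]) / 4
        assert nv.loc["A1", "temperature"] == pytest.approx(expected,
                                                            abs=1e-12)


class TestCorrelogram:
    def test_block_structure_signs_match_hand_calculation(self):
        # two tight niche blocks mirrored by two phylo blocks: the
        # short-distance class holds the similar pairs, so r > 0 there
        # and r < 0 in the far class
        ids = list("abcd")
        phylo = np.array([[0, 1, 9, 9], [1, 0, 9, 9],
                          [9, 9, 0, 1], [9, 9, 1, 0]], float)
        niche = np.array([[0, .1, 5, 5], [.1, 0, 5, 5],
                          [5, 5, 0, .1], [5, 5, .1, 0]], float)
        res = mantel_correlogram(DistanceMatrix(ids, niche),
                                 DistanceMatrix(ids, phylo),
                                 n_classes=2, n_perm=99, seed=0)
        r = res.classes["mantel_r"].to_numpy()
        assert r[0] > 0 > r[1]

    def test_corrected_p_never_below_raw(self):
        tree = simulate_tree(40, seed=3)
        traits = simulate_traits_bm(tree, 1.0, seed=4)
        ids = list(traits.index)
        nd = DistanceMatrix(
            ids, squareform(pdist(traits.to_numpy()[:, None])))
        res = mantel_correlogram(nd, tree.patristic_matrix(order=ids),
                                 n_perm=99, seed=5)
        tested = res.classes.dropna(subset=["p_raw"])
        assert (tested["p_corrected"] >= tested["p_raw"] - 1e-12).all()

    def test_classes_cover_half_the_range(self):
        tree = simulate_tree(30, seed=6)
        traits = simulate_traits_bm(tree, 1.0, seed=7)
        ids = list(traits.index)
        nd = DistanceMatrix(
            ids, squareform(pdist(traits.to_numpy()[:, None])))
        pdm = tree.patristic_matrix(order=ids)
        res = mantel_correlogram(nd, pdm, n_perm=49, seed=8)
        tested = res.classes.dropna(subset=["mantel_r"])
        assert tested["midpoint"].max() >= 0.5 * pdm.values.max() * 0.5
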