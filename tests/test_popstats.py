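"""Population statistics: PCA, pDFA, Mahalanobis, Mantel, dendrograms."""

import numpy as np
import pytest

from lyresong import features, popstats


def zscaled(rng, n, p):
    X = rng.normal(size=(n, p))
    return (X - X.mean(0)) / X.std(0, ddof=1)


class TestPCA:
    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        X = np.column_stack([x, x])
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        with pytest.warns(UserWarning, match="rank-deficient"):
            res = popstats.pca(X)
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_isotropic_variance_fractions(self):
        rng = np.random.default_rng(1)
        res = popstats.pca(zscaled(rng, 20_000, 4))
        np.testing.assert_allclose(res.variance_fraction, 0.25, atol=0.02)

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(2)
        X = zscaled(rng, 200, 5)
        res = popstats.pca(X)
        np.testing.assert_allclose(res.scores @ res.loadings.T, X, atol=1e-8)

    def test_loadings_orthonormal_and_fractions_sorted(self):
        rng = np.random.default_rng(3)
        res = popstats.pca(zscaled(rng, 150, 6))
        np.testing.assert_allclose(res.loadings.T @ res.loadings, np.eye(6),
                                   atol=1e-8)
        assert np.all(np.diff(res.variance_fraction) <= 1e-12)
        assert res.variance_fraction.sum() <= 1 + 1e-8


class TestRetainComponents:
    @pytest.mark.parametrize("fractions,target,expected", [
        ([0.50, 0.30, 0.15, 0.05], 0.75, 2),
        ([0.40, 0.20, 0.15, 0.15, 0.10], 0.75, 3),
        ([0.60, 0.25, 0.08, 0.07], 0.80, 2),
        ([0.90, 0.05, 0.05], 0.75, 1),
    ])
    def test_rule(self, fractions, target, expected):
        assert popstats.retain_components(fractions, target) == expected

    def test_unreachable_target_warns_and_keeps_eligible(self):
        with pytest.warns(UserWarning, match="cannot reach"):
            n = popstats.retain_components([0.30, 0.20, 0.09, 0.09], 0.75)
        assert n == 2

    def test_empty_eligible_set(self):
        with pytest.raises(ValueError):
            popstats.retain_components([0.05] * 20, 0.75)


def make_groups(rng, n_pops=2, n_indiv=4, n_songs=8, effect=6.0, indiv_sd=0.0,
                p=3):
    X, pops, indivs = [], [], []
    for g in range(n_pops):
        mu = np.zeros(p)
        mu[g % p] = effect * g
        for i in range(n_indiv):
            delta = rng.normal(0, indiv_sd, p)
            X.append(mu + delta + rng.normal(size=(n_songs, p)))
            pops += [f"pop{g}"] * n_songs
            indivs += [f"pop{g}_i{i}"] * n_songs
    return np.vstack(X), np.array(pops), np.array(indivs)


class TestPDFA:
    def test_perfect_separation(self):
        """Widely separated populations: ~100% correct, smallest possible p.

        Ten individuals per population keep the individual-permutation
        space large enough that no null draw reproduces the block
        structure (with two populations a whole-group swap also separates
        perfectly, so small groups would floor p above 1/(B+1))."""
        rng = np.random.default_rng(0)
        X, pops, indivs = make_groups(rng, n_indiv=10, n_songs=4, effect=30.0)
        res = popstats.pdfa(X, pops, indivs, n_permutations=999,
                            n_selections=1, seed=1)
        assert res.observed_correct_pct > 99.0
        assert res.p_value <= 0.001 + 1e-12

    def test_chance_level_six_populations(self):
        """Pure noise, six populations: observed correct ~ 100/6."""
        rng = np.random.default_rng(1)
        rates = []
        for rep in range(20):
            X, pops, indivs = make_groups(rng, n_pops=6, n_indiv=4, n_songs=8,
                                          effect=0.0)
            res = popstats.pdfa(X, pops, indivs, n_permutations=0,
                                n_selections=4, seed=rep)
            rates.append(res.observed_correct_pct)
        assert np.mean(rates) == pytest.approx(100 / 6, abs=2.5)

    def test_permutations_respect_individual_partition(self):
        rng = np.random.default_rng(2)
        X, pops, indivs = make_groups(rng, n_pops=3, n_indiv=3, n_songs=5)
        res = popstats.pdfa(X, pops, indivs, n_permutations=25,
                            n_selections=2, seed=3)
        # stored permutations assign one population per whole individual,
        # preserving population sizes
        orig = sorted(res.permuted_assignments[0])
        for perm in res.permuted_assignments:
            assert sorted(perm) == orig

    def test_confusion_rows_sum_to_100(self):
        rng = np.random.default_rng(4)
        X, pops, indivs = make_groups(rng, n_pops=3, n_indiv=3, n_songs=6,
                                      effect=2.0)
        res = popstats.pdfa(X, pops, indivs, n_permutations=5,
                            n_selections=10, seed=5)
        np.testing.assert_allclose(res.confusion.sum(axis=1), 100.0, atol=0.1)

    def test_degenerate_inputs_rejected(self):
        rng = np.random.default_rng(5)
        X, pops, indivs = make_groups(rng)
        with pytest.raises(ValueError, match="constant"):
            popstats.pdfa(np.zeros_like(X), pops, indivs, 1, 1)
        solo = indivs.copy()
        solo[pops == "pop0"] = "only_one"
        with pytest.raises(ValueError, match="fewer than 2"):
            popstats.pdfa(X, pops, solo, 1, 1)


class TestPairwiseMahalanobis:
    def test_identity_covariance_hand_value(self):
        """Centroids (0,0) and (3,4) under unit pooled covariance: D^2=25."""
        z = np.sqrt(2.0) * np.array(
            [[1, 0], [-1, 0], [0, 1], [0, -1], [0, 0]], dtype=float)
        X = np.vstack([z, z + [3.0, 4.0]])
        pops = np.array(["a"] * 5 + ["b"] * 5)
        names, D2 = popstats.pairwise_mahalanobis(X, pops)
        assert D2[0, 1] == pytest.approx(25.0, abs=1e-10)

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(600, 3))
        pops = np.repeat(["a", "b", "c"], 200)
        _, D2 = popstats.pairwise_mahalanobis(X, pops)
        off = D2[np.triu_indices(3, 1)]
        assert np.all(off < 0.2)

    def test_matches_direct_solve_oracle(self):
        """Independent oracle: explicit solve of S x = mu_g - mu_h."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            X = rng.normal(size=(90, 4)) @ rng.normal(size=(4, 4))
            pops = np.repeat(["a", "b", "c"], 30)
            names, D2 = popstats.pairwise_mahalanobis(X, pops)
            mus = {p: X[pops == p].mean(0) for p in names}
            n, G = len(X), 3
            S = sum((np.sum(pops == p) - 1) * np.cov(X[pops == p], rowvar=False)
                    for p in names) / (n - G)
            for i, g in enumerate(names):
                for j, h in enumerate(names):
                    if i < j:
                        diff = mus[g] - mus[h]
                        expect = float(diff @ np.linalg.solve(S, diff))
                        assert D2[i, j] == pytest.approx(expect, abs=1e-10)

    def test_invariance_under_invertible_linear_maps(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(120, 3))
        pops = np.repeat(["a", "b", "c"], 40)
        _, D2 = popstats.pairwise_mahalanobis(X, pops)
        for _ in range(5):
            A = rng.normal(size=(3, 3))
            while abs(np.linalg.det(A)) < 0.1:
                A = rng.normal(size=(3, 3))
            _, D2t = popstats.pairwise_mahalanobis(X @ A, pops)
            np.testing.assert_allclose(D2t, D2, atol=1e-8)

    def test_singular_covariance_reported(self):
        X = np.repeat(np.arange(20.0)[:, None], 2, axis=1)  # collinear
        pops = np.repeat(["a", "b"], 10)
        with pytest.raises(ValueError, match="collinear"):
            popstats.pairwise_mahalanobis(X, pops)


def random_distance_matrix(rng, n):
    pts = rng.normal(size=(n, 3))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return D


class TestMantel:
    def test_identity_matrices(self):
        rng = np.random.default_rng(0)
        D = random_distance_matrix(rng, 10)
        res = popstats.mantel(D, D.copy(), n_permutations=999, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        D = random_distance_matrix(rng, 8)
        res = popstats.mantel(D, 2.0 * D + 3.0, n_permutations=99, seed=2)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(res.r ** 2)

    def test_small_matrix_warns(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            popstats.mantel(D, D, n_permutations=9, seed=0)

    def test_asymmetric_rejected(self):
        D = np.arange(16.0).reshape(4, 4)
        with pytest.raises(ValueError):
            popstats.mantel(D, D, n_permutations=9)


class TestClusterDendrogram:
    def test_first_merge_is_closest_pair(self):
        D = np.array([[0.0, 1.0, 10.0],
                      [1.0, 0.0, 10.0],
                      [10.0, 10.0, 0.0]])
        Z, newick = popstats.cluster_dendrogram(D, ["A", "B", "C"])
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == pytest.approx(1.0)
        assert np.all(np.diff(Z[:, 2]) >= 0)

    def test_ultrametric_recovered_exactly(self):
        """Average linkage reproduces an ultrametric input exactly."""
        # leaves {A,B} join at 2, {C,D} at 4, root at 10
        D = np.array([
            [0.0, 2.0, 10.0, 10.0],
            [2.0, 0.0, 10.0, 10.0],
            [10.0, 10.0, 0.0, 4.0],
            [10.0, 10.0, 4.0, 0.0]])
        Z, newick = popstats.cluster_dendrogram(D, list("ABCD"))
        assert sorted(Z[:, 2]) == [2.0, 4.0, 10.0]

    def test_two_populations_single_merge(self):
        D = np.array([[0.0, 7.0], [7.0, 0.0]])
        Z, newick = popstats.cluster_dendrogram(D, ["X", "Y"])
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(7.0)

    def test_newick_parseable_with_correct_heights(self):
        """The exported Newick round-trips through an independent parser
        (dendropy) and reproduces the cophenetic distances."""
        import dendropy

        D = np.array([
            [0.0, 2.0, 10.0, 10.0],
            [2.0, 0.0, 10.0, 10.0],
            [10.0, 10.0, 0.0, 4.0],
            [10.0, 10.0, 4.0, 0.0]])
        _, newick = popstats.cluster_dendrogram(D, list("ABCD"))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        labels = list("ABCD")
        for i in range(4):
            for j in range(i + 1, 4):
                got = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
                assert got == pytest.approx(D[i, j], abs=1e-6)


class TestEndToEndRecovery:
    def test_body_coupled_intro_not(self, pop_distances, small_corpus):
        """On a default-parameter corpus the body Mantel p is far below the
        intro Mantel p (single-replicate version of the recovery contrast;
        the replicated version lives in the acceptance suite)."""
        names, straight = pop_distances
        _, elements, _, _ = small_corpus
        lab = features.label_corpus(elements)
        ps = {}
        for scope in ("body", "intro"):
            if scope == "body":
                tab = features.song_feature_table(lab, "body_only").dropna(
                    subset=features.SONG_VARS)
            else:
                tab = lab[lab["component"] == "intro"].copy()
            mat, _ = features.transform_variables(tab, scope)
            keep = features.prune_correlated(mat.values, 0.7)
            vals = features.zscale(mat.values[keep], keep)
            pc = popstats.pca(vals.to_numpy())
            nk = popstats.retain_components(
                pc.variance_fraction, 0.75 if scope == "body" else 0.80)
            _, D2 = popstats.pairwise_mahalanobis(
                pc.scores[:, :nk], mat.labels["population"].to_numpy())
            ps[scope] = popstats.mantel(D2, straight, n_permutations=199,
                                        seed=0).p_value
        assert ps["body"] < ps["intro"]
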