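import dendropy
import numpy as np
import pandas as pd
import pytest

from traitnet import associations, varpart


class TestBuildResponse:
    def test_saturated_species_all_ones(self):
        m = pd.DataFrame([[1, 1, 1]], columns=list("abc"))
        assert (varpart.build_response(m).to_numpy() == 1).all()

    def test_single_trait_species_all_zero(self):
        m = pd.DataFrame([[0, 1, 0]], columns=list("abc"))
        assert (varpart.build_response(m).to_numpy() == 0).all()

    def test_column_sums_match_pair_counts(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame((rng.random((30, 5)) < 0.5).astype(int),
                         columns=[f"t{j}" for j in range(5)])
        Y = varpart.build_response(m)
        k = 0
        for a in range(5):
            for b in range(a + 1, 5):
                pos, _ = associations.pair_counts(m.to_numpy(), a, b)
                assert Y.iloc[:, k].sum() == pos
                k += 1


class TestAdjustedR2:
    def test_perfect_fit(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        Y = X @ rng.normal(size=(3, 4))
        assert varpart.adjusted_r2(Y, X) == pytest.approx(1.0)

    def test_noise_unbiased_near_zero(self):
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(100):
            X = rng.normal(size=(200, 5))
            Y = rng.normal(size=(200, 3))
            vals.append(varpart.adjusted_r2(Y, X))
        assert abs(np.mean(vals)) < 0.02

    def test_matches_variance_weighted_univariate(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 1))
        Y = np.column_stack([2 * X[:, 0] + rng.normal(size=80),
                             rng.normal(size=80) * 3])
        Yc = Y - Y.mean(0)
        r2_cols = []
        for k in range(2):
            beta = np.linalg.lstsq(X - X.mean(0), Yc[:, k:k + 1], rcond=None)[0]
            fit = (X - X.mean(0)) @ beta
            r2_cols.append((fit**2).sum() / (Yc[:, k]**2).sum())
        w = (Yc**2).sum(0) / (Yc**2).sum()
        expected = float(np.dot(w, r2_cols))
        n, p = 80, 1
        expected_adj = 1 - (1 - expected) * (n - 1) / (n - p - 1)
        assert varpart.adjusted_r2(Y, X) == pytest.approx(expected_adj)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            varpart.adjusted_r2(np.ones((10, 2)), np.random.default_rng(0).normal(size=(10, 1)))


class TestPartition3:
    def rng_sets(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        return (rng.normal(size=(n, 3)) for _ in range(3))

    def test_inclusion_exclusion_sums_to_total(self):
        Xp, Xb, Xe = self.rng_sets(4)
        rng = np.random.default_rng(5)
        Y = np.hstack([Xp, Xb]) @ rng.normal(size=(6, 8)) + rng.normal(size=(200, 8))
        res = varpart.partition3(Y, Xp, Xb, Xe)
        parts = (res.phy + res.bio + res.env + res.phy_bio + res.phy_env
                 + res.bio_env + res.phy_bio_env)
        assert parts == pytest.approx(res.total, abs=1e-10)

    def test_orthogonal_predictors_no_shared_fractions(self):
        rng = np.random.default_rng(7)
        raw = rng.normal(size=(200, 9))
        Q, _ = np.linalg.qr(raw - raw.mean(0))
        Xp, Xb, Xe = Q[:, :3], Q[:, 3:6], Q[:, 6:9]
        Y = Xb @ rng.normal(size=(3, 6)) + 0.7 * rng.normal(size=(200, 6))
        res = varpart.partition3(Y, Xp, Xb, Xe)
        for shared in (res.phy_bio, res.phy_env, res.bio_env, res.phy_bio_env):
            assert abs(shared) < 0.01

    def test_planted_biology_recovered_as_unique(self):
        Xp, Xb, Xe = self.rng_sets(8)
        rng = np.random.default_rng(9)
        Y = Xb @ rng.normal(size=(3, 6))
        res = varpart.partition3(Y, Xp, Xb, Xe)
        assert res.bio == pytest.approx(res.total, abs=0.01)
        assert res.total > 0.95

    def test_species_permutation_invariance(self):
        Xp, Xb, Xe = (np.asarray(x) for x in self.rng_sets(10))
        rng = np.random.default_rng(11)
        Y = Xb @ rng.normal(size=(3, 5)) + rng.normal(size=(200, 5))
        res = varpart.partition3(Y, Xp, Xb, Xe)
        perm = rng.permutation(200)
        res2 = varpart.partition3(Y[perm], Xp[perm], Xb[perm], Xe[perm])
        assert res.bio == pytest.approx(res2.bio, abs=1e-9)
        assert res.total == pytest.approx(res2.total, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            varpart.partition3(np.ones((10, 2)), np.ones((9, 1)),
                               np.ones((10, 1)), np.ones((10, 1)))


def test_phylo_predictors_embed_patristic_distances():
    nwk = "((A:1,B:1):2,(C:1,(D:0.5,E:0.5):0.5):2);"
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    X = varpart.phylo_predictors(tree, ["A", "B", "C", "D", "E"], cum_eig=0.999)
    # PCoA embedding distances should reproduce patristic distances
    from scipy.spatial.distance import pdist, squareform
    emb = squareform(pdist(X.to_numpy()))
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    names = ["A", "B", "C", "D", "E"]
    for i in range(5):
        for j in range(i + 1, 5):
            true = pdm.patristic_distance(taxa[names[i]], taxa[names[j]])
            assert emb[i, j] == pytest.approx(true, rel=0.05)


def test_biology_predictors_count_categories():
    m = pd.DataFrame([[1, 1, 0], [0, 1, 1]], columns=["glc", "gal", "xyl"])
    cats = {"glc": "hexose", "gal": "hexose", "xyl": "pentose"}
    X = varpart.biology_predictors(m, cats)
    assert X["hexose"].tolist() == [2, 1]
    assert X["pentose"].tolist() == [0, 1]
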