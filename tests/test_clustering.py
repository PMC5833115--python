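import numpy as np
import pandas as pd
import pytest

from traitnet import clustering


def block_profiles(rng, n=16, gap=30.0):
    labels = [f"t{i}" for i in range(n)]
    prof = pd.DataFrame(0.0, index=labels, columns=labels)
    half = n // 2
    for i in range(half):
        for j in range(half):
            if i != j:
                prof.iloc[i, j] = gap + rng.normal()
                prof.iloc[half + i, half + j] = -gap + rng.normal()
    return prof


def test_profiles_zero_where_not_significant():
    table = pd.DataFrame({
        "item_a": ["a", "a", "b"], "item_b": ["b", "c", "c"],
        "str_pos": [5.0, 2.0, 1.0], "str_neg": [1.0, 7.0, 1.0],
        "direction": ["positive", "negative", "none"],
    })
    prof = clustering.association_profiles(table)
    assert prof.loc["a", "b"] == 5.0
    assert prof.loc["a", "c"] == -7.0
    assert prof.loc["b", "c"] == 0.0
    assert (np.diag(prof) == 0).all()


class TestDistance:
    def test_identical_profiles_distance_zero(self):
        prof = pd.DataFrame([[0, 1, 1], [0, 1, 1], [5, 5, 0]],
                            index=list("abc"), columns=list("abc"), dtype=float)
        d = clustering.profile_distance(prof)
        assert d.loc["a", "b"] == 0

    def test_hand_euclid(self):
        prof = pd.DataFrame([[3.0, 0.0], [0.0, 4.0]], index=["x", "y"], columns=["x", "y"])
        assert clustering.profile_distance(prof).loc["x", "y"] == pytest.approx(5.0)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(0)
        prof = pd.DataFrame(rng.normal(size=(8, 8)),
                            index=[f"t{i}" for i in range(8)],
                            columns=[f"t{i}" for i in range(8)])
        d = clustering.profile_distance(prof).to_numpy()
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_localized_profile_change(self):
        """Zeroing one pair only changes distances involving those two traits."""
        rng = np.random.default_rng(1)
        prof = pd.DataFrame(rng.normal(size=(6, 6)),
                            index=[f"t{i}" for i in range(6)],
                            columns=[f"t{i}" for i in range(6)])
        prof = (prof + prof.T) / 2
        np.fill_diagonal(prof.values, 0.0)
        d0 = clustering.profile_distance(prof)
        prof2 = prof.copy()
        prof2.loc["t1", "t4"] = prof2.loc["t4", "t1"] = 0.0
        d1 = clustering.profile_distance(prof2)
        diff = (d0 - d1).abs()
        untouched = diff.drop(index=["t1", "t4"], columns=["t1", "t4"])
        assert (untouched.to_numpy() == 0).all()


class TestWard:
    def test_first_merge_joins_closest(self):
        prof = pd.DataFrame(0.0, index=list("abc"), columns=list("abc"))
        # 1-D points 0, 1, 10 encoded via distances
        from scipy.spatial.distance import squareform
        d = pd.DataFrame(squareform([1.0, 10.0, 9.0]), index=list("abc"), columns=list("abc"))
        Z = clustering.ward_cluster(d)
        assert sorted(Z[0, :2].astype(int).tolist()) == [0, 1]

    def test_duplicate_merges_at_zero(self):
        d = pd.DataFrame([[0, 0, 5], [0, 0, 5], [5, 5, 0]], dtype=float,
                         index=list("abc"), columns=list("abc"))
        Z = clustering.ward_cluster(d)
        assert Z[0, 2] == 0

    def test_heights_monotone(self):
        rng = np.random.default_rng(2)
        prof = pd.DataFrame(rng.normal(size=(10, 10)),
                            index=[f"t{i}" for i in range(10)],
                            columns=[f"t{i}" for i in range(10)])
        Z = clustering.ward_cluster(clustering.profile_distance(prof))
        assert (np.diff(Z[:, 2]) >= -1e-9).all()

    def test_too_few_items(self):
        d = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            clustering.ward_cluster(d)


class TestSupport:
    def test_planted_blocks_supported(self):
        rng = np.random.default_rng(0)
        prof = block_profiles(rng)
        sup = clustering.cluster_support(prof, n_boot=200, seed=1)
        labels = list(prof.index)
        assert sup[frozenset(labels[:8])] >= 0.95
        assert sup[frozenset(labels[8:])] >= 0.95

    def test_root_support_is_one(self):
        rng = np.random.default_rng(3)
        prof = block_profiles(rng, n=8)
        sup = clustering.cluster_support(prof, n_boot=50, seed=2)
        assert sup[frozenset(prof.index)] == 1.0

    def test_noise_profiles_rarely_supported(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            labels = [f"x{i}" for i in range(10)]
            noise = pd.DataFrame(rng.normal(size=(10, 10)), index=labels, columns=labels)
            sup = clustering.cluster_support(noise, n_boot=100, seed=s)
            nonroot = sup.drop(index=[frozenset(labels)])
            hits += nonroot.max() > 0.95
        assert hits <= 1  # >= 90% of seeds show no supported node

    def test_seed_reproducible(self):
        rng = np.random.default_rng(5)
        prof = block_profiles(rng, n=8)
        a = clustering.cluster_support(prof, n_boot=50, seed=9)
        b = clustering.cluster_support(prof, n_boot=50, seed=9)
        assert a.sort_index(key=lambda i: i.map(str)).tolist() == \
               b.sort_index(key=lambda i: i.map(str)).tolist()
        assert ((a >= 0) & (a <= 1)).all()


def test_newick_export_parses():
    import dendropy

    rng = np.random.default_rng(6)
    prof = block_profiles(rng, n=8)
    Z = clustering.ward_cluster(clustering.profile_distance(prof))
    sup = clustering.cluster_support(prof, n_boot=20, seed=0)
    nwk = clustering.linkage_to_newick(Z, list(prof.index), sup)
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    assert len(tree.leaf_nodes()) == 8
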