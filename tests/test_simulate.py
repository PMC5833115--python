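import dendropy
import numpy as np
import pandas as pd
import pytest

from traitnet import data_io, simulate


class TestTraitGenerator:
    def test_seed_determinism(self):
        a, xa, _ = simulate.simulate_trait_matrix(60, 30, seed=5)
        b, xb, _ = simulate.simulate_trait_matrix(60, 30, seed=5)
        assert (xa == xb).all()
        pd.testing.assert_frame_equal(a, b)

    def test_independence_limit_no_covariance(self):
        rng = np.random.default_rng(0)
        truth = simulate.SyntheticTruth(
            modules=[], negative_pairs=[], module_boost=0.0, negative_strength=0.0,
            prevalence=rng.uniform(0.2, 0.8, 20), missing_rate=0.0, variable_rate=0.0)
        x = simulate.simulate_binary_traits(2000, truth, seed=1)
        c = np.cov(x.T)
        off = np.abs(c[~np.eye(20, dtype=bool)])
        assert off.max() < 0.035  # ~4 sd of a zero covariance at n=2000

    def test_realized_prevalence_tracks_target(self):
        truth = simulate.default_truth(20, seed=3, n_modules=1, module_size=4,
                                       n_negative_pairs=2)
        x = simulate.simulate_binary_traits(1000, truth, seed=10)
        sd = np.sqrt(truth.prevalence * (1 - truth.prevalence) / 1000)
        assert (np.abs(x.mean(0) - truth.prevalence) <= 3 * sd).all()

    def test_planted_signs_in_correlations(self):
        truth = simulate.default_truth(20, seed=4, n_modules=1, module_size=4,
                                       n_negative_pairs=2)
        x = simulate.simulate_binary_traits(1500, truth, seed=10)
        c = np.corrcoef(x.T)
        for a, b in truth.module_pairs():
            assert c[a, b] > 0.1
        for a, b in truth.negative_pairs:
            assert c[a, b] < -0.1

    def test_coded_matrix_round_trips_the_codes(self, tmp_path):
        coded, _, _ = simulate.simulate_trait_matrix(40, 30, seed=6)
        assert set(np.unique(coded.to_numpy())) <= {
            data_io.PRESENT, data_io.ABSENT, data_io.VARIABLE, data_io.MISSING}
        p = tmp_path / "sim.tsv"
        data_io.write_trait_table(coded, p)
        pd.testing.assert_frame_equal(coded, data_io.read_trait_table(p))

    def test_infeasible_prevalence_rejected(self):
        truth = simulate.SyntheticTruth(
            modules=[], negative_pairs=[], module_boost=0.0, negative_strength=0.0,
            prevalence=np.array([0.0, 0.5]), missing_rate=0.0, variable_rate=0.0)
        with pytest.raises(ValueError):
            simulate.simulate_binary_traits(10, truth)


class TestTreeGenerator:
    def test_newick_parses_with_labeled_tips(self):
        nwk, tips = simulate.simulate_tree_and_traits(32, [0.5] * 3,
                                                      ["brownian"] * 3, seed=7)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 32
        assert tips.shape == (32, 3)
        assert set(np.unique(tips.to_numpy())) <= {0, 1}

    def test_modes_control_signal(self):
        # joint calibration lives in the phylo-signal tests; here: prevalence kept
        nwk, tips = simulate.simulate_tree_and_traits(
            50, [0.3, 0.3], ["brownian", "shuffled"], seed=8)
        assert tips.iloc[:, 0].sum() == tips.iloc[:, 1].sum() == 15

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_tree_and_traits(4, [0.5], ["brownian"], seed=0)


@pytest.fixture(scope="module")
def dataset():
    truth = simulate.default_truth(24, seed=9, n_modules=2, module_size=4,
                                   n_negative_pairs=2)
    x = simulate.simulate_binary_traits(400, truth, seed=11)
    env, genes = simulate.simulate_environments_and_genes(
        x, truth, seed=12, n_environments=12)
    return x, truth, env, genes


class TestEnvironmentAndGenes:
    def test_sizes_cover_control_grid(self, dataset):
        x, truth, env, _ = dataset
        sizes = set(env.sum(0).tolist())
        expected = {s for s in simulate.ENV_SIZE_GRID if s <= len(x)}
        assert expected <= sizes

    def test_members_enriched_for_suite(self, dataset):
        x, truth, env, _ = dataset
        name = "env05"
        suite = truth.env_suites[name]
        members = env[name].to_numpy().astype(bool)
        assert x[members][:, suite].mean() > x[~members][:, suite].mean()

    def test_noise_free_gene_equals_trait(self):
        truth = simulate.default_truth(24, seed=13, n_modules=2, module_size=4,
                                       n_negative_pairs=2)
        truth.gene_noise = 0.0
        x = simulate.simulate_binary_traits(100, truth, seed=14)
        _, genes = simulate.simulate_environments_and_genes(
            x, truth, seed=15, n_environments=4, n_gene_species=100)
        for gene, t in truth.gene_map.items():
            assert (genes[gene].to_numpy() == x[:, t]).all()

    def test_gene_table_subsets_species(self, dataset):
        x, _, _, genes = dataset
        assert len(genes) == 79


def test_environment_driven_generator_conditional_independence():
    traits, env = simulate.simulate_environment_driven(
        800, 10, [[0, 1, 2], [3, 4, 5]], seed=0)
    x = traits.to_numpy()
    # marginal co-occurrence between suite traits
    assert np.corrcoef(x[:, 0], x[:, 1])[0, 1] > 0.1
    # conditional on environment: independence
    members = env["env00"].to_numpy().astype(bool)
    assert abs(np.corrcoef(x[members][:, 0], x[members][:, 1])[0, 1]) < 0.1
    assert (env.sum(1) == 1).all()
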