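import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rbprior.alterations import PROGRESSION, count_per_gene, first_quartile_genes
from rbprior.synthetic import (
    ConfigError,
    SimulationConfig,
    gene_universe,
    make_truth,
    simulate_all,
    simulate_cohort,
    simulate_dependency,
    simulate_ihc,
    simulate_networks,
    write_all,
)


class TestConfigValidation:
    def test_bad_proportions_rejected(self):
        with pytest.raises(ConfigError, match="sum to 1"):
            SimulationConfig(subtype_proportions=(0.5, 0.5, 0.5, 0.0, 0.0))

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_patients=0)

    def test_planted_exceeding_rbp_set_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(set_sizes=(8, 4, 4, 4), n_planted_progressors=5)


class TestCohort:
    def test_zero_background_rate_gives_no_background_calls(self):
        config = SimulationConfig(seed=1, alteration_rate_background=0.0)
        calls, samples, _ = simulate_cohort(config)
        assert len(calls) == 0
        assert len(samples) == config.n_patients

    def test_fixed_seed_reproducibility(self):
        a = simulate_cohort(SimulationConfig(seed=1))
        b = simulate_cohort(SimulationConfig(seed=1))
        assert a[0].equals(b[0]) and a[1].equals(b[1]) and a[2] == b[2]

    def test_planted_progressors_exceed_background_event_counts(self):
        config = SimulationConfig(seed=3, n_patients=500)
        calls, _, truth = simulate_cohort(config)
        counts = count_per_gene(calls, PROGRESSION, set(gene_universe(config)["rbp"]))
        planted = counts[list(truth.planted_progressors)]
        background = counts.drop(list(truth.planted_progressors | truth.planted_suppressors))
        res = stats.mannwhitneyu(planted, background, alternative="greater")
        assert res.pvalue < 0.01

    def test_label_coherence(self, default_config, bundle):
        universe = gene_universe(default_config)
        all_sets = [set(universe["rbp"]), set(universe["bc"]), set(universe["noncancer"])]
        seen = set(bundle["alterations"]["gene"]) | set(bundle["ihc"]["gene"])
        seen |= set(bundle["ppi"]["gene_a"]) | set(bundle["ppi"]["gene_b"])
        seen |= set(bundle["funcnet"].nodes)
        for gene in seen:
            assert sum(gene in s for s in all_sets) == 1
        truth = bundle["truth"]
        assert truth.planted_progressors <= set(universe["rbp"])
        assert truth.planted_complex <= set(universe["rbp"])

    def test_boost_monotonically_improves_planted_rank(self):
        """Raising the planted boost never worsens the planted genes' mean
        rank among per-gene progression event counts (checked over seeds)."""
        mean_ranks = []
        for boost in (1.0, 5.0, 15.0):
            ranks = []
            for seed in range(6):
                config = SimulationConfig(seed=seed, n_patients=300, progressor_boost=boost)
                calls, _, truth = simulate_cohort(config)
                counts = count_per_gene(calls, PROGRESSION, set(gene_universe(config)["rbp"]))
                order = counts.rank(ascending=True, method="average")
                ranks.append(order[list(truth.planted_progressors)].mean())
            mean_ranks.append(np.mean(ranks))
        assert mean_ranks[0] <= mean_ranks[1] <= mean_ranks[2]

    def test_planted_progressors_reach_first_quartile(self):
        for seed in range(20):
            config = SimulationConfig(seed=seed)
            calls, _, truth = simulate_cohort(config)
            counts = count_per_gene(calls, PROGRESSION, set(gene_universe(config)["rbp"]))
            assert truth.planted_progressors <= first_quartile_genes(counts)


class TestIHC:
    def test_modal_tumor_level_of_planted_progressors_is_high_scale(self, default_config, truth):
        from rbprior.ihc import LEVELS, consensus_level

        ihc = simulate_ihc(default_config, truth)
        for gene in truth.planted_progressors:
            tumor = ihc[(ihc["gene"] == gene) & (ihc["tissue"] == "tumor")]["level"]
            normal = ihc[(ihc["gene"] == gene) & (ihc["tissue"] == "normal")]["level"].iloc[0]
            assert consensus_level(tumor) >= LEVELS["medium"]
            assert consensus_level(tumor) - LEVELS[normal] >= 2

    def test_fixed_seed_reproducibility(self, default_config, truth):
        assert simulate_ihc(default_config, truth).equals(simulate_ihc(default_config, truth))


class TestNetworks:
    def test_no_noise_no_clique_gives_expected_structure(self):
        config = SimulationConfig(seed=2, noise_edge_prob=0.0)
        truth = make_truth(config)
        _, funcnet, _ = simulate_networks(config, truth)
        # only the planted clique contributes edges
        k = config.planted_complex_size
        assert funcnet.number_of_edges() == k * (k - 1) // 2

    def test_clique_degree_property(self, default_config, truth, bundle):
        funcnet = bundle["funcnet"]
        for gene in truth.planted_complex:
            assert funcnet.degree(gene) >= default_config.planted_complex_size - 1

    def test_catalog_names_the_planted_complex(self, truth, bundle):
        from rbprior.synthetic import PLANTED_COMPLEX_NAME

        assert bundle["complexes"][PLANTED_COMPLEX_NAME] == set(truth.planted_complex)


class TestWriteAll:
    def test_round_trip_of_key_tables(self, tmp_path, default_config):
        bundle = simulate_all(default_config)
        write_all(bundle, tmp_path)
        calls = pd.read_csv(tmp_path / "alterations.tsv", sep="\t")
        assert len(calls) == len(bundle["alterations"])
        dep = pd.read_csv(tmp_path / "dep_rnai.tsv", sep="\t", index_col=0)
        assert dep.shape == bundle["dep_rnai"].shape
        truth_text = (tmp_path / "truth.json").read_text()
        from rbprior.synthetic import GroundTruth

        assert GroundTruth.from_json(truth_text) == bundle["truth"]

    def test_dependency_reproducibility(self, default_config, truth):
        a = simulate_dependency(default_config, truth)
        b = simulate_dependency(default_config, truth)
        assert a[0].equals(b[0]) and a[1].equals(b[1]) and a[2].equals(b[2])
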