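"""Synthetic-data generator: determinism, planted truth, annotation structure."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from crosspath import (
    GeneSetCollection,
    InteractionNetwork,
    SimulationConfig,
    ease_score,
    generate_pathways_and_ppi,
    generate_probe_map,
    generate_two_platform_dataset,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"de_fraction": 1.0},
            {"de_fraction": 0.0},
            {"n_genes": 0},
            {"noise_sd": 0.0},
            {"de_ppi_enrichment": 0.5},
            {"pathway_size_range": (50, 20)},
            {"pathway_size_range": (10, 500), "n_genes": 100},
            {"n_samples_per_group_per_platform": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestTwoPlatformDataset:
    def test_seed_determinism_bitwise(self, small_config):
        a1, b1, ann1, t1 = generate_two_platform_dataset(small_config)
        a2, b2, ann2, t2 = generate_two_platform_dataset(small_config)
        assert a1.values.equals(a2.values)
        assert b1.values.equals(b2.values)
        assert ann1.equals(ann2)
        assert t1.de_genes == t2.de_genes

    def test_different_seeds_differ(self, small_config):
        a1, *_ = generate_two_platform_dataset(small_config)
        a2, *_ = generate_two_platform_dataset(
            dataclasses.replace(small_config, seed=small_config.seed + 1))
        assert not a1.values.equals(a2.values)

    def test_planted_de_count_forced_by_parameters(self):
        config = SimulationConfig(n_genes=100, de_fraction=0.1, seed=0)
        *_, truth = generate_two_platform_dataset(config)
        assert len(truth.de_genes) == 10
        assert set(truth.de_genes.values()) <= {"up", "down"}

    def test_planted_effect_direction_matches_group_means(self, small_config):
        matrix_a, _, annotation, truth = generate_two_platform_dataset(
            dataclasses.replace(small_config, effect_size=4.0))
        ann = annotation[annotation.platform == "A"].set_index("sample_id")
        tumor = [s for s in matrix_a.sample_ids if ann.loc[s, "group"] == "tumor"]
        normal = [s for s in matrix_a.sample_ids if ann.loc[s, "group"] == "normal"]
        diff = matrix_a.values[tumor].mean(axis=1) - matrix_a.values[normal].mean(axis=1)
        agree = sum(
            1 for g, d in truth.de_genes.items()
            if (diff[g] > 0) == (d == "up")
        )
        assert agree / len(truth.de_genes) > 0.95

    def test_platform_affine_effect_applied(self):
        # with zero noise the platform relation is exactly affine
        config = SimulationConfig(n_genes=200, noise_sd=1e-9, effect_size=0.0,
                                  platform_shift=3.0, platform_scale=1.5, seed=5)
        matrix_a, matrix_b, _, truth = generate_two_platform_dataset(config)
        mean_a = matrix_a.values.mean(axis=1)
        mean_b = matrix_b.values.mean(axis=1)
        np.testing.assert_allclose(mean_b, 1.5 * mean_a + 3.0, atol=1e-6)
        assert truth.platform_shift == 3.0 and truth.platform_scale == 1.5

    def test_null_effect_gives_uniform_p_values(self):
        """effect_size=0: two-sample t p-values over genes are Uniform(0,1)."""
        config = SimulationConfig(n_genes=2000, n_samples_per_group_per_platform=10,
                                  effect_size=0.0, seed=42)
        matrix_a, _, annotation, truth = generate_two_platform_dataset(config)
        assert len(truth.de_genes) == 200  # still listed even with no effect
        ann = annotation[annotation.platform == "A"].set_index("sample_id")
        tumor = [s for s in matrix_a.sample_ids if ann.loc[s, "group"] == "tumor"]
        normal = [s for s in matrix_a.sample_ids if ann.loc[s, "group"] == "normal"]
        _, p = stats.ttest_ind(matrix_a.values[tumor], matrix_a.values[normal],
                               axis=1)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_partial_gene_overlap(self, small_config):
        config = dataclasses.replace(small_config, shared_gene_fraction=0.8)
        matrix_a, matrix_b, _, truth = generate_two_platform_dataset(config)
        shared = set(matrix_a.gene_ids) & set(matrix_b.gene_ids)
        union = set(matrix_a.gene_ids) | set(matrix_b.gene_ids)
        assert union == set(truth.gene_ids)
        assert len(shared) == round(0.8 * config.n_genes)

    def test_annotation_structure(self, small_config):
        _, _, annotation, _ = generate_two_platform_dataset(small_config)
        n = small_config.n_samples_per_group_per_platform
        assert list(annotation.columns) == ["sample_id", "group", "platform"]
        assert len(annotation) == 4 * n
        counts = annotation.groupby(["platform", "group"]).size()
        assert (counts == n).all()


class TestProbeMap:
    def test_no_multimapping_when_fraction_zero(self, small_config):
        probe_map = generate_probe_map(small_config, 0.0)
        assert probe_map.multi_mapping_probes() == set()
        assert all(len(genes) == 1 for _, genes in probe_map.items())

    def test_multimapping_count_forced(self):
        config = SimulationConfig(n_genes=100, probes_per_gene=1, seed=2)
        probe_map = generate_probe_map(config, 0.2)
        assert len(probe_map) == 100
        assert len(probe_map.multi_mapping_probes()) == 20

    def test_every_gene_covered(self, small_config):
        probe_map = generate_probe_map(small_config, 0.3)
        singles = set()
        for _, genes in probe_map.items():
            if len(genes) == 1:
                singles |= genes
        assert len(probe_map.genes()) == small_config.n_genes

    def test_round_trip_through_tsv(self, small_config, tmp_path):
        probe_map = generate_probe_map(small_config, 0.2)
        path = tmp_path / "map.tsv"
        probe_map.to_tsv(path)
        assert probe_map.__class__.from_tsv(path) == probe_map

    def test_invalid_fraction_rejected(self, small_config):
        with pytest.raises(ValueError):
            generate_probe_map(small_config, 1.0)


class TestPathwaysAndPpi:
    def test_neutral_attachment_degree_ratio(self):
        """de_ppi_enrichment=1: DE and non-DE genes get comparable degrees."""
        ratios = []
        for seed in range(10):
            config = SimulationConfig(n_genes=1000, ppi_edge_count=2000,
                                      de_ppi_enrichment=1.0, seed=seed)
            *_, truth = generate_two_platform_dataset(config)
            _, network = generate_pathways_and_ppi(config, truth)
            degrees = network.degrees()
            de = set(truth.de_genes)
            de_mean = np.mean([degrees.get(g, 0) for g in truth.gene_ids if g in de])
            bg_mean = np.mean([degrees.get(g, 0) for g in truth.gene_ids if g not in de])
            ratios.append(de_mean / bg_mean)
        assert 0.8 <= np.mean(ratios) <= 1.25

    def test_enriched_attachment_raises_de_degree(self, small_config):
        config = dataclasses.replace(small_config, de_ppi_enrichment=5.0)
        *_, truth = generate_two_platform_dataset(config)
        _, network = generate_pathways_and_ppi(config, truth)
        degrees = network.degrees()
        de = set(truth.de_genes)
        de_mean = np.mean([degrees.get(g, 0) for g in truth.gene_ids if g in de])
        bg_mean = np.mean([degrees.get(g, 0) for g in truth.gene_ids if g not in de])
        assert de_mean > 2 * bg_mean

    def test_zero_edges_gives_empty_network(self, small_config):
        config = dataclasses.replace(small_config, ppi_edge_count=0)
        *_, truth = generate_two_platform_dataset(config)
        _, network = generate_pathways_and_ppi(config, truth)
        assert network.n_edges == 0
        assert all(d == 0 for d in network.degrees().values())

    def test_no_self_loops_or_duplicates(self, small_config):
        *_, truth = generate_two_platform_dataset(small_config)
        _, network = generate_pathways_and_ppi(small_config, truth)
        edges = network.edges()
        assert network.n_edges == small_config.ppi_edge_count
        assert all(u != v for u, v in edges)
        assert len(set(edges)) == len(edges)

    def test_signal_pathway_enriched_for_planted_degs(self):
        """20-of-25 planted overlap against 10% background: EASE p < 1e-6."""
        config = SimulationConfig(n_genes=1000, de_fraction=0.1,
                                  pathway_size_range=(25, 25),
                                  signal_pathway_de_fraction=0.8, seed=3)
        *_, truth = generate_two_platform_dataset(config)
        collection, _ = generate_pathways_and_ppi(config, truth)
        signal = collection["pathway_01"]
        overlap = len(signal.members & set(truth.de_genes))
        assert overlap == 20
        p = ease_score(overlap, len(truth.de_genes), len(signal.members),
                       config.n_genes)
        assert p < 1e-6

    def test_gmt_and_edge_list_round_trip(self, small_config, tmp_path):
        *_, truth = generate_two_platform_dataset(small_config)
        collection, network = generate_pathways_and_ppi(small_config, truth)
        collection.to_gmt(tmp_path / "sets.gmt")
        network.to_tsv(tmp_path / "edges.tsv")
        assert GeneSetCollection.from_gmt(tmp_path / "sets.gmt") == collection
        assert InteractionNetwork.from_tsv(tmp_path / "edges.tsv") == network

    def test_truth_records_generated_annotations(self, small_config):
        *_, truth = generate_two_platform_dataset(small_config)
        collection, network = generate_pathways_and_ppi(small_config, truth)
        assert set(truth.pathway_membership) == set(collection.names())
        assert truth.ppi_edges == network.edges()
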