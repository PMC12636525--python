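import numpy as np
import pandas as pd
import pytest

from metapan import codon, envcluster, pangenome, recruitment, simulate
from metapan.errors import ConfigError


class TestGenPangenome:
    def test_core_clusters_present_in_every_genome(self):
        config = simulate.SimConfig(
            n_genera=3, genomes_per_genus=2, n_core=10,
            n_genus_specific_per_genus=0, n_multi_genus=0, n_singletons=0,
            habitat_of_genus=("coastal", "offshore", "coastal"), seed=0,
        )
        matrix, meta, truth = simulate.gen_pangenome(config)
        core = [c for c, cat in truth.cluster_category.items() if cat == "core"]
        assert len(core) == 10
        assert (matrix.loc[core] >= 1).all().all()
        assert matrix.shape == (10, 6)

    def test_same_seed_is_bit_identical(self):
        config = simulate.SimConfig(seed=42)
        a = simulate.gen_pangenome(config)
        b = simulate.gen_pangenome(config)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        assert a[2].cluster_category == b[2].cluster_category

    def test_truth_covers_every_cluster_exactly_once(self):
        matrix, _, truth = simulate.gen_pangenome(simulate.SimConfig(seed=5))
        assert set(truth.cluster_category) == set(matrix.index)
        assert set(truth.habitat_tag) == set(matrix.index)

    @pytest.mark.parametrize("seed", range(20))
    def test_classifier_recovers_designed_categories(self, seed):
        rng = np.random.default_rng(seed)
        config = simulate.SimConfig(
            n_genera=int(rng.integers(3, 6)),
            genomes_per_genus=int(rng.integers(1, 4)),
            n_core=int(rng.integers(1, 20)),
            n_genus_specific_per_genus=int(rng.integers(0, 5)),
            n_multi_genus=int(rng.integers(0, 8)),
            n_singletons=int(rng.integers(0, 10)),
            seed=seed,
        )
        matrix, meta, truth = simulate.gen_pangenome(config)
        cats = pangenome.habitat_specific(
            pangenome.classify_clusters(matrix, meta), meta
        )
        for row in cats.itertuples():
            assert row.category == truth.cluster_category[row.cluster_id], \
                row.cluster_id
            assert row.habitat_tag == truth.habitat_tag[row.cluster_id], \
                row.cluster_id

    def test_multi_genus_needs_three_genera(self):
        with pytest.raises(ConfigError):
            simulate.SimConfig(
                n_genera=2, n_multi_genus=1,
                habitat_of_genus=("coastal", "offshore"),
            ).validate()


class TestGenCoverage:
    def test_deterministic_mode_gives_constant_depth(self):
        config = simulate.SimConfig(
            seed=1, depth_dispersion=0.0, depth_genome_sigma=0.0,
            n_samples_per_habitat=1,
        )
        matrix, meta, _ = simulate.gen_pangenome(config)
        profiles, _ = simulate.gen_coverage(matrix, meta, config)
        habitat_of = meta.set_index("genome_id")["habitat"]
        for p in profiles:
            expected = {
                "rare": config.depth_rare,
                p.sample_id.split("_")[1]: config.depth_match,
            }.get(habitat_of[p.genome_id], config.depth_mismatch)
            assert np.all(p.depths == expected)

    def test_same_seed_gives_identical_depths(self):
        config = simulate.SimConfig(seed=8, n_samples_per_habitat=1)
        matrix, meta, _ = simulate.gen_pangenome(config)
        a, _ = simulate.gen_coverage(matrix, meta, config)
        b, _ = simulate.gen_coverage(matrix, meta, config)
        for pa, pb in zip(a, b):
            assert pa.genome_id == pb.genome_id and pa.sample_id == pb.sample_id
            assert np.array_equal(pa.depths, pb.depths)

    def test_detection_separates_matched_from_mismatched(self):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            config = simulate.SimConfig(
                seed=seed, n_genera=2, genomes_per_genus=1, n_core=10,
                n_genus_specific_per_genus=2, n_multi_genus=0, n_singletons=0,
                habitat_of_genus=("coastal", "offshore"),
                n_samples_per_habitat=1, depth_match=50.0, depth_mismatch=0.1,
            )
            matrix, meta, _ = simulate.gen_pangenome(config)
            profiles, _ = simulate.gen_coverage(matrix, meta, config)
            habitat_of = meta.set_index("genome_id")["habitat"]
            ok = True
            for p in profiles:
                det = recruitment.detection(p.depths)
                matched = p.sample_id.split("_")[1] == habitat_of[p.genome_id]
                ok &= (det >= 0.25) == matched
            hits += ok
        assert hits >= 0.95 * n_seeds

    def test_truth_abundance_columns_sum_to_one(self):
        config = simulate.SimConfig(seed=3, n_samples_per_habitat=2)
        matrix, meta, _ = simulate.gen_pangenome(config)
        _, truth = simulate.gen_coverage(matrix, meta, config)
        sums = truth.abundance.sum(axis=0)
        assert np.allclose(sums[sums > 0], 1.0)


class TestGenScvs:
    def test_zero_target_pn_records_zero_truth(self):
        config = simulate.SimConfig(
            depth_dispersion=0.0, target_pn=0.0, target_ps=0.1, seed=0
        )
        cds = simulate.random_cds(50, np.random.default_rng(1))
        _, truth = simulate.gen_scvs(cds, config)
        assert truth.pnps["gene_1"] == 0.0

    def test_all_ggg_toy_truth(self):
        # 1 nonsynonymous + 2 synonymous on 9 x GGG: (1/18) / (2/9) = 0.25
        config = simulate.SimConfig(
            depth_dispersion=0.0, target_pn=1 / 18, target_ps=2 / 9, seed=0
        )
        _, truth = simulate.gen_scvs("GGG" * 9, config)
        assert truth.pnps["gene_1"] == pytest.approx(0.25)

    def test_every_codon_gets_a_covered_record(self):
        config = simulate.SimConfig(depth_dispersion=0.0, seed=0)
        cds = simulate.random_cds(25, np.random.default_rng(2))
        table, _ = simulate.gen_scvs(cds, config)
        assert sorted(table["codon_index"]) == list(range(1, 26))
        assert (table["coverage"] >= config.scv_coverage).all()

    def test_same_seed_identical_tables(self):
        config = simulate.SimConfig(seed=13)
        cds = simulate.random_cds(30, np.random.default_rng(3))
        a, _ = simulate.gen_scvs(cds, config)
        b, _ = simulate.gen_scvs(cds, config)
        pd.testing.assert_frame_equal(a, b)

    def test_internal_stop_rejected(self):
        config = simulate.SimConfig(seed=0)
        with pytest.raises(Exception):
            simulate.gen_scvs("GGGTAAGGG", config)

    def test_gene_pnps_recovers_deterministic_truth(self):
        config = simulate.SimConfig(depth_dispersion=0.0, seed=6)
        cds = simulate.random_cds(60, np.random.default_rng(6))
        table, truth = simulate.gen_scvs(cds, config)
        out = codon.gene_pnps(table, cds)
        assert out.iloc[0]["ratio"] == pytest.approx(truth.pnps["gene_1"],
                                                     rel=1e-12)


class TestGenEnv:
    def test_two_well_separated_clusters_are_recovered(self):
        config = simulate.SimConfig(seed=4, env_separation=10.0,
                                    n_samples_per_habitat=6)
        env, labels = simulate.gen_env(config)
        k, found = envcluster.kmeans_select(envcluster.zscale(env), k_max=5)
        assert k == 2
        table = pd.crosstab(labels, found)
        assert table.max(axis=1).sum() == len(labels)  # perfect up to relabeling

    def test_same_seed_identical_table(self):
        config = simulate.SimConfig(seed=10)
        a, _ = simulate.gen_env(config)
        b, _ = simulate.gen_env(config)
        pd.testing.assert_frame_equal(a, b)

    def test_needs_two_samples_per_habitat(self):
        with pytest.raises(ConfigError):
            simulate.gen_env(simulate.SimConfig(n_samples_per_habitat=1))


class TestGenPnpsTable:
    def test_balanced_layout_and_positive_ratios(self):
        table = simulate.gen_pnps_table(n_genes=5, n_genomes=2, n_samples=3,
                                        seed=1)
        assert len(table) == 5 * 2 * 3
        assert (table["ratio"] > 0).all()
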