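import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import oracle_classify, random_cluster_matrix
from metapan import pangenome
from metapan.errors import InputError


class TestClassifyClusters:
    def test_one_cluster_per_category(self, toy_matrix, toy_meta):
        cats = pangenome.classify_clusters(toy_matrix, toy_meta)
        got = dict(zip(cats["cluster_id"], cats["category"]))
        assert got == {
            "c_core": "core",
            "c_single": "singleton",
            "c_genusA": "genus_specific",
            "c_multiAB": "multi_genus_specific",
            "c_other": "accessory_other",
        }
        hosts = dict(zip(cats["cluster_id"], cats["genera"]))
        assert hosts["c_genusA"] == "A"
        assert hosts["c_multiAB"] == "A;B"

    def test_single_genome_input_prefers_singleton(self):
        matrix = pd.DataFrame({"g1": [1]}, index=["c1"])
        meta = pd.DataFrame(
            {"genome_id": ["g1"], "genus": ["A"], "habitat": ["coastal"]}
        )
        cats = pangenome.classify_clusters(matrix, meta)
        assert cats.loc[0, "category"] == "singleton"

    def test_multicopy_presence_does_not_change_category(self, toy_matrix, toy_meta):
        inflated = toy_matrix.copy()
        inflated.loc["c_core", "g1"] = 7
        a = pangenome.classify_clusters(toy_matrix, toy_meta)["category"]
        b = pangenome.classify_clusters(inflated, toy_meta)["category"]
        assert (a == b).all()

    def test_missing_metadata_rejected(self, toy_matrix, toy_meta):
        with pytest.raises(InputError):
            pangenome.classify_clusters(toy_matrix, toy_meta.iloc[:-1])

    @pytest.mark.parametrize("trial", range(25))
    def test_agrees_with_subset_enumeration_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        matrix, meta, genus_of = random_cluster_matrix(rng)
        cats = pangenome.classify_clusters(matrix, meta)
        for row in cats.itertuples():
            expected = oracle_classify(matrix.loc[row.cluster_id] >= 1, genus_of)
            assert row.category == expected, row.cluster_id

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(7)
        matrix, meta, _ = random_cluster_matrix(rng, n_genomes=6, n_clusters=30)
        cats = pangenome.classify_clusters(matrix, meta)
        assert len(cats) == 30
        assert pangenome.category_counts(cats).sum() == 30

    def test_adding_a_genome_lacking_a_core_cluster_demotes_it(
        self, toy_matrix, toy_meta
    ):
        matrix = toy_matrix.copy()
        matrix["g7"] = [0, 0, 0, 0, 0]
        matrix.loc["c_other", "g7"] = 1  # keep a nonzero column
        meta = pd.concat(
            [toy_meta, pd.DataFrame([{"genome_id": "g7", "genus": "D",
                                      "habitat": "rare"}])],
            ignore_index=True,
        )
        cats = pangenome.classify_clusters(matrix, meta)
        got = dict(zip(cats["cluster_id"], cats["category"]))
        assert got["c_core"] != "core"


class TestHabitatSpecific:
    def test_tags_follow_host_genus_habitats(self, toy_matrix, toy_meta):
        cats = pangenome.habitat_specific(
            pangenome.classify_clusters(toy_matrix, toy_meta), toy_meta
        )
        tags = dict(zip(cats["cluster_id"], cats["habitat_tag"]))
        assert tags["c_genusA"] == "coastal"  # genus A is coastal
        assert tags["c_multiAB"] == "none"  # A coastal + B offshore
        assert tags["c_core"] == "none"

    def test_uniform_offshore_multi_genus_cluster(self):
        genomes = ["g1", "g2", "g3", "g4", "g5"]
        matrix = pd.DataFrame(
            {"g1": [1, 1], "g2": [1, 1], "g3": [1, 1], "g4": [1, 1],
             "g5": [1, 0]},
            index=["c_all", "c_DE"],
        )
        meta = pd.DataFrame(
            {"genome_id": genomes,
             "genus": ["D", "D", "E", "E", "F"],
             "habitat": ["offshore"] * 4 + ["coastal"]}
        )
        cats = pangenome.habitat_specific(
            pangenome.classify_clusters(matrix, meta), meta
        )
        tags = dict(zip(cats["cluster_id"], cats["habitat_tag"]))
        assert tags["c_DE"] == "offshore"


class TestPrevalenceClasses:
    @pytest.mark.parametrize(
        "present, expected",
        [(10, "core"), (1, "rare"), (5, "intermediate")],
    )
    def test_threshold_arithmetic_on_ten_genomes(self, present, expected):
        genomes = [f"g{i}" for i in range(10)]
        matrix = pd.DataFrame(
            [[1] * present + [0] * (10 - present)], index=["c1"], columns=genomes
        )
        meta = pd.DataFrame(
            {"genome_id": genomes, "genus": ["A"] * 10, "habitat": ["coastal"] * 10}
        )
        table = pangenome.prevalence_classes(matrix, meta)
        assert table.loc[0, "class"] == expected
        assert table.loc[0, "prevalence"] == pytest.approx(present / 10)

    def test_boundary_value_is_intermediate(self):
        genomes = [f"g{i}" for i in range(20)]
        matrix = pd.DataFrame([[1] * 3 + [0] * 17], index=["c1"], columns=genomes)
        meta = pd.DataFrame(
            {"genome_id": genomes, "genus": ["A"] * 20, "habitat": ["coastal"] * 20}
        )
        table = pangenome.prevalence_classes(matrix, meta)
        assert table.loc[0, "prevalence"] == pytest.approx(0.15)
        assert table.loc[0, "class"] == "intermediate"

    def test_absent_pairs_are_omitted(self, toy_matrix, toy_meta):
        table = pangenome.prevalence_classes(toy_matrix, toy_meta)
        assert (table["prevalence"] > 0).all()
        pairs = set(zip(table["cluster_id"], table["genus"]))
        assert ("c_single", "B") not in pairs


class TestFunctionalEnrichment:
    @staticmethod
    def _presence(rows, genomes):
        return pd.DataFrame(rows, columns=genomes)

    def test_uniform_presence_scores_zero(self):
        genomes = [f"g{i}" for i in range(6)]
        presence = pd.DataFrame([[1] * 6], index=["f1"], columns=genomes)
        groups = pd.Series(["x"] * 3 + ["y"] * 3, index=genomes)
        out = pangenome.functional_enrichment(presence, groups)
        assert out.loc[0, "score"] == 0.0
        assert out.loc[0, "p_value"] == 1.0

    def test_perfect_split_closed_form(self):
        genomes = [f"g{i}" for i in range(10)]
        presence = pd.DataFrame([[1] * 5 + [0] * 5], index=["f1"], columns=genomes)
        groups = pd.Series(["x"] * 5 + ["y"] * 5, index=genomes)
        out = pangenome.functional_enrichment(presence, groups)
        assert out.loc[0, "score"] == pytest.approx(10.0)
        assert out.loc[0, "p_value"] == pytest.approx(stats.chi2.sf(10, 1))

    def test_score_invariant_to_group_relabeling(self):
        rng = np.random.default_rng(5)
        genomes = [f"g{i}" for i in range(12)]
        presence = pd.DataFrame(
            rng.integers(0, 2, (8, 12)), columns=genomes,
            index=[f"f{i}" for i in range(8)],
        )
        groups = pd.Series(["x"] * 6 + ["y"] * 6, index=genomes)
        swapped = groups.map({"x": "y", "y": "x"})
        a = pangenome.functional_enrichment(presence, groups)
        b = pangenome.functional_enrichment(presence, swapped)
        assert np.allclose(a["score"], b["score"])
        assert np.allclose(a["p_value"], b["p_value"])

    def test_chi_square_p_matches_permutation_oracle(self):
        # large groups so the asymptotic chi-square null is accurate
        rng = np.random.default_rng(11)
        genomes = [f"g{i}" for i in range(200)]
        row = [1] * 60 + [0] * 40 + [1] * 45 + [0] * 55
        presence = pd.DataFrame([row], index=["f1"], columns=genomes)
        groups = pd.Series(["x"] * 100 + ["y"] * 100, index=genomes)
        out = pangenome.functional_enrichment(presence, groups)
        observed = out.loc[0, "score"]
        n_perm, hits = 2000, 0
        labels = groups.to_numpy().copy()
        for _ in range(n_perm):
            rng.shuffle(labels)
            perm = pangenome.functional_enrichment(
                presence, pd.Series(labels, index=genomes)
            )
            if perm.loc[0, "score"] >= observed - 1e-12:
                hits += 1
        emp = hits / n_perm
        se = np.sqrt(emp * (1 - emp) / n_perm)
        assert abs(emp - out.loc[0, "p_value"]) < 3 * se + 0.01

    def test_q_values_dominate_p_values(self):
        rng = np.random.default_rng(3)
        genomes = [f"g{i}" for i in range(10)]
        presence = pd.DataFrame(
            rng.integers(0, 2, (20, 10)), columns=genomes,
            index=[f"f{i}" for i in range(20)],
        )
        groups = pd.Series(["x"] * 5 + ["y"] * 5, index=genomes)
        out = pangenome.functional_enrichment(presence, groups)
        assert (out["q_value"] >= out["p_value"] - 1e-12).all()

    def test_single_group_rejected(self):
        genomes = ["g1", "g2"]
        presence = pd.DataFrame([[1, 0]], index=["f1"], columns=genomes)
        with pytest.raises(InputError):
            pangenome.functional_enrichment(
                presence, pd.Series(["x", "x"], index=genomes)
            )
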