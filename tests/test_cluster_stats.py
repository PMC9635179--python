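import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from strscape.abundance import AbundanceMatrix
from strscape.cluster_stats import (
    DegenerateDesignError,
    Partition,
    abundance_summaries,
    cluster_species,
    cut,
    great_ape_outlier,
    motif_concordance,
    partitions_equal,
    reference_partition,
    species_effect_anova,
    species_effect_nonparametric,
)
from strscape.synthetic import default_profile_spec, simulate_profiles


def toy_matrix(columns, index=None):
    df = pd.DataFrame(columns)
    df.index = index or [str(i + 1) for i in range(len(df))]
    return AbundanceMatrix(df)


class TestPartition:
    def test_equal_under_id_permutation(self):
        a = Partition({"x": 1, "y": 1, "z": 2})
        b = Partition({"x": 2, "y": 2, "z": 1})
        assert partitions_equal(a, b)

    def test_moving_one_species_breaks_equality(self, reference):
        moved = dict(reference.assignments)
        moved["human"] = moved["macaque"]
        assert not partitions_equal(reference, Partition(moved))

    def test_singletons_differ_from_one_block(self):
        names = ["a", "b", "c"]
        singles = Partition({n: i + 1 for i, n in enumerate(names)})
        one = Partition({n: 1 for n in names})
        assert not partitions_equal(singles, one)

    def test_species_mismatch_rejected(self):
        with pytest.raises(ValueError):
            partitions_equal(Partition({"a": 1}), Partition({"b": 1}))

    def test_equivalence_on_triples(self):
        a = Partition({"x": 1, "y": 2, "z": 2})
        b = Partition({"x": 2, "y": 1, "z": 1})
        c = Partition({"x": 1, "y": 1, "z": 2})
        assert partitions_equal(a, a)
        assert partitions_equal(a, b) and partitions_equal(b, a)
        assert not partitions_equal(a, c) and not partitions_equal(b, c)

    def test_non_contiguous_ids_rejected(self):
        with pytest.raises(ValueError):
            Partition({"a": 1, "b": 3})

    def test_reference_blocks(self, reference):
        assert reference.blocks() == frozenset(
            {
                frozenset({"rat", "mouse"}),
                frozenset({"gelada", "baboon", "macaque"}),
                frozenset({"gorilla", "chimpanzee", "bonobo", "human"}),
            }
        )


class TestClustering:
    def test_identical_columns_merge_at_height_zero(self):
        m = toy_matrix({"a": [1, 2, 3], "b": [1, 2, 3], "c": [9, 9, 9]})
        tree = cluster_species(m)
        first = tree.merges[0]
        assert first[2] == 0.0
        assert {tree.labels[first[0]], tree.labels[first[1]]} == {"a", "b"}

    def test_close_pair_merges_first(self):
        # c is consistently extreme, a and b nearly identical
        m = toy_matrix({"a": [10, 20, 30], "b": [11, 20, 30], "c": [500, 600, 700]})
        tree = cluster_species(m)
        first = tree.merges[0]
        assert {tree.labels[first[0]], tree.labels[first[1]]} == {"a", "b"}

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            cluster_species(toy_matrix({"a": [1, 2]}))

    def test_cut_block_counts_and_extremes(self):
        m = toy_matrix({c: list(np.arange(3) * i) for i, c in enumerate("abcde")})
        tree = cluster_species(m)
        for k in range(1, 6):
            assert cut(tree, k).n_clusters == k
        assert cut(tree, 1).blocks() == frozenset({frozenset("abcde")})
        assert cut(tree, 5).n_clusters == 5
        with pytest.raises(ValueError):
            cut(tree, 0)
        with pytest.raises(ValueError):
            cut(tree, 6)

    def test_cuts_are_nested(self, mono):
        tree = cluster_species(mono)
        parts = {k: cut(tree, k) for k in range(1, 10)}
        for k in range(1, 9):
            coarse, fine = parts[k], parts[k + 1]
            for block in fine.blocks():
                assert any(block <= b for b in coarse.blocks())

    def test_complete_linkage_heights_monotone(self, mono):
        tree = cluster_species(mono)
        heights = [h for _, _, h in tree.merges]
        assert all(a <= b for a, b in zip(heights, heights[1:]))

    def test_cophenetic_bounds_input_distances(self, mono):
        tree = cluster_species(mono)
        features = mono.harmonize().values.rank(axis=1).to_numpy(float).T
        d = pdist(features)
        coph = hierarchy.cophenet(tree.linkage)
        assert np.all(coph >= d - 1e-9)

    def test_newick_export_parses(self, mono, tmp_path):
        import dendropy

        nwk = cluster_species(mono).to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert labels == set(mono.species)


class TestConcordance:
    def test_fixture_stratum_is_concordant(self, mono):
        flags = motif_concordance({("T", 10): mono})
        assert flags == {("T", 10): True}

    def test_planted_strata_concordant_null_strata_mostly_not(self, reference):
        spec = default_profile_spec()
        planted, _ = simulate_profiles(spec, 5)
        null_hits = 0
        n_null = 30
        rng = np.random.default_rng(99)
        for s in range(n_null):
            flat = pd.DataFrame(
                np.maximum(rng.normal(1000, 300, size=(23, 9)), 0).round(),
                index=spec.group_means.columns,
                columns=planted.species,
            )
            null = AbundanceMatrix(flat.astype(int))
            flags = motif_concordance({("AT", 8): null})
            null_hits += bool(flags[("AT", 8)])
        assert motif_concordance({("T", 10): planted})[("T", 10)] is True
        assert null_hits < n_null // 2

    def test_failing_stratum_does_not_block_others(self, mono):
        single = AbundanceMatrix(pd.DataFrame({"only": [1, 2]}, index=["1", "3"]))
        flags = motif_concordance({"bad": single, "good": mono})
        assert flags["bad"] is None
        assert flags["good"] is True


class TestAnova:
    def test_identical_columns_give_p_one(self):
        m = toy_matrix({"a": [5, 9, 13], "b": [5, 9, 13]})
        res = species_effect_anova(m, factor="species")
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_planted_species_effect_detected(self, rng):
        counts = {
            "a": rng.poisson(100, 12),
            "b": rng.poisson(100, 12),
            "c": rng.poisson(4000, 12),
        }
        res = species_effect_anova(toy_matrix(counts), factor="species")
        assert res.p_value < 1e-6

    def test_one_way_repeated_measures_design(self, mono):
        res = species_effect_anova(mono, design="one_way_rm", factor="cluster")
        assert 0 < res.p_value < 4e-5
        assert res.design == "one_way_rm"

    def test_single_level_factor_rejected(self):
        m = toy_matrix({"a": [1, 2]})
        with pytest.raises((DegenerateDesignError, ValueError)):
            species_effect_anova(m, factor="species")

    def test_constant_matrix_degenerate(self):
        m = toy_matrix({"a": [7, 7], "b": [7, 7]})
        with pytest.raises(DegenerateDesignError):
            species_effect_anova(m, design="one_way_rm", factor="species")

    def test_fixture_p_values_bounded(self, fixtures_by_category):
        for m in fixtures_by_category.values():
            res = species_effect_anova(m)
            assert res.p_value <= 4e-5
            assert res.statistic > 0
            assert res.df_effect == 2


class TestNonparametric:
    def test_identical_columns_no_effect(self):
        m = toy_matrix({"a": [5, 9, 13], "b": [5, 9, 13]})
        res = species_effect_nonparametric(m, factor="species")
        assert res.p_value == pytest.approx(1.0)

    def test_planted_effect_detected(self, rng):
        counts = {c: rng.poisson(mu, 15) for c, mu in
                  [("a", 100), ("b", 110), ("c", 5000)]}
        res = species_effect_nonparametric(toy_matrix(counts), factor="species")
        assert res.p_value < 1e-4

    def test_agrees_with_anova_on_fixtures(self, fixtures_by_category):
        for m in fixtures_by_category.values():
            assert species_effect_nonparametric(m).p_value <= 4e-5

    def test_kruskal_fallback_with_single_block(self):
        m = toy_matrix({"a": [1], "b": [50]}, index=["1"])
        res = species_effect_nonparametric(m, factor="species")
        assert res.design == "kruskal"


class TestSummaries:
    def test_single_row_collapses_to_value(self):
        m = toy_matrix({"a": [4], "b": [9]}, index=["1"])
        s = abundance_summaries(m)
        assert (s.loc["a"] == 4).all()
        assert (s.loc["b"] == 9).all()

    def test_structural_zeros_excluded(self, mono):
        s = abundance_summaries(mono)
        # rat's minimum over existing chromosomes is far above 0
        assert s.loc["rat", "min"] > 0


class TestGreatApeOutlier:
    def test_human_most_distant_in_trinucleotide(self, tri):
        d = great_ape_outlier(tri)["mean_distance_to_other_great_apes"]
        assert d["human"] > d.drop("human").max()
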