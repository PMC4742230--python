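import itertools
import math

import numpy as np
import pytest

from cobel.great_enrichment import (
    GeneModel,
    GreatConfig,
    Ontology,
    basal_plus_extension_domains,
    bh_fdr,
    binomial_region_test,
    enrich,
    hypergeometric_gene_test,
    rank_and_select_top,
    related_term_group,
    term_genome_fraction,
)


class TestRegulatoryDomains:
    def test_lone_gene_extends_one_megabase(self):
        genes = [GeneModel("G1", "chr1", 5_000_000, "+")]
        (d,) = basal_plus_extension_domains(genes, {"chr1": 10_000_000})
        assert (d.basal_start, d.basal_end) == (4_995_000, 5_001_000)
        assert (d.start, d.end) == (3_995_000, 6_001_000)

    def test_neighbors_stop_extension_at_basal_boundary(self):
        genes = [
            GeneModel("G1", "chr1", 1_000_000, "+"),
            GeneModel("G2", "chr1", 1_100_000, "+"),
        ]
        domains = {
            d.gene: d
            for d in basal_plus_extension_domains(genes, {"chr1": 10_000_000})
        }
        # G2 basal = [1,095,000, 1,101,000); G1 extends right up to it
        assert domains["G1"].end == 1_095_000
        # G1 basal ends 1,001,000; G2 extends left down to it
        assert domains["G2"].start == 1_001_000

    def test_clipped_at_chromosome_start(self):
        genes = [GeneModel("G1", "chr1", 1000, "+")]
        (d,) = basal_plus_extension_domains(genes, {"chr1": 100_000})
        assert d.basal_start == 0 and d.start == 0

    def test_minus_strand_basal_mirrored(self):
        genes = [GeneModel("G1", "chr1", 500_000, "-")]
        (d,) = basal_plus_extension_domains(genes, {"chr1": 1_000_000})
        assert d.basal_end - 500_000 == pytest.approx(5001, abs=1)
        assert 500_000 - d.basal_start == pytest.approx(999, abs=1)

    def test_tss_beyond_chromosome_raises(self):
        with pytest.raises(ValueError):
            basal_plus_extension_domains(
                [GeneModel("G1", "chr1", 200, "+")], {"chr1": 100}
            )

    def test_basal_always_inside_extended(self):
        rng = np.random.default_rng(0)
        genes = [
            GeneModel(f"G{i}", "chr1", int(t), "+" if rng.random() < 0.5 else "-")
            for i, t in enumerate(sorted(rng.integers(10_000, 990_000, size=20)))
        ]
        for d in basal_plus_extension_domains(genes, {"chr1": 1_000_000}):
            assert d.start <= d.basal_start <= d.basal_end <= d.end


def toy_ontology():
    """root -> mid -> leaf chain plus a diamond (d1, d2 both under root,
    leaf_d under both)."""
    edges = [
        ("mid", "root"),
        ("leaf", "mid"),
        ("d1", "root"),
        ("d2", "root"),
        ("leaf_d", "d1"),
        ("leaf_d", "d2"),
    ]
    annotations = {
        "leaf": {"A", "B"},
        "mid": {"C"},
        "leaf_d": {"D"},
        "d1": set(),
        "d2": {"E"},
    }
    return Ontology(edges, annotations)


class TestOntology:
    def test_related_term_group(self):
        onto = toy_ontology()
        assert related_term_group("leaf", onto) == {"leaf"}
        assert related_term_group("root", onto) == {
            "root",
            "mid",
            "leaf",
            "d1",
            "d2",
            "leaf_d",
        }
        # diamond: leaf_d reachable twice, counted once
        assert related_term_group("d1", onto) == {"d1", "leaf_d"}

    def test_propagated_annotation_supersets(self):
        onto = toy_ontology()
        assert onto.genes("leaf") == {"A", "B"}
        assert onto.genes("mid") == {"A", "B", "C"}
        assert onto.genes("root") >= onto.genes("mid")

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            Ontology([("a", "b"), ("b", "a")], {})

    def test_unknown_term_raises(self):
        with pytest.raises(KeyError):
            toy_ontology().descendants("nope")


class TestTermGenomeFraction:
    def _domains(self):
        genes = [
            GeneModel("A", "chr1", 10_000, "+"),
            GeneModel("B", "chr1", 60_000, "+"),
        ]
        return basal_plus_extension_domains(
            genes, {"chr1": 100_000}, GreatConfig(max_extension=1000)
        )

    def test_no_annotated_genes_zero(self):
        onto = toy_ontology()
        assert term_genome_fraction("d1", onto, [], 100_000) == 0.0

    def test_disjoint_domains_sum(self):
        onto = Ontology([], {"t": {"A", "B"}})
        domains = self._domains()
        total = sum(d.end - d.start for d in domains)
        assert term_genome_fraction("t", onto, domains, 100_000) == pytest.approx(
            total / 100_000
        )

    def test_overlap_counted_once(self):
        from cobel.great_enrichment import RegulatoryDomain

        onto = Ontology([], {"t": {"A", "B"}})
        domains = [
            RegulatoryDomain("A", "chr1", 0, 0, 1000, 3000),
            RegulatoryDomain("B", "chr1", 0, 0, 2500, 4000),
        ]
        assert term_genome_fraction("t", onto, domains, 100_000) == pytest.approx(
            3000 / 100_000
        )

    def test_ancestor_fraction_at_least_descendant(self):
        onto = toy_ontology()
        genes = [
            GeneModel(s, "chr1", 10_000 + 20_000 * i, "+")
            for i, s in enumerate("ABCDE")
        ]
        domains = basal_plus_extension_domains(genes, {"chr1": 200_000})
        for term in ("leaf", "mid"):
            f_child = term_genome_fraction(term, onto, domains, 200_000)
            f_root = term_genome_fraction("root", onto, domains, 200_000)
            assert f_root >= f_child


class TestBinomialRegionTest:
    def test_worked_cardiac_output_numbers(self):
        p_value, fold, expected = binomial_region_test(6321, 57, 0.0045)
        assert round(expected) == 28
        assert round(fold, 2) == 2.00
        assert p_value < 1e-5

    def test_zero_observed_full_tail(self):
        p_value, fold, _ = binomial_region_test(10, 0, 0.3)
        assert p_value == pytest.approx(1.0)
        assert fold == 0.0

    def test_tail_equals_enumeration(self):
        n, p, k = 10, 0.3, 7
        expected_tail = sum(
            math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
        )
        p_value, _, _ = binomial_region_test(n, k, p)
        assert p_value == pytest.approx(expected_tail)

    def test_monotone_decreasing_in_k(self):
        values = [binomial_region_test(50, k, 0.1)[0] for k in range(0, 51)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_fold_expected_consistency(self):
        _, fold, expected = binomial_region_test(100, 17, 0.07)
        assert fold * expected == pytest.approx(17)

    def test_degenerate_p_zero(self):
        p_value, fold, _ = binomial_region_test(5, 3, 0.0)
        assert p_value == 0.0 and math.isinf(fold)


class TestHypergeometricGeneTest:
    def test_zero_hits_is_one(self):
        assert hypergeometric_gene_test(10, 5, 4, 0) == pytest.approx(1.0)

    def test_closed_form(self):
        # C(5,4)C(5,0)/C(10,4) = 5/210
        assert hypergeometric_gene_test(10, 5, 4, 4) == pytest.approx(5 / 210)

    def test_matches_enumeration_on_small_instances(self):
        for N, K, n_hit in [(8, 3, 4), (7, 4, 3), (6, 2, 5)]:
            population = list(range(N))
            annotated = set(range(K))
            for k_hit in range(0, min(K, n_hit) + 1):
                count = sum(
                    1
                    for draw in itertools.combinations(population, n_hit)
                    if len(set(draw) & annotated) >= k_hit
                )
                expected = count / math.comb(N, n_hit)
                assert hypergeometric_gene_test(N, K, n_hit, k_hit) == pytest.approx(
                    expected
                )

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            hypergeometric_gene_test(10, 5, 4, 5)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.01])[0] == pytest.approx(0.01)

    def test_step_up_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 1.0])
        assert np.allclose(q, [0.04, 0.04, 0.04, 1.0])

    def test_all_equal(self):
        q = bh_fdr([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_order_preserving(self):
        rng = np.random.default_rng(2)
        p = rng.random(30)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestEnrichAndRank:
    def _setup(self):
        rng = np.random.default_rng(3)
        genes = [
            GeneModel(f"G{i}", "chr1", 20_000 * (i + 1), "+") for i in range(10)
        ]
        onto = Ontology(
            [("t1", "root"), ("t2", "root"), ("t3", "root")],
            {
                "t1": {"G0", "G1", "G2"},
                "t2": {"G3", "G4"},
                "t3": {"G5", "G6", "G7", "G8", "G9"},
            },
        )
        chrom_lengths = {"chr1": 400_000}
        return genes, onto, chrom_lengths

    def test_planted_signal_recovered_matches_brute_force(self):
        genes, onto, chrom_lengths = self._setup()
        # pile regions onto t1's basal domains
        regions = []
        for tss in (20_000, 40_000, 60_000):
            regions += [("chr1", tss - 100 + i * 37, tss - 92 + i * 37) for i in range(6)]
        df = enrich(regions, genes, chrom_lengths, onto)
        top = rank_and_select_top(df)
        assert top is not None and top["term"] == "t1"
        # brute-force the ranking rule over the result frame
        passing = df[(df.binom_q <= 0.05) & (df.hyper_q <= 0.05) & (df.fold >= 2)]
        best = min(
            passing.itertuples(), key=lambda r: (r.binom_p, -r.fold, r.term)
        )
        assert best.term == top["term"]

    def test_no_passing_term_returns_none(self):
        genes, onto, chrom_lengths = self._setup()
        rng = np.random.default_rng(4)
        starts = rng.integers(0, 399_000, size=5)
        regions = [("chr1", int(s), int(s) + 8) for s in starts]
        df = enrich(regions, genes, chrom_lengths, onto)
        top = rank_and_select_top(df)
        if top is not None:  # random placement may accidentally enrich
            assert top["binom_q"] <= 0.05
        df_empty = enrich([], genes, chrom_lengths, onto)
        assert rank_and_select_top(df_empty) is None

    def test_k_le_n_and_expected_consistency(self):
        genes, onto, chrom_lengths = self._setup()
        regions = [("chr1", 19_000 + i * 50, 19_008 + i * 50) for i in range(20)]
        df = enrich(regions, genes, chrom_lengths, onto)
        assert (df.k <= df.n).all()
        nonzero = df[df.expected > 0]
        assert np.allclose(nonzero.fold * nonzero.expected, nonzero.k)
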