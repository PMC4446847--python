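import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from simmod.errors import InputError
from simmod.enrichment import (
    AnnotationSet,
    OntologyDAG,
    enrich_partition,
    enrichment_score,
    holm_adjust,
    hypergeom_upper_tail,
    parent_child_p,
    summarize_enrichment,
)
from simmod.multiplex import Partition


def brute_force_upper_tail(k: int, n_m: int, K: int, N: int) -> float:
    """Exact integer-arithmetic mass summation of P(X >= k)."""
    total = 0
    for i in range(k, min(n_m, K) + 1):
        total += math.comb(K, i) * math.comb(N - K, n_m - i)
    return total / math.comb(N, n_m)


CHAIN_DAG = OntologyDAG({
    "root": frozenset(),
    "A": frozenset({"root"}),
    "B": frozenset({"A"}),
})


def chain_annotations() -> AnnotationSet:
    genes = [f"g{i}" for i in range(10)]
    direct = {g: {"root"} for g in genes}
    for g in ("g0", "g1", "g2"):
        direct[g] = {"B"}
    for g in ("g3", "g4"):
        direct[g] = {"A"}
    return AnnotationSet.from_direct(direct, CHAIN_DAG, population=genes)


class TestHypergeomUpperTail:
    def test_worked_case(self):
        assert hypergeom_upper_tail(5, 5, 5, 20) == pytest.approx(
            1 / 15504, rel=1e-12)

    def test_k_zero_is_certain(self):
        assert hypergeom_upper_tail(0, 3, 5, 20) == 1.0

    def test_saturated_counts_are_certain(self):
        assert hypergeom_upper_tail(7, 7, 7, 7) == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(InputError, match="inconsistent"):
            hypergeom_upper_tail(6, 5, 5, 20)

    def test_agrees_with_brute_force_small_grid(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n_m in range(N + 1):
                    for k in range(min(n_m, K) + 1):
                        assert hypergeom_upper_tail(k, n_m, K, N) == pytest.approx(
                            brute_force_upper_tail(k, n_m, K, N), rel=1e-9
                        ), (k, n_m, K, N)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]) == [0.03]

    def test_two_value_step_down(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_capped_at_one(self):
        assert holm_adjust([0.6, 0.7]) == [1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError, match="outside"):
            holm_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_monotone_and_never_below_raw(self, pvals):
        adjusted = holm_adjust(pvals)
        for raw, adj in zip(pvals, adjusted):
            assert adj >= raw - 1e-15
            assert 0.0 <= adj <= 1.0
        order = sorted(range(len(pvals)), key=lambda i: pvals[i])
        ranked = [adjusted[i] for i in order]
        assert all(a <= b + 1e-15 for a, b in zip(ranked, ranked[1:]))

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=15))
    def test_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        _, expected, _, _ = multipletests(pvals, method="holm")
        assert holm_adjust(pvals) == pytest.approx(list(expected), rel=1e-12)


class TestEnrichmentScore:
    def test_proportional_is_one(self):
        assert enrichment_score(2, 8, 5, 20) == pytest.approx(1.0)

    def test_worked_case(self):
        assert enrichment_score(5, 5, 5, 20) == pytest.approx(4.0)

    def test_zero_count_is_zero(self):
        assert enrichment_score(0, 5, 5, 20) == 0.0

    def test_zero_population_count_rejected(self):
        with pytest.raises(InputError):
            enrichment_score(0, 5, 0, 20)


class TestOntologyDAG:
    def test_roots_and_ancestors(self):
        assert CHAIN_DAG.roots == {"root"}
        assert CHAIN_DAG.ancestors("B") == {"A", "root"}

    def test_cycle_rejected(self):
        with pytest.raises(InputError, match="cycle"):
            OntologyDAG({"a": frozenset({"b"}), "b": frozenset({"a"})})

    def test_unknown_parent_rejected(self):
        with pytest.raises(InputError, match="unknown parent"):
            OntologyDAG({"a": frozenset({"zz"})})

    def test_from_obo(self, tmp_path):
        obo = tmp_path / "mini.obo"
        obo.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: root\n\n"
            "[Term]\nid: GO:0000002\nname: a\nis_a: GO:0000001 ! root\n\n"
            "[Term]\nid: GO:0000003\nname: b\nis_a: GO:0000002 ! a\n"
            "relationship: part_of GO:0000001 ! root\n",
            encoding="utf-8",
        )
        dag = OntologyDAG.from_obo(obo)
        assert dag.roots == {"GO:0000001"}
        assert dag.parents["GO:0000003"] == {"GO:0000002", "GO:0000001"}


class TestAnnotations:
    def test_propagation_to_ancestors(self):
        ann = chain_annotations()
        assert ann.gene_to_terms["g0"] == {"B", "A", "root"}
        assert ann.gene_to_terms["g3"] == {"A", "root"}
        assert ann.genes_annotated("A") == {"g0", "g1", "g2", "g3", "g4"}

    def test_gaf_parsing(self, tmp_path):
        gaf = tmp_path / "ann.gaf"
        rows = [
            "!gaf-version: 2.2",
            "DB\tg0\tS0\t\tB\tREF\tEXP\t\tP\t\t\tprotein\ttaxon:1\t0\tX",
            "DB\tg1\tS1\tNOT\tB\tREF\tEXP\t\tP\t\t\tprotein\ttaxon:1\t0\tX",
            "DB\tg2\tS2\t\tA\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:1\t0\tX",
        ]
        gaf.write_text("\n".join(rows) + "\n", encoding="utf-8")
        ann = AnnotationSet.from_gaf(
            gaf, CHAIN_DAG, population=["g0", "g1", "g2"], exclude_evidence=["IEA"]
        )
        assert set(ann.gene_to_terms) == {"g0"}  # NOT row and IEA row skipped

    def test_annotated_gene_outside_population_rejected(self):
        with pytest.raises(InputError, match="not in population"):
            AnnotationSet.from_direct({"gX": {"root"}}, CHAIN_DAG, population=["g0"])


class TestParentChild:
    def test_root_not_testable(self):
        ann = chain_annotations()
        assert parent_child_p("root", {"g0", "g1"}, ann, CHAIN_DAG) == 1.0

    def test_reduces_to_classic_when_parent_covers_population(self):
        """Term A's only parent is the root, which annotates every gene, so
        the conditional test equals the whole-population test."""
        ann = chain_annotations()
        module = frozenset({"g0", "g3", "g4", "g5"})
        expected = hypergeom_upper_tail(3, 4, 5, 10)  # A annotates g0..g4
        assert parent_child_p("A", module, ann, CHAIN_DAG) == pytest.approx(
            expected, rel=1e-12)

    def test_matches_subset_enumeration_oracle(self):
        """Exhaustive enumeration of the conditional null: draw the module's
        parent-annotated genes uniformly from the parent population and count
        outcomes with at least k term genes."""
        ann = chain_annotations()
        module = frozenset({"g0", "g1", "g3", "g5", "g7"})
        parent_pop = sorted(ann.genes_annotated("A"))  # g0..g4
        term_genes = ann.genes_annotated("B")          # g0, g1, g2
        n_prime = len(set(module) & set(parent_pop))   # 3
        k = len(module & term_genes)                   # 2
        hits = sum(
            1 for combo in itertools.combinations(parent_pop, n_prime)
            if len(set(combo) & term_genes) >= k
        )
        expected = hits / math.comb(len(parent_pop), n_prime)
        assert parent_child_p("B", module, ann, CHAIN_DAG) == pytest.approx(
            expected, rel=1e-12)


class TestEnrichPartition:
    def test_rare_term_module_is_enriched(self):
        ann = chain_annotations()
        partition = Partition({g: (1 if g in ("g0", "g1", "g2") else 2)
                               for g in ann.population})
        results = enrich_partition(partition, ann, CHAIN_DAG, method="classic")
        by = {(r.module, r.term): r for r in results}
        hit = by[(1, "B")]
        assert hit.enriched
        assert hit.raw_p == pytest.approx(
            hypergeom_upper_tail(3, 3, 3, 10), rel=1e-12)
        assert hit.score == pytest.approx((3 / 3) / (3 / 10))

    def test_single_module_partition_nothing_enriched(self):
        ann = chain_annotations()
        partition = Partition({g: 1 for g in ann.population})
        results = enrich_partition(partition, ann, CHAIN_DAG, method="classic")
        assert results  # terms are tested...
        assert all(r.raw_p == 1.0 for r in results)  # ...but never significant
        assert not any(r.enriched for r in results)

    def test_small_module_skipped_with_warning(self, caplog):
        ann = chain_annotations()
        partition = Partition({g: (3 if g == "g9" else (1 if g < "g5" else 2))
                               for g in ann.population})
        with caplog.at_level("WARNING"):
            results = enrich_partition(partition, ann, CHAIN_DAG)
        assert "skipped" in caplog.text
        assert all(r.module != 3 for r in results)

    def test_summary_reports_best_enriched_term(self):
        ann = chain_annotations()
        partition = Partition({g: (1 if g in ("g0", "g1", "g2") else 2)
                               for g in ann.population})
        results = enrich_partition(partition, ann, CHAIN_DAG, method="classic")
        summary = summarize_enrichment(results)
        assert summary["modules"][1]["best_term"] == "B"
        assert 0.0 < summary["enriched_module_fraction"] <= 1.0
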