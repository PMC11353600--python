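"""Exact hypergeometric upper tail and per-length-class GO
over-representation."""

import itertools
import math

import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from utrsurvey.enrichment import (
    EnrichmentError,
    EnrichmentResult,
    GOAnnotationSet,
    adjust_pvalues,
    enrich_by_length_class,
    hypergeom_upper_tail,
    read_gene2go,
    read_obo,
    top_terms,
)


def enumerate_upper_tail(k, K, n, N):
    """Independent oracle: enumerate all C(N, n) equally likely draws."""
    marked = set(range(K))
    total = hit = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hit += 1
    return hit / total if total else 1.0


class TestHypergeomUpperTail:
    def test_k_zero_is_certain(self):
        assert hypergeom_upper_tail(0, 5, 3, 20) == 1.0

    def test_two_of_two_in_four(self):
        # all C(4,2)=6 draws equally likely; only one contains both marked
        assert hypergeom_upper_tail(2, 2, 2, 4) == pytest.approx(1 / 6, rel=1e-12)

    def test_single_draw(self):
        assert hypergeom_upper_tail(1, 5, 1, 10) == pytest.approx(0.5, rel=1e-12)

    def test_exhaustive_small_universes(self):
        # every valid (k, K, n, N) with N <= 12 against the enumeration oracle
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(1, min(n, K) + 1):
                        expected = enumerate_upper_tail(k, K, n, N)
                        got = hypergeom_upper_tail(k, K, n, N)
                        assert got == pytest.approx(expected, rel=1e-12), \
                            (k, K, n, N)

    @settings(derandomize=True, max_examples=100)
    @given(st.data())
    def test_monotone_in_k_and_symmetric(self, data):
        N = data.draw(st.integers(2, 60))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        tails = [hypergeom_upper_tail(k, K, n, N)
                 for k in range(min(n, K) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))
        # swapping the class and term roles leaves the tail unchanged
        k = data.draw(st.integers(0, min(n, K)))
        assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
            hypergeom_upper_tail(k, n, K, N), rel=1e-9, abs=1e-300)

    def test_agrees_with_scipy_at_genome_scale(self):
        # independent cross-check on survey-sized counts
        for k, K, n, N in [(40, 400, 900, 30000), (3, 11, 500, 28000),
                           (120, 130, 5000, 40000)]:
            assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                float(scipy.stats.hypergeom.sf(k - 1, N, K, n)), rel=1e-9)

    def test_invalid_counts_error(self):
        with pytest.raises(EnrichmentError):
            hypergeom_upper_tail(3, 2, 5, 10)
        with pytest.raises(EnrichmentError):
            hypergeom_upper_tail(1, 11, 5, 10)
        with pytest.raises(EnrichmentError):
            hypergeom_upper_tail(-1, 2, 5, 10)


class TestAdjustment:
    def test_bh_monotone_and_bounded(self):
        p = [0.001, 0.01, 0.02, 0.5, 0.9, 0.04]
        q = adjust_pvalues(sorted(p), "BH")
        assert all(a <= b + 1e-15 for a, b in zip(q, q[1:]))
        assert all(pi <= qi <= 1 for pi, qi in zip(sorted(p), q))

    def test_bonferroni(self):
        assert adjust_pvalues([0.01, 0.3], "bonferroni") == [0.02, 0.6]


def toy_go(n_genes=100, term_genes=10, extra_terms=()):
    genes = [f"g{i}" for i in range(n_genes)]
    mapping = {g: set() for g in genes}
    for g in genes[:term_genes]:
        mapping[g].add("GO:T1")
    for term, members in extra_terms:
        for g in members:
            mapping[g].add(term)
    names = {"GO:T1": ("term one", "BP")}
    names.update({t: (t, "BP") for t, _ in extra_terms})
    return genes, GOAnnotationSet(mapping, names)


class TestEnrichByLengthClass:
    def test_exhaustive_sum_oracle(self):
        # N=100, K=10, class n=10 with k=5 annotated
        genes, go = toy_go()
        cls = set(genes[:5]) | set(genes[50:55])
        res = enrich_by_length_class({"c": cls}, go, genes)["c"]
        expected = sum(
            math.comb(10, i) * math.comb(90, 10 - i) for i in range(5, 11)
        ) / math.comb(100, 10)
        [r] = res
        assert (r.k, r.K, r.n, r.N) == (5, 10, 10, 100)
        assert r.p == pytest.approx(expected, rel=1e-12)

    def test_unannotated_class_yields_empty_list(self):
        genes, go = toy_go()
        res = enrich_by_length_class({"c": set(genes[20:30])}, go, genes)
        assert res["c"] == []

    def test_universal_term_has_p_one(self):
        genes, go = toy_go(term_genes=100)
        res = enrich_by_length_class({"c": set(genes[:7])}, go, genes)["c"]
        assert res[0].p == pytest.approx(1.0)

    def test_class_outside_universe_errors(self):
        genes, go = toy_go()
        with pytest.raises(EnrichmentError, match="outside the universe"):
            enrich_by_length_class({"c": {"ghost"}}, go, genes)

    def test_empty_universe_errors(self):
        _, go = toy_go()
        with pytest.raises(EnrichmentError, match="empty"):
            enrich_by_length_class({}, go, [])

    def test_results_sorted_by_p_then_term(self):
        genes, go = toy_go(extra_terms=[("GO:A2", [f"g{i}" for i in range(10)])])
        cls = set(genes[:10])
        res = enrich_by_length_class({"c": cls}, go, genes)["c"]
        # GO:A2 and GO:T1 annotate the same genes -> identical p; term order
        assert [r.term for r in res] == ["GO:A2", "GO:T1"]
        assert res[0].p == res[1].p

    def test_ancestor_propagation_counts_parents(self):
        mapping = {"g0": {"GO:CHILD"}, "g1": {"GO:PARENT"}, "g2": set()}
        names = {"GO:CHILD": ("c", "BP"), "GO:PARENT": ("p", "BP")}
        edges = {"GO:CHILD": {"GO:PARENT"}}
        go = GOAnnotationSet(mapping, names, edges)
        res = enrich_by_length_class(
            {"c": {"g0", "g1"}}, go, ["g0", "g1", "g2"], propagate=True
        )["c"]
        parent = next(r for r in res if r.term == "GO:PARENT")
        assert (parent.k, parent.K) == (2, 2)


class TestTopTerms:
    def _results(self, n):
        return [
            EnrichmentResult(f"GO:{i:07d}", "", "BP", 1, 5, 5, 50,
                             p=0.01 * (i + 1), q=0.05)
            for i in range(n)
        ]

    def test_takes_first_five(self):
        assert len(top_terms(self._results(7), 5)) == 5

    def test_short_list_passthrough(self):
        assert len(top_terms(self._results(3), 5)) == 3

    def test_m_below_one_errors(self):
        with pytest.raises(EnrichmentError):
            top_terms(self._results(3), 0)


class TestIO:
    def test_two_column_tsv(self):
        mapping = read_gene2go("g1\tGO:1\ng1\tGO:2\ng2\tGO:1\n")
        assert mapping == {"g1": {"GO:1", "GO:2"}, "g2": {"GO:1"}}

    def test_gaf(self):
        row = "\t".join(
            ["DB", "geneX", "sym", "", "GO:0006810", "ref", "IEA", "", "P",
             "", "", "protein", "taxon:4577", "20240101", "DB", "", ""]
        )
        mapping = read_gene2go("!gaf-version: 2.2\n" + row + "\n")
        assert mapping == {"geneX": {"GO:0006810"}}

    def test_obo_roundtrip_names_and_edges(self):
        obo = "\n".join([
            "format-version: 1.2", "",
            "[Term]", "id: GO:1", "name: root", "namespace: biological_process",
            "", "[Term]", "id: GO:2", "name: child",
            "namespace: biological_process", "is_a: GO:1 ! root", "",
        ])
        names, edges = read_obo(obo)
        assert names["GO:2"] == ("child", "BP")
        assert edges["GO:2"] == {"GO:1"}
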