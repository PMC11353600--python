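"""GO over-representation of UTR-containing genes by length class.

The test statistic is the exact upper-tail hypergeometric probability
P(X >= k) for k annotated genes observed in a class of n genes, drawn
from a universe of N genes of which K carry the term.  The tail sum is
computed from scratch in log space (lgamma-based binomial coefficients
with a log-sum-exp reduction), so it is stable for genome-scale counts
and exactly enumerable for small universes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

import pandas as pd
from statsmodels.stats.multitest import multipletests

NAMESPACES = {"BP": "biological_process", "MF": "molecular_function",
              "CC": "cellular_component"}
_NS_SHORT = {v: k for k, v in NAMESPACES.items()}


class EnrichmentError(ValueError):
    pass


@dataclass
class GOAnnotationSet:
    gene_to_terms: dict[str, set[str]]
    term_names: dict[str, tuple[str, str]]  # term -> (name, namespace short)
    ontology_edges: Optional[dict[str, set[str]]] = None  # term -> is_a parents

    def terms_in_namespace(self, namespace: str) -> Optional[set[str]]:
        """Terms of one namespace, or None when no names are loaded."""
        if not self.term_names:
            return None
        return {t for t, (_, ns) in self.term_names.items() if ns == namespace}

    def propagated(self) -> "GOAnnotationSet":
        """Close every gene's term set under is_a ancestors."""
        if not self.ontology_edges:
            return self
        cache: dict[str, set[str]] = {}

        def ancestors(term: str) -> set[str]:
            if term in cache:
                return cache[term]
            seen: set[str] = set()
            stack = list(self.ontology_edges.get(term, ()))
            while stack:
                parent = stack.pop()
                if parent not in seen:
                    seen.add(parent)
                    stack.extend(self.ontology_edges.get(parent, ()))
            cache[term] = seen
            return seen

        closed = {
            g: set().union(terms, *(ancestors(t) for t in terms))
            for g, terms in self.gene_to_terms.items()
        }
        return GOAnnotationSet(closed, self.term_names, self.ontology_edges)


@dataclass
class EnrichmentResult:
    term: str
    name: str
    namespace: str
    k: int
    n: int
    K: int
    N: int
    p: float
    q: float = float("nan")


def _log_comb(n: int, r: int) -> float:
    if r < 0 or r > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(r + 1) - math.lgamma(n - r + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N genes in the universe, K annotated with the term, n drawn (the length
    class), k annotated among the drawn.  Computed as a log-space sum of
    exact pmf terms; k = 0 returns 1 exactly.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v < 0:
            raise EnrichmentError(f"{name} must be non-negative, got {v}")
    if K > N or n > N:
        raise EnrichmentError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(n, K):
        raise EnrichmentError(f"k={k} exceeds min(n={n}, K={K})")
    if k == 0:
        return 1.0
    log_denom = _log_comb(N, n)
    log_terms = [
        _log_comb(K, i) + _log_comb(N - K, n - i) - log_denom
        for i in range(k, min(n, K) + 1)
    ]
    log_terms = [t for t in log_terms if t > -math.inf]
    if not log_terms:
        return 0.0
    m = max(log_terms)
    total = m + math.log(sum(math.exp(t - m) for t in log_terms))
    return min(1.0, math.exp(total))


def adjust_pvalues(pvals: Sequence[float], method: str = "BH") -> list[float]:
    """Multiple-testing adjustment within one family (one length class)."""
    if method == "none" or not len(pvals):
        return list(pvals)
    smethod = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if smethod is None:
        raise EnrichmentError(f"unknown adjustment method {method!r}")
    return list(multipletests(list(pvals), method=smethod)[1])


def enrich_by_length_class(
    class_members: Mapping[str, Iterable[str]],
    go: GOAnnotationSet,
    universe: Iterable[str],
    namespace: str = "BP",
    propagate: bool = False,
    adjust: str = "BH",
) -> dict[str, list[EnrichmentResult]]:
    """Per-class over-representation over every term with k >= 1.

    Results per class are sorted ascending by p, ties broken by term id;
    q-values are computed within each class.
    """
    universe = set(universe)
    if not universe:
        raise EnrichmentError("empty gene universe")
    if namespace not in NAMESPACES:
        raise EnrichmentError(f"unknown namespace {namespace!r}")
    for label, members in class_members.items():
        extra = set(members) - universe
        if extra:
            raise EnrichmentError(
                f"class {label!r} has genes outside the universe: "
                f"{sorted(extra)[:5]}"
            )

    work = go.propagated() if propagate else go
    allowed = work.terms_in_namespace(namespace)

    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for term in work.gene_to_terms.get(gene, ()):
            if allowed is not None and term not in allowed:
                continue
            term_genes.setdefault(term, set()).add(gene)

    N = len(universe)
    out: dict[str, list[EnrichmentResult]] = {}
    for label, members in class_members.items():
        members = set(members)
        n = len(members)
        # The adjustment family is every testable term (K >= 1 in the
        # universe); terms with k = 0 enter at p = 1 and are dropped from
        # the report afterwards.  Restricting the family to observed terms
        # would be selection before correction and inflates the per-class
        # false-discovery rate in small classes.
        results = []
        for term, genes in sorted(term_genes.items()):
            k = len(genes & members)
            K = len(genes)
            name, ns = work.term_names.get(term, ("", namespace))
            results.append(
                EnrichmentResult(
                    term=term, name=name, namespace=ns,
                    k=k, n=n, K=K, N=N,
                    p=hypergeom_upper_tail(k, K, n, N) if k else 1.0,
                )
            )
        for r, q in zip(results, adjust_pvalues([r.p for r in results], adjust)):
            r.q = q
        observed = [r for r in results if r.k >= 1]
        observed.sort(key=lambda r: (r.p, r.term))
        out[label] = observed
    return out


def top_terms(
    results: Sequence[EnrichmentResult], m: int = 5
) -> list[EnrichmentResult]:
    """First m results of an already p-sorted list (ties by term id)."""
    if m < 1:
        raise EnrichmentError(f"m must be >= 1, got {m}")
    return list(results[:m])


def results_table(per_class: Mapping[str, Sequence[EnrichmentResult]]) -> pd.DataFrame:
    rows = [
        {"class": label, "term": r.term, "name": r.name,
         "namespace": r.namespace, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
         "p": r.p, "q": r.q}
        for label, results in per_class.items()
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["class", "term", "name", "namespace",
                       "k", "n", "K", "N", "p", "q"]
    )


# ---------------------------------------------------------------------------
# I/O: gene->GO mappings (2-column TSV or GAF 2.x) and OBO ontologies.

def read_gene2go(stream: Union[str, TextIO]) -> dict[str, set[str]]:
    """Read a gene->term mapping from 2-column TSV or GAF 2.x text.

    GAF lines (detected by the ``!gaf-version`` header or 15+ columns) use
    column 2 as the gene id and column 5 as the term.
    """
    text = stream if isinstance(stream, str) else stream.read()
    mapping: dict[str, set[str]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("!") or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) >= 15:  # GAF 2.x
            gene, term = fields[1], fields[4]
        elif len(fields) >= 2:
            gene, term = fields[0], fields[1]
        else:
            raise EnrichmentError(f"unparseable gene->GO line: {line!r}")
        mapping.setdefault(gene, set()).add(term)
    return mapping


def read_obo(stream: Union[str, TextIO]) -> tuple[dict[str, tuple[str, str]],
                                                  dict[str, set[str]]]:
    """Read term names/namespaces and is_a edges from OBO 1.2 text.

    Returns (term_names, ontology_edges) in the shapes GOAnnotationSet
    expects.  Uses obonet; namespaces come back as BP/MF/CC.
    """
    import io

    import obonet

    handle = io.StringIO(stream) if isinstance(stream, str) else stream
    graph = obonet.read_obo(handle)
    names: dict[str, tuple[str, str]] = {}
    edges: dict[str, set[str]] = {}
    for term, data in graph.nodes(data=True):
        ns = _NS_SHORT.get(data.get("namespace", ""), "BP")
        names[term] = (data.get("name", ""), ns)
        parents = set(data.get("is_a", []))
        if parents:
            edges[term] = parents
    return names, edges
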