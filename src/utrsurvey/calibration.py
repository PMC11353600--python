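"""Replicated enrichment calibration on synthetic GO universes.

Two arms, both holding the gene/length-class structure fixed and
resampling the GO annotation per replicate (the randomness under study is
the annotation draw):

* null: all enrichment odds 1; how often does any length class report a
  BH q below 0.05?  This estimates the family false-alarm rate of the
  whole per-class procedure.
* power: one term planted into one class at a given odds ratio; how often
  does that term rank first by p in its class?
"""

from __future__ import annotations

from dataclasses import replace
from .enrichment import GOAnnotationSet, enrich_by_length_class, read_gene2go
from .simulate import (
    GeneratorParams,
    GOParams,
    SyntheticTruth,
    generate_annotation,
    generate_go_universe,
)
from .utr import BIN_LABELS


def _fixture_truth(n_genes: int, seed: int) -> tuple[GeneratorParams,
                                                     SyntheticTruth]:
    params = GeneratorParams(n_genes=n_genes, seed=seed)
    bundle = generate_annotation(params, with_sequences=False)
    return params, bundle.truth


def enrich_from_truth(
    truth: SyntheticTruth,
    mapping: dict[str, set[str]],
    adjust: str = "BH",
) -> dict:
    """Run per-class enrichment with the package's default universe:
    genes with a 5' UTR and at least one annotation."""
    annotated = {g for g, terms in mapping.items() if terms}
    universe = {
        g for g, info in truth.genes.items() if info["bin_5"]
    } & annotated
    classes = {
        label: {g for g in universe if truth.genes[g]["bin_5"] == label}
        for label in BIN_LABELS
    }
    go = GOAnnotationSet(mapping, term_names={})
    return enrich_by_length_class(classes, go, universe, adjust=adjust)


def null_rejection_rate(
    n_replicates: int = 200,
    n_genes: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null replicates where min per-class BH q < alpha."""
    params, truth = _fixture_truth(n_genes, seed)
    fired = 0
    for rep in range(n_replicates):
        tsv, _ = generate_go_universe(params, truth, seed=seed * 100003 + rep)
        results = enrich_from_truth(truth, read_gene2go(tsv))
        qmin = min(
            (r.q for rs in results.values() for r in rs), default=1.0
        )
        if qmin < alpha:
            fired += 1
    return fired / n_replicates


def planted_top_rank_rate(
    n_replicates: int = 100,
    n_genes: int = 500,
    odds: float = 20.0,
    planted_class: str = "1-500",
    planted_term: str = "GO:1000003",
    seed: int = 0,
) -> float:
    """Fraction of replicates where the planted term is ranked first by p
    in its length class."""
    params, truth = _fixture_truth(n_genes, seed)
    params = replace(
        params,
        go=GOParams(planted=[(planted_class, planted_term, odds)]),
    )
    top = 0
    for rep in range(n_replicates):
        tsv, _ = generate_go_universe(params, truth, seed=seed * 100019 + rep)
        results = enrich_from_truth(truth, read_gene2go(tsv))
        ranked = results.get(planted_class, [])
        if ranked and ranked[0].term == planted_term:
            top += 1
    return top / n_replicates
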