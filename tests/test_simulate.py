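"""The synthetic fixture generator: determinism, truth consistency, and
the statistical structure it plants."""

import numpy as np
import pytest

from utrsurvey.annotation import parse_annotation, select_longest_transcript
from utrsurvey.cisscan import Motif, scan_motifs
from utrsurvey.enrichment import GOAnnotationSet, read_gene2go, read_obo
from utrsurvey.simulate import (
    GeneratorParams,
    GOParams,
    SimulationError,
    generate_annotation,
    generate_go_universe,
    implant_motifs,
)
from utrsurvey.utr import genome_utr_summary, infer_utrs


class TestGenerateAnnotation:
    def test_same_seed_byte_identical(self):
        a = generate_annotation(GeneratorParams(n_genes=40, seed=5))
        b = generate_annotation(GeneratorParams(n_genes=40, seed=5))
        assert a.gtf == b.gtf
        assert a.gtf_explicit == b.gtf_explicit
        assert a.mrna_fasta == b.mrna_fasta
        assert a.genome_fasta == b.genome_fasta
        assert a.truth.to_json() == b.truth.to_json()

    def test_different_seed_differs(self):
        a = generate_annotation(GeneratorParams(n_genes=40, seed=5),
                                with_sequences=False)
        b = generate_annotation(GeneratorParams(n_genes=40, seed=6),
                                with_sequences=False)
        assert a.gtf != b.gtf

    def test_truth_lengths_recovered_from_gtf(self, small_bundle_noseq):
        """Re-parsing the emitted GTF reproduces every gene's true UTR
        lengths exactly."""
        ann = parse_annotation(small_bundle_noseq.gtf)
        truth = small_bundle_noseq.truth
        assert ann.n_genes == len(truth.genes)
        for gene in ann.genes:
            tx = select_longest_transcript(gene)
            pair = infer_utrs(tx)
            info = truth.genes[gene.gene_id]
            assert tx.transcript_id == info["transcript_id"]
            assert pair.five_len == info["utr5_len"]
            assert pair.three_len == info["utr3_len"]
            assert tx.cds_length == info["cds_len"]

    def test_bin_counts_recovered_exactly(self, small_bundle_noseq):
        summary = genome_utr_summary(parse_annotation(small_bundle_noseq.gtf))
        assert summary.bins_5.counts == small_bundle_noseq.truth.bin_counts("5")
        assert summary.bins_3.counts == small_bundle_noseq.truth.bin_counts("3")

    def test_no_utr_genome_has_zero_fraction(self):
        params = GeneratorParams(n_genes=30, p_no_utr5=1.0, p_no_utr3=1.0,
                                 seed=2)
        bundle = generate_annotation(params, with_sequences=False)
        summary = genome_utr_summary(parse_annotation(bundle.gtf))
        assert summary.utr_fraction == 0.0

    def test_explicit_variant_same_utrs(self, small_bundle_noseq):
        derived = genome_utr_summary(parse_annotation(small_bundle_noseq.gtf))
        explicit = genome_utr_summary(
            parse_annotation(small_bundle_noseq.gtf_explicit),
            mode="prefer_explicit",
        )
        assert derived.bins_5.counts == explicit.bins_5.counts
        assert derived.utr_fraction == explicit.utr_fraction

    def test_mrna_lengths_match_truth(self, small_bundle):
        from Bio import SeqIO
        import io

        lengths = {
            rec.id: len(rec.seq)
            for rec in SeqIO.parse(io.StringIO(small_bundle.mrna_fasta), "fasta")
        }
        for gid, info in small_bundle.truth.genes.items():
            expected = info["utr5_len"] + info["cds_len"] + info["utr3_len"]
            assert lengths[info["transcript_id"]] == expected

    def test_multi_transcript_genes_present(self, small_bundle_noseq):
        ann = parse_annotation(small_bundle_noseq.gtf)
        n_multi = sum(1 for g in ann.genes if len(g.transcripts) > 1)
        assert n_multi > 0
        # secondary isoforms are strictly shorter, so selection is exercised
        for g in ann.genes:
            if len(g.transcripts) > 1:
                rep = select_longest_transcript(g)
                assert rep.transcript_id.endswith("T01")

    def test_strand_balance_and_bin_convergence(self):
        """At n=5000 the sampled strand ratio and bin proportions fall
        within 3-sigma binomial bounds of the parameters."""
        params = GeneratorParams(n_genes=5000, seed=77)
        bundle = generate_annotation(params, with_sequences=False)
        genes = bundle.truth.genes.values()
        n = len(genes)
        n_plus = sum(1 for g in genes if g["strand"] == "+")
        sigma = np.sqrt(n * 0.5 * 0.5)
        assert abs(n_plus - 0.5 * n) < 3 * sigma

        with_utr5 = [g for g in genes if g["bin_5"]]
        counts = bundle.truth.bin_counts("5")
        total = sum(counts)
        assert total == len(with_utr5)
        for c, p in zip(counts, params.bin_probs_5):
            sd = np.sqrt(total * p * (1 - p))
            assert abs(c - total * p) < 3 * sd + 1

    def test_invalid_params_rejected(self):
        with pytest.raises(SimulationError):
            GeneratorParams(bin_probs_5=(0.5, 0.5, 0.5, 0.5)).validate()
        with pytest.raises(SimulationError):
            GeneratorParams(p_no_utr5=1.5).validate()
        with pytest.raises(SimulationError):
            GeneratorParams(n_genes=0).validate()


class TestGOUniverse:
    def test_annotation_rates_near_base_rate(self, small_bundle_noseq):
        params = GeneratorParams(n_genes=300, seed=12)
        tsv, _ = generate_go_universe(params, small_bundle_noseq.truth, seed=40)
        mapping = read_gene2go(tsv)
        n_pairs = sum(len(v) for v in mapping.values())
        expected = 300 * params.go.n_terms * params.go.base_rate
        sd = np.sqrt(300 * params.go.n_terms * params.go.base_rate
                     * (1 - params.go.base_rate))
        assert abs(n_pairs - expected) < 4 * sd

    def test_planted_term_over_annotated_in_class(self, small_bundle_noseq):
        params = GeneratorParams(
            n_genes=300, seed=12,
            go=GOParams(planted=[("1-500", "GO:1000003", 20.0)]),
        )
        truth = small_bundle_noseq.truth
        tsv, _ = generate_go_universe(params, truth, seed=41)
        mapping = read_gene2go(tsv)
        in_class = [g for g, i in truth.genes.items() if i["bin_5"] == "1-500"]
        out_class = [g for g, i in truth.genes.items() if i["bin_5"] != "1-500"]
        rate_in = np.mean(["GO:1000003" in mapping.get(g, ()) for g in in_class])
        rate_out = np.mean(["GO:1000003" in mapping.get(g, ()) for g in out_class])
        assert rate_in > 3 * rate_out

    def test_obo_parses_with_bp_namespace(self, small_bundle_noseq):
        params = GeneratorParams(n_genes=300, seed=12)
        _, obo = generate_go_universe(params, small_bundle_noseq.truth, seed=42)
        names, edges = read_obo(obo)
        assert all(ns == "BP" for _, ns in names.values())
        assert any(edges.values())
        # propagation over the emitted chain terminates and only adds terms
        go = GOAnnotationSet({"g": {"GO:1000002"}}, names, edges)
        closed = go.propagated().gene_to_terms["g"]
        assert {"GO:1000002", "GO:1000001", "GO:1000000",
                "GO:2000000"} <= closed


class TestImplantMotifs:
    def test_scan_recovers_implants(self):
        params = GeneratorParams(
            n_genes=20, seed=9,
            motif_implants=[("STRE", "AGGGG", 1.5)],
        )
        bundle = generate_annotation(params)
        fasta, truth = implant_motifs(bundle.utr5_fasta, params)
        hits = []
        import io
        from Bio import SeqIO

        for rec in SeqIO.parse(io.StringIO(fasta), "fasta"):
            hits.extend(
                (rec.id, h.position, h.strand)
                for h in scan_motifs(str(rec.seq), [Motif("STRE", "AGGGG")])
            )
        implanted = {
            (t["sequence_id"], t["position"], t["strand"])
            for t in truth.motif_implants
        }
        assert implanted <= set(hits)

    def test_background_hit_rate_matches_poisson_expectation(self):
        """On uniform sequence, 5-mer hits per strand occur at rate
        (L-4)/4^5; the mean over 100 seeded sequences must sit within 3
        sigma of the analytic expectation."""
        rng = np.random.default_rng(123)
        L, w = 800, 5
        motif = Motif("m", "AGGGG")
        counts = []
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=L))
            counts.append(len(scan_motifs(seq, [motif], strands="plus")))
        expected = (L - w + 1) / 4 ** w
        sd = np.sqrt(expected / 100)  # Poisson, mean of 100 replicates
        assert abs(np.mean(counts) - expected) < 3 * sd

    def test_empty_fasta_errors(self):
        with pytest.raises(SimulationError, match="empty"):
            implant_motifs("", GeneratorParams())

    def test_sequence_too_short_errors(self):
        params = GeneratorParams(
            seed=1, motif_implants=[("long", "ACGTACGTACGT", 50.0)]
        )
        with pytest.raises(SimulationError):
            implant_motifs(">s\nACG\n", params)
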