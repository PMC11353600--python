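"""Synthetic annotation / sequence / GO / motif fixtures with stored truth.

The generator emulates the statistical structure a plant UTR survey
assumes: a multi-gene single-chromosome annotation with controllable
UTR-length gradient proportions on both sides, multi-transcript genes (so
longest-transcript selection is exercised), both strands, 0-2 introns per
transcript, a GO universe with optionally planted class-enriched terms,
and uniform-composition UTR sequences with implanted motif words.  Every
output is deterministic given (params, seed).

Default parameters are fixed to the study conditions of the maize B73
survey this package reproduces: gradient proportions 87.64/9.87/2.30/0.19%
(5') and 78.46/17.03/4.04/0.47% (3'), and a CDS length range chosen so the
expected UTR base fraction is ~24.7% (see docs/methods.md for the
arithmetic).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .utr import BIN_LABELS

_BIN_RANGES = ((1, 500), (501, 1000), (1001, 2000), (2001, None))


class SimulationError(ValueError):
    pass


@dataclass
class GOParams:
    n_terms: int = 30
    base_rate: float = 0.08
    #: planted (length-class label, term id, enrichment odds) triples
    planted: list[tuple[str, str, float]] = field(default_factory=list)


@dataclass
class GeneratorParams:
    n_genes: int = 1000
    p_multi_transcript: float = 0.3
    bin_probs_5: tuple[float, float, float, float] = (0.8764, 0.0987, 0.0230, 0.0019)
    bin_probs_3: tuple[float, float, float, float] = (0.7846, 0.1703, 0.0404, 0.0047)
    p_no_utr5: float = 0.10
    p_no_utr3: float = 0.10
    cds_len_range: tuple[int, int] = (200, 3800)
    strand_prob: float = 0.5
    max_introns: int = 2
    intron_len_range: tuple[int, int] = (60, 500)
    bin4_cap: int = 4000  # keeps fixtures small; >2000 bin samples 2001..cap
    intergenic: int = 200
    chrom: str = "chr1"
    go: GOParams = field(default_factory=GOParams)
    #: (motif name, IUPAC consensus, mean implants per sequence)
    motif_implants: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for name, probs in (("bin_probs_5", self.bin_probs_5),
                            ("bin_probs_3", self.bin_probs_3)):
            if len(probs) != 4 or any(p < 0 for p in probs):
                raise SimulationError(f"{name} must be 4 non-negative values")
            if abs(sum(probs) - 1.0) > 1e-6:
                raise SimulationError(f"{name} must sum to 1, got {sum(probs)}")
        for name, p in (("p_multi_transcript", self.p_multi_transcript),
                        ("p_no_utr5", self.p_no_utr5),
                        ("p_no_utr3", self.p_no_utr3),
                        ("strand_prob", self.strand_prob)):
            if not 0 <= p <= 1:
                raise SimulationError(f"{name} must be a probability, got {p}")
        if self.n_genes < 1:
            raise SimulationError("n_genes must be >= 1")
        if self.cds_len_range[0] < 6 or self.cds_len_range[1] < self.cds_len_range[0]:
            raise SimulationError(f"bad cds_len_range {self.cds_len_range}")
        if self.bin4_cap <= 2000:
            raise SimulationError("bin4_cap must exceed 2000")


@dataclass
class SyntheticTruth:
    """Ground truth paired with the emitted files."""

    genes: dict[str, dict] = field(default_factory=dict)
    planted_go: list[tuple[str, str, float]] = field(default_factory=list)
    gene_terms: dict[str, list[str]] = field(default_factory=dict)
    motif_implants: list[dict] = field(default_factory=list)

    def bin_counts(self, side: str = "5") -> tuple[int, int, int, int]:
        key = f"bin_{side}"
        counts = [0, 0, 0, 0]
        for info in self.genes.values():
            label = info[key]
            if label:
                counts[BIN_LABELS.index(label)] += 1
        return tuple(counts)

    def to_json(self) -> str:
        return json.dumps(
            {
                "genes": self.genes,
                "planted_go": [list(t) for t in self.planted_go],
                "gene_terms": self.gene_terms,
                "motif_implants": self.motif_implants,
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class SyntheticBundle:
    gtf: str                 # exon/CDS geometry only (derive mode)
    gtf_explicit: str        # same models plus explicit UTR features
    mrna_fasta: str          # mature transcript sequences, 5'->3'
    utr5_fasta: str          # 5' UTR portion of each coding mRNA
    genome_fasta: str
    truth: SyntheticTruth


def _sample_utr_len(rng: np.random.Generator, probs, p_none: float,
                    cap: int) -> tuple[int, Optional[int]]:
    if rng.random() < p_none:
        return 0, None
    b = int(rng.choice(4, p=np.asarray(probs) / np.sum(probs)))
    lo, hi = _BIN_RANGES[b]
    hi = cap if hi is None else hi
    return int(rng.integers(lo, hi + 1)), b


def _axis_to_genomic(segments: list[tuple[int, int, int]],
                     a: int, b: int) -> list[tuple[int, int]]:
    """Map axis (left-to-right transcript-space) range [a, b] 1-based to
    genomic 0-based half-open intervals; segments = (axis_start, axis_end,
    genomic_start) per exon."""
    out = []
    for seg_a, seg_b, g0 in segments:
        lo, hi = max(a, seg_a), min(b, seg_b)
        if lo <= hi:
            out.append((g0 + (lo - seg_a), g0 + (hi - seg_a) + 1))
    return out


def generate_annotation(
    params: GeneratorParams, with_sequences: bool = True
) -> SyntheticBundle:
    """Emit GTF (with and without explicit UTR features), FASTA and truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    truth = SyntheticTruth()
    gtf_lines: list[str] = []
    gtfx_lines: list[str] = []
    # per-transcript: (tid, gid, strand, exon intervals, axis segments, marks)
    tx_records: list[dict] = []
    cursor = params.intergenic

    for gi in range(params.n_genes):
        gid = f"SGENE{gi + 1:05d}"
        strand = "+" if rng.random() < params.strand_prob else "-"
        utr5, b5 = _sample_utr_len(
            rng, params.bin_probs_5, params.p_no_utr5, params.bin4_cap)
        utr3, b3 = _sample_utr_len(
            rng, params.bin_probs_3, params.p_no_utr3, params.bin4_cap)
        cds = 3 * int(rng.integers(params.cds_len_range[0] // 3,
                                   params.cds_len_range[1] // 3 + 1))
        L = utr5 + cds + utr3

        n_introns = int(rng.integers(0, params.max_introns + 1))
        cuts = sorted(
            int(c) for c in rng.choice(np.arange(1, L), size=min(n_introns, L - 1),
                                       replace=False)
        )
        bounds = [0] + cuts + [L]
        seg_lens = [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]

        segments = []  # (axis_start, axis_end, genomic_start), axis 1-based
        g = cursor
        axis = 1
        for i, sl in enumerate(seg_lens):
            segments.append((axis, axis + sl - 1, g))
            axis += sl
            g += sl
            if i < len(seg_lens) - 1:
                g += int(rng.integers(*params.intron_len_range))
        gene_end = g
        cursor = gene_end + params.intergenic

        # axis ranges: on '+' the 5' UTR is leftmost, on '-' rightmost
        if strand == "+":
            r5 = (1, utr5)
            rc = (utr5 + 1, utr5 + cds)
            r3 = (utr5 + cds + 1, L)
        else:
            r3 = (1, utr3)
            rc = (utr3 + 1, utr3 + cds)
            r5 = (utr3 + cds + 1, L)

        tid = f"{gid}_T01"
        transcripts = [(tid, 1, L)]
        if rng.random() < params.p_multi_transcript and (utr5 >= 2 or utr3 >= 2):
            # shorter isoform: same CDS, UTRs halved
            t5, t3 = utr5 // 2, utr3 // 2
            if strand == "+":
                a2, b2 = 1 + t5, L - t3
            else:
                a2, b2 = 1 + t3, L - t5
            if (a2, b2) != (1, L):
                transcripts.append((f"{gid}_T02", a2, b2))

        truth.genes[gid] = {
            "transcript_id": tid,
            "strand": strand,
            "utr5_len": utr5,
            "utr3_len": utr3,
            "cds_len": cds,
            "bin_5": BIN_LABELS[b5] if b5 is not None else None,
            "bin_3": BIN_LABELS[b3] if b3 is not None else None,
        }

        for t_id, a, b in transcripts:
            exon_ivs = _axis_to_genomic(segments, a, b)
            cds_ivs = _axis_to_genomic(segments, max(rc[0], a), min(rc[1], b))
            utr5_ivs = (
                _axis_to_genomic(segments, max(r5[0], a), min(r5[1], b))
                if r5[0] <= r5[1] else []
            )
            utr3_ivs = (
                _axis_to_genomic(segments, max(r3[0], a), min(r3[1], b))
                if r3[0] <= r3[1] else []
            )

            def emit(lines: list[str], ftype: str, ivs) -> None:
                for s0, e0 in ivs:
                    lines.append(
                        "\t".join(
                            [params.chrom, "utrsim", ftype,
                             str(s0 + 1), str(e0), ".", strand, ".",
                             f'gene_id "{gid}"; transcript_id "{t_id}";']
                        )
                    )

            emit(gtf_lines, "exon", exon_ivs)
            emit(gtf_lines, "CDS", cds_ivs)
            emit(gtfx_lines, "exon", exon_ivs)
            emit(gtfx_lines, "CDS", cds_ivs)
            emit(gtfx_lines, "five_prime_utr", utr5_ivs)
            emit(gtfx_lines, "three_prime_utr", utr3_ivs)
            tx_records.append(
                {"tid": t_id, "strand": strand, "exons": exon_ivs,
                 "utr5_len": utr5 if t_id == tid else None}
            )

    gtf = "\n".join(gtf_lines) + "\n"
    gtf_explicit = "\n".join(gtfx_lines) + "\n"

    mrna_fasta = utr5_fasta = genome_fasta = ""
    if with_sequences:
        genome_len = cursor
        genome = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=genome_len)
        genome_str = genome.tobytes().decode()
        mrna_chunks = []
        utr5_chunks = []
        for rec in tx_records:
            seq = "".join(genome_str[s:e] for s, e in rec["exons"])
            if rec["strand"] == "-":
                seq = _revcomp(seq)
            mrna_chunks.append(f">{rec['tid']}\n{_wrap(seq)}")
            if rec["utr5_len"]:
                utr5_chunks.append(
                    f">{rec['tid']}\n{_wrap(seq[:rec['utr5_len']])}"
                )
        mrna_fasta = "\n".join(mrna_chunks) + "\n"
        utr5_fasta = "\n".join(utr5_chunks) + ("\n" if utr5_chunks else "")
        genome_fasta = f">{params.chrom}\n{_wrap(genome_str)}\n"

    return SyntheticBundle(gtf, gtf_explicit, mrna_fasta, utr5_fasta,
                           genome_fasta, truth)


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _wrap(seq: str, width: int = 70) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))


# ---------------------------------------------------------------------------
# GO universe


def generate_go_universe(
    params: GeneratorParams,
    truth: SyntheticTruth,
    seed: Optional[int] = None,
) -> tuple[str, str]:
    """Emit a gene->GO 2-column TSV and a minimal BP OBO.

    Background annotation is uniform: every gene carries every term with
    probability ``base_rate``.  For each planted (class, term, odds)
    triple, genes whose true 5' UTR bin equals the class receive the term
    with the base odds multiplied by the planted odds.  Term sets are
    recorded in ``truth.gene_terms``.
    """
    if not truth.genes:
        raise SimulationError("truth has no genes")
    gp = params.go
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    terms = [f"GO:{1000000 + i}" for i in range(gp.n_terms)]
    planted_by_term = {t: (cls, odds) for cls, t, odds in gp.planted}
    unknown = set(planted_by_term) - set(terms)
    if unknown:
        raise SimulationError(f"planted terms outside universe: {sorted(unknown)}")
    truth.planted_go = list(gp.planted)

    p0 = gp.base_rate
    lines = []
    for gid, info in sorted(truth.genes.items()):
        gene_terms = []
        for t in terms:
            p = p0
            planted = planted_by_term.get(t)
            if planted is not None and info["bin_5"] == planted[0]:
                odds = planted[1] * p0 / (1 - p0)
                p = odds / (1 + odds)
            if rng.random() < p:
                gene_terms.append(t)
                lines.append(f"{gid}\t{t}")
        truth.gene_terms[gid] = gene_terms
    tsv = "\n".join(lines) + "\n"

    root = "GO:2000000"
    obo = ["format-version: 1.2", "ontology: utrsurvey-synthetic", ""]
    obo += ["[Term]", f"id: {root}", "name: synthetic biological process root",
            "namespace: biological_process", ""]
    for i, t in enumerate(terms):
        obo += ["[Term]", f"id: {t}", f"name: synthetic process {i}",
                "namespace: biological_process"]
        # short is_a chain: each term under the root; term i>0 also under i-1
        obo.append(f"is_a: {root} ! synthetic biological process root")
        if i in (1, 2):
            obo.append(f"is_a: {terms[i - 1]} ! synthetic process {i - 1}")
        obo.append("")
    return tsv, "\n".join(obo)


# ---------------------------------------------------------------------------
# Motif implantation


def implant_motifs(
    fasta: str,
    params: GeneratorParams,
    seed: Optional[int] = None,
) -> tuple[str, SyntheticTruth]:
    """Write exact motif words into FASTA sequences at non-overlapping
    positions; returns the edited FASTA and a truth recording each implant
    (sequence, motif, 1-based position, strand)."""
    import io

    from Bio import SeqIO

    from .cisscan import IUPAC, reverse_complement

    records = list(SeqIO.parse(io.StringIO(fasta), "fasta"))
    if not records:
        raise SimulationError("empty FASTA")
    rng = np.random.default_rng(params.seed + 2 if seed is None else seed)
    truth = SyntheticTruth()
    out_chunks = []
    for record in records:
        seq = list(str(record.seq).upper())
        occupied: list[tuple[int, int]] = []
        for name, consensus, rate in params.motif_implants:
            word_len = len(consensus)
            n_implants = int(rng.poisson(rate))
            for _ in range(n_implants):
                if len(seq) < word_len:
                    raise SimulationError(
                        f"sequence {record.id} too short for motif {name}"
                    )
                word = "".join(
                    IUPAC[c][int(rng.integers(len(IUPAC[c])))]
                    for c in consensus.upper()
                )
                strand = "+" if rng.random() < 0.5 else "-"
                placed = False
                for _try in range(200):
                    pos = int(rng.integers(0, len(seq) - word_len + 1))
                    if all(pos + word_len <= s or pos >= e for s, e in occupied):
                        placed = True
                        break
                if not placed:
                    raise SimulationError(
                        f"sequence {record.id}: no room left for motif {name}"
                    )
                written = word if strand == "+" else reverse_complement(word)
                seq[pos:pos + word_len] = list(written)
                occupied.append((pos, pos + word_len))
                truth.motif_implants.append(
                    {"sequence_id": record.id, "motif": name,
                     "position": pos + 1, "strand": strand, "word": word}
                )
        out_chunks.append(f">{record.id}\n{_wrap(''.join(seq))}")
    return "\n".join(out_chunks) + "\n", truth
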