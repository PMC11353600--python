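"""Inference of 5'/3' UTR intervals and genome-wide UTR length statistics.

A UTR here is the exonic sequence of a coding transcript outside the
genomic span of its CDS: on the + strand the low-coordinate side is the
5' UTR, on the - strand the high-coordinate side is.  Lengths are then
stratified into the four gradients used throughout the package:
1-500, 501-1000, 1001-2000 and >2000 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .annotation import (
    FIVE_PRIME,
    THREE_PRIME,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptModel,
    select_longest_transcript,
)

#: Closed bin ranges, in nt; the last bin is open-ended.
BIN_EDGES: tuple[tuple[int, Optional[int]], ...] = (
    (1, 500),
    (501, 1000),
    (1001, 2000),
    (2001, None),
)
BIN_LABELS = ("1-500", "501-1000", "1001-2000", ">2000")


class UTRError(ValueError):
    pass


@dataclass
class UTRPair:
    """Inferred UTR intervals and lengths for one transcript."""

    transcript_id: str
    five_prime: list[GenomicInterval] = field(default_factory=list)
    three_prime: list[GenomicInterval] = field(default_factory=list)

    @property
    def five_len(self) -> int:
        return sum(len(iv) for iv in self.five_prime)

    @property
    def three_len(self) -> int:
        return sum(len(iv) for iv in self.three_prime)


@dataclass
class BinDistribution:
    counts: tuple[int, int, int, int]
    labels: tuple[str, ...] = BIN_LABELS

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def proportions(self) -> tuple[float, ...]:
        t = self.total
        if t == 0:
            return (0.0, 0.0, 0.0, 0.0)
        return tuple(c / t for c in self.counts)

    @property
    def empty(self) -> bool:
        return self.total == 0


@dataclass
class GenomeUTRSummary:
    n_genes_analyzed: int
    cds_bases: int
    utr5_bases: int
    utr3_bases: int
    mean_utr5_len: float
    mean_utr3_len: float
    bins_5: BinDistribution
    bins_3: BinDistribution
    per_gene: pd.DataFrame  # gene_id, transcript_id, five_len, three_len, ...

    @property
    def utr_fraction(self) -> float:
        total = self.cds_bases + self.utr5_bases + self.utr3_bases
        return (self.utr5_bases + self.utr3_bases) / total if total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_genes_analyzed": self.n_genes_analyzed,
            "cds_bases": self.cds_bases,
            "utr5_bases": self.utr5_bases,
            "utr3_bases": self.utr3_bases,
            "utr_fraction": self.utr_fraction,
            "mean_utr5_len": self.mean_utr5_len,
            "mean_utr3_len": self.mean_utr3_len,
            "bins_5": {"labels": list(BIN_LABELS),
                       "counts": list(self.bins_5.counts),
                       "proportions": list(self.bins_5.proportions)},
            "bins_3": {"labels": list(BIN_LABELS),
                       "counts": list(self.bins_3.counts),
                       "proportions": list(self.bins_3.proportions)},
        }


def infer_utrs(tx: TranscriptModel, mode: str = "derive") -> UTRPair:
    """Infer 5'/3' UTR intervals for one transcript.

    mode
        ``derive``: exonic bases outside the CDS genomic span.
        ``explicit``: use the annotation's explicit UTR features.
        ``prefer_explicit``: explicit features when present, else derive.
    """
    if mode not in ("derive", "explicit", "prefer_explicit"):
        raise UTRError(f"unknown mode {mode!r}")
    if mode == "prefer_explicit":
        mode = "explicit" if tx.explicit_utrs else "derive"

    if mode == "explicit":
        if not tx.explicit_utrs:
            raise UTRError(
                f"transcript {tx.transcript_id}: explicit UTRs requested but absent"
            )
        pair = UTRPair(tx.transcript_id)
        for side, iv in tx.explicit_utrs:
            (pair.five_prime if side == FIVE_PRIME else pair.three_prime).append(iv)
        return pair

    if not tx.cds:
        raise UTRError(f"non-coding transcript {tx.transcript_id}")

    cds_start = min(c.start for c in tx.cds)
    cds_end = max(c.end for c in tx.cds)
    left: list[GenomicInterval] = []
    right: list[GenomicInterval] = []
    for e in tx.exons:
        if e.start < cds_start:
            left.append(
                GenomicInterval(e.chrom, e.start, min(e.end, cds_start), e.strand)
            )
        if e.end > cds_end:
            right.append(
                GenomicInterval(e.chrom, max(e.start, cds_end), e.end, e.strand)
            )
    pair = UTRPair(tx.transcript_id)
    if tx.strand == "+":
        pair.five_prime, pair.three_prime = left, right
    else:
        pair.five_prime, pair.three_prime = right, left
    return pair


def bin_index(length: int) -> int:
    """0-based gradient index of a UTR length (length >= 1)."""
    if length < 1:
        raise UTRError(f"UTR length must be >= 1, got {length}")
    for i, (lo, hi) in enumerate(BIN_EDGES):
        if length >= lo and (hi is None or length <= hi):
            return i
    raise AssertionError("unreachable")


def bin_lengths(lengths: Iterable[int]) -> BinDistribution:
    """Bin UTR lengths into the four gradients (closed ranges)."""
    counts = [0, 0, 0, 0]
    n = 0
    for length in lengths:
        counts[bin_index(int(length))] += 1
        n += 1
    if n == 0:
        raise UTRError("cannot bin an empty length collection")
    return BinDistribution(tuple(counts))


def genome_utr_summary(
    annotation: GenomeAnnotation, mode: str = "derive"
) -> GenomeUTRSummary:
    """Genome-wide UTR survey over one representative transcript per gene.

    For each gene the longest transcript (summed exon length) is taken and
    its UTRs inferred.  Means are over transcripts that possess the UTR
    (length > 0); zero-length UTRs still contribute to the base-fraction
    denominator via their CDS, but not to bins or means.  Non-coding
    representative transcripts are excluded entirely.
    """
    rows = []
    for gene in annotation.genes:
        tx = select_longest_transcript(gene)
        if not tx.is_coding and mode == "derive":
            continue
        try:
            pair = infer_utrs(tx, mode=mode)
        except UTRError:
            continue
        cds_len = tx.cds_length if tx.is_coding else 0
        rows.append(
            {
                "gene_id": gene.gene_id,
                "transcript_id": tx.transcript_id,
                "five_len": pair.five_len,
                "three_len": pair.three_len,
                "cds_len": cds_len,
                "bin_5": BIN_LABELS[bin_index(pair.five_len)]
                if pair.five_len > 0 else "",
                "bin_3": BIN_LABELS[bin_index(pair.three_len)]
                if pair.three_len > 0 else "",
            }
        )
    if not rows:
        raise UTRError("annotation contains no analyzable coding genes")
    table = pd.DataFrame(rows)

    five = table.loc[table.five_len > 0, "five_len"]
    three = table.loc[table.three_len > 0, "three_len"]
    bins_5 = (
        bin_lengths(five) if len(five) else BinDistribution((0, 0, 0, 0))
    )
    bins_3 = (
        bin_lengths(three) if len(three) else BinDistribution((0, 0, 0, 0))
    )
    return GenomeUTRSummary(
        n_genes_analyzed=len(table),
        cds_bases=int(table.cds_len.sum()),
        utr5_bases=int(table.five_len.sum()),
        utr3_bases=int(table.three_len.sum()),
        mean_utr5_len=float(five.mean()) if len(five) else 0.0,
        mean_utr3_len=float(three.mean()) if len(three) else 0.0,
        bins_5=bins_5,
        bins_3=bins_3,
        per_gene=table,
    )


def length_classes(summary: GenomeUTRSummary, side: str = "5") -> dict[str, set]:
    """Gene sets per length gradient for one UTR side ('5' or '3')."""
    col_bin = "bin_5" if side == "5" else "bin_3"
    t = summary.per_gene
    return {
        label: set(t.loc[t[col_bin] == label, "gene_id"]) for label in BIN_LABELS
    }


def compare_summaries(
    a: GenomeUTRSummary,
    b: GenomeUTRSummary,
    pairs: Optional[dict[str, str]] = None,
    labels: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Side-by-side bin proportions and mean UTR lengths for two genomes.

    With ``pairs`` (query gene in *a* -> subject gene in *b*) the comparison
    is restricted to the mapped genes; otherwise it is genome-wide.
    """
    if pairs is not None:
        missing_a = sorted(set(pairs) - set(a.per_gene.gene_id))
        missing_b = sorted(set(pairs.values()) - set(b.per_gene.gene_id))
        if missing_a or missing_b:
            raise UTRError(
                f"ortholog map references unknown genes: "
                f"{labels[0]}={missing_a[:5]} {labels[1]}={missing_b[:5]}"
            )
        ta = a.per_gene[a.per_gene.gene_id.isin(set(pairs))]
        tb = b.per_gene[b.per_gene.gene_id.isin(set(pairs.values()))]
    else:
        ta, tb = a.per_gene, b.per_gene

    def stats(t: pd.DataFrame) -> dict:
        out: dict[str, float] = {}
        for side, col in (("5", "five_len"), ("3", "three_len")):
            vals = t.loc[t[col] > 0, col]
            dist = (
                bin_lengths(vals) if len(vals) else BinDistribution((0, 0, 0, 0))
            )
            out[f"mean_utr{side}"] = float(vals.mean()) if len(vals) else 0.0
            for lab, p in zip(BIN_LABELS, dist.proportions):
                out[f"utr{side}_{lab}"] = p
        return out

    sa, sb = stats(ta), stats(tb)
    rows = [
        {"metric": k, labels[0]: sa[k], labels[1]: sb[k], "delta": sa[k] - sb[k]}
        for k in sa
    ]
    return pd.DataFrame(rows)


def per_gene_table_tsv(summary: GenomeUTRSummary) -> str:
    return summary.per_gene.to_csv(sep="\t", index=False)


def utr_bed(annotation: GenomeAnnotation, mode: str = "derive") -> str:
    """BED6 export of inferred UTR intervals (name = transcript_id|side)."""
    lines = []
    for gene in annotation.genes:
        tx = select_longest_transcript(gene)
        if not tx.is_coding:
            continue
        pair = infer_utrs(tx, mode=mode)
        for side, ivs in ((FIVE_PRIME, pair.five_prime),
                          (THREE_PRIME, pair.three_prime)):
            for iv in ivs:
                lines.append(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{tx.transcript_id}|{side}\t0\t{iv.strand}"
                )
    return "\n".join(lines) + ("\n" if lines else "")
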