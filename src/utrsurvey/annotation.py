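"""Strand-aware gene/transcript models parsed from GTF or GFF3.

All coordinates are held internally as 0-based half-open intervals; the
GTF/GFF3 boundary (1-based inclusive) is converted in exactly one place on
read and one on write.  "Longest transcript" throughout the package means
largest summed exon length (mature transcript length), not genomic span.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO, Union

logger = logging.getLogger(__name__)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

# Feature-type spellings accepted for explicit UTR features (GFF3 and the
# various GTF dialects in the wild).
_UTR5_TYPES = {"five_prime_utr", "5utr", "utr5", "5'utr", "five_prime_UTR".lower()}
_UTR3_TYPES = {"three_prime_utr", "3utr", "utr3", "3'utr"}


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on one strand of one sequence."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    explicit_utrs: list[tuple[str, GenomicInterval]] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def sorted(self) -> "TranscriptModel":
        """Return self with intervals sorted by genomic start (in place)."""
        self.exons.sort(key=lambda iv: (iv.start, iv.end))
        self.cds.sort(key=lambda iv: (iv.start, iv.end))
        self.explicit_utrs.sort(key=lambda su: (su[1].start, su[1].end, su[0]))
        return self

    def validate(self) -> None:
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        for c in self.cds:
            if not any(e.contains(c) for e in self.exons):
                raise AnnotationError(
                    f"CDS interval {c.start}-{c.end} outside exons of "
                    f"transcript {self.transcript_id}"
                )


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)


@dataclass
class GenomeAnnotation:
    genes: list[GeneModel]
    source_dialect: str
    provenance: str = ""

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes)


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str, dialect: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if dialect == "GTF":
        for key, value in _GTF_ATTR.findall(attr_field):
            attrs.setdefault(key, value)
    else:
        for part in attr_field.strip().split(";"):
            part = part.strip()
            if not part or "=" not in part:
                continue
            key, _, value = part.partition("=")
            attrs.setdefault(key.strip(), value.strip())
    return attrs


def _sniff_dialect(attr_field: str) -> str:
    if "=" in attr_field and '"' not in attr_field:
        return "GFF3"
    return "GTF"


def parse_annotation(
    stream: Union[str, TextIO, Iterable[str]],
    dialect: str = "auto",
    provenance: str = "",
) -> GenomeAnnotation:
    """Parse GTF or GFF3 text into a :class:`GenomeAnnotation`.

    Parameters
    ----------
    stream
        Annotation text, an open text handle, or an iterable of lines.
    dialect
        ``"GTF"``, ``"GFF3"`` or ``"auto"`` (sniffed from the first data
        line's attribute column).

    Input coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention.  GTF ``stop_codon`` features are merged
    into the CDS so the inferred 3' UTR starts after the stop codon.
    Explicit UTR features are captured; unknown feature types are counted
    and ignored.
    """
    if isinstance(stream, str):
        lines: Iterable[str] = stream.splitlines()
    elif hasattr(stream, "read"):
        lines = stream  # type: ignore[assignment]
    else:
        lines = stream

    if dialect not in ("GTF", "GFF3", "auto"):
        raise AnnotationError(f"unknown dialect {dialect!r}")

    # transcript_id -> TranscriptModel; gff3 id chains resolved as we go
    transcripts: dict[str, TranscriptModel] = {}
    gene_order: list[str] = []
    tx_parent: dict[str, str] = {}  # GFF3: transcript ID -> gene ID
    skipped: dict[str, int] = {}
    eff_dialect = None if dialect == "auto" else dialect

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationError(
                f"line {lineno}: expected 9 tab-separated fields, got "
                f"{len(fields)}"
            )
        chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attr = fields
        if eff_dialect is None:
            eff_dialect = _sniff_dialect(attr)
        attrs = _parse_attributes(attr, eff_dialect)
        ftype_l = ftype.lower()

        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise AnnotationError(f"line {lineno}: non-integer coordinate") from exc
        start0, end0 = start1 - 1, end1  # single conversion point

        if eff_dialect == "GFF3" and ftype_l in ("mrna", "transcript"):
            tid = attrs.get("ID")
            gid = attrs.get("Parent", attrs.get("gene_id", tid))
            if tid:
                tx_parent[tid] = gid or tid
            continue
        if ftype_l == "gene":
            continue

        known = (
            ftype_l in ("exon", "cds", "stop_codon")
            or ftype_l in _UTR5_TYPES
            or ftype_l in _UTR3_TYPES
        )
        if not known:
            skipped[ftype] = skipped.get(ftype, 0) + 1
            continue

        if eff_dialect == "GTF":
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id", tid)
        else:
            tid = attrs.get("Parent") or attrs.get("transcript_id")
            gid = tx_parent.get(tid or "", tid)
        if not tid:
            raise AnnotationError(
                f"line {lineno}: {ftype} feature missing transcript attribution"
            )

        tx = transcripts.get(tid)
        if tx is None:
            tx = TranscriptModel(transcript_id=tid, gene_id=gid or tid, strand=strand)
            transcripts[tid] = tx
            if tx.gene_id not in gene_order:
                gene_order.append(tx.gene_id)
        iv = GenomicInterval(chrom, start0, end0, strand)

        if ftype_l == "exon":
            tx.exons.append(iv)
        elif ftype_l in ("cds", "stop_codon"):
            tx.cds.append(iv)
        elif ftype_l in _UTR5_TYPES:
            tx.explicit_utrs.append((FIVE_PRIME, iv))
        else:
            tx.explicit_utrs.append((THREE_PRIME, iv))

    if skipped:
        logger.info("ignored feature types: %s", skipped)

    genes: dict[str, GeneModel] = {}
    for tx in transcripts.values():
        tx.sorted()
        tx.cds = _merge_adjacent(tx.cds)
        if not tx.exons:
            raise AnnotationError(
                f"transcript {tx.transcript_id} has no exon features"
            )
        tx.validate()
        genes.setdefault(tx.gene_id, GeneModel(tx.gene_id)).transcripts.append(tx)

    ann = GenomeAnnotation(
        genes=[genes[g] for g in gene_order if g in genes],
        source_dialect=eff_dialect or "GTF",
        provenance=provenance,
    )
    n_noncoding = sum(
        1 for g in ann.genes for t in g.transcripts if not t.is_coding
    )
    logger.info(
        "parsed %d genes, %d transcripts (%d non-coding transcripts)",
        ann.n_genes, ann.n_transcripts, n_noncoding,
    )
    return ann


def _merge_adjacent(ivs: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge touching/overlapping intervals (stop_codon abuts the CDS)."""
    merged: list[GenomicInterval] = []
    for iv in sorted(ivs, key=lambda i: (i.start, i.end)):
        if merged and iv.start <= merged[-1].end:
            last = merged[-1]
            merged[-1] = GenomicInterval(
                last.chrom, last.start, max(last.end, iv.end), last.strand
            )
        else:
            merged.append(iv)
    return merged


def select_longest_transcript(gene: GeneModel) -> TranscriptModel:
    """Representative transcript: largest summed exon length.

    Ties break to the lexicographically smallest transcript_id, so the
    choice is invariant under enumeration order.
    """
    if not gene.transcripts:
        raise AnnotationError(f"gene {gene.gene_id} has no transcripts")
    return min(gene.transcripts, key=lambda t: (-t.exonic_length, t.transcript_id))


_UTR_FEATURE_NAME = {FIVE_PRIME: "five_prime_utr", THREE_PRIME: "three_prime_utr"}


def write_gtf(annotation: GenomeAnnotation, handle: Optional[TextIO] = None) -> str:
    """Serialize to GTF text (1-based inclusive coordinates).

    Round-trips through :func:`parse_annotation`: models come back with
    identical intervals, ids and strands.
    """
    out: list[str] = []

    def emit(tx: TranscriptModel, ftype: str, iv: GenomicInterval) -> None:
        out.append(
            "\t".join(
                [
                    iv.chrom, "utrsurvey", ftype,
                    str(iv.start + 1), str(iv.end), ".", iv.strand, ".",
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";',
                ]
            )
        )

    for gene in annotation.genes:
        for tx in gene.transcripts:
            for e in tx.exons:
                emit(tx, "exon", e)
            for c in tx.cds:
                emit(tx, "CDS", c)
            for side, iv in tx.explicit_utrs:
                emit(tx, _UTR_FEATURE_NAME[side], iv)
    text = "\n".join(out) + ("\n" if out else "")
    if handle is not None:
        handle.write(text)
    return text
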