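"""IUPAC cis-element scanning of 5' UTR sequences.

The motif dictionary is a bundled, editable TSV (name, IUPAC consensus,
functional category, description) standing in for interactive promoter-
element services; it ships with the stress / phytohormone / development /
light element set relevant to plant 5' UTRs (STRE, ABRE, ARE, the CGTCA
and TGACG MeJA pair, LTR, MBS, the G-box family, ...).  Occurrences are
counted on both strands, overlaps included; exact replication of any web
service's output is not promised.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from importlib import resources
from itertools import product
from typing import Iterable, Optional, Sequence, TextIO, Union

import pandas as pd
from Bio import SeqIO

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

CATEGORIES = (
    "Abiotic and biological stresses",
    "Phytohormone response",
    "Plant growth and development",
    "Light responsiveness",
    "Other",
)


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class Motif:
    name: str
    consensus: str
    category: str = "Other"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ScanError(f"motif {self.name}: empty consensus")
        for ch in self.consensus.upper():
            if ch not in IUPAC:
                raise ScanError(
                    f"motif {self.name}: invalid IUPAC character {ch!r}"
                )


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    motif: str
    position: int  # 1-based start on the forward (given) sequence
    strand: str
    matched: str


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC degeneracy (R<->Y, K<->M, ...)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


class IUPACMatcher:
    """Matcher for one IUPAC consensus.

    Accepts exactly the unambiguous DNA words consistent with the
    consensus; an N in the scanned sequence matches only an N consensus
    position (degenerate consensus positions never swallow unknown bases).
    """

    def __init__(self, consensus: str):
        consensus = consensus.upper()
        parts = []
        for ch in consensus:
            if ch not in IUPAC:
                raise ScanError(f"invalid IUPAC character {ch!r}")
            allowed = IUPAC[ch] + ("N" if ch == "N" else "")
            parts.append(f"[{allowed}]" if len(allowed) > 1 else allowed)
        self.consensus = consensus
        # lookahead so overlapping occurrences are all found
        self._finder = re.compile("(?=(" + "".join(parts) + "))")
        self._checker = re.compile("".join(parts) + r"\Z")

    def __len__(self) -> int:
        return len(self.consensus)

    def matches(self, word: str) -> bool:
        return self._checker.match(word.upper()) is not None

    def words(self) -> list[str]:
        """All unambiguous words (exponential in degeneracy; small motifs)."""
        return ["".join(w) for w in product(*(IUPAC[c] for c in self.consensus))]

    def finditer(self, seq: str):
        return self._finder.finditer(seq)


def expand_iupac(consensus: str) -> IUPACMatcher:
    """Compile an IUPAC consensus into a matcher over unambiguous words."""
    return IUPACMatcher(consensus)


def scan_motifs(
    seq: str,
    motifs: Iterable[Motif],
    sequence_id: str = "seq",
    strands: str = "both",
) -> list[MotifHit]:
    """Report every (overlapping) motif occurrence in one sequence.

    Minus-strand hits are matches of the reverse complement of the
    consensus, reported at their 1-based start position on the given
    forward sequence.  Output is sorted by (position, strand, motif name).
    """
    if not seq:
        raise ScanError("empty sequence")
    if strands not in ("plus", "both"):
        raise ScanError(f"strands must be 'plus' or 'both', got {strands!r}")
    useq = seq.upper()
    bad = set(useq) - set("ACGTN")
    if bad:
        raise ScanError(f"sequence {sequence_id}: invalid characters {sorted(bad)}")

    hits: list[MotifHit] = []
    for motif in motifs:
        searches = [("+", expand_iupac(motif.consensus))]
        if strands == "both":
            searches.append(("-", expand_iupac(reverse_complement(motif.consensus))))
        w = len(motif.consensus)
        for strand, matcher in searches:
            for m in matcher.finditer(useq):
                start = m.start()
                hits.append(
                    MotifHit(
                        sequence_id=sequence_id,
                        motif=motif.name,
                        position=start + 1,
                        strand=strand,
                        matched=useq[start:start + w],
                    )
                )
    hits.sort(key=lambda h: (h.position, h.strand, h.motif))
    return hits


@dataclass
class ElementProfile:
    sequence_id: str
    counts_by_motif: dict[str, int]
    counts_by_category: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts_by_motif.values())


def profile_elements(
    hits: Sequence[MotifHit], motifs: Iterable[Motif], sequence_id: str = ""
) -> ElementProfile:
    """Aggregate hits into per-motif and per-functional-category counts.

    Every known motif and every category appears in the output, zero
    counts included.
    """
    motif_list = list(motifs)
    by_name = {m.name: m for m in motif_list}
    counts_by_motif = {m.name: 0 for m in motif_list}
    categories = list(dict.fromkeys(
        list(CATEGORIES) + [m.category for m in motif_list]
    ))
    counts_by_category = {c: 0 for c in categories}
    for hit in hits:
        if hit.motif not in by_name:
            raise ScanError(f"hit references unknown motif {hit.motif!r}")
        counts_by_motif[hit.motif] += 1
        counts_by_category[by_name[hit.motif].category] += 1
    if not sequence_id:
        sequence_id = hits[0].sequence_id if hits else ""
    return ElementProfile(sequence_id, counts_by_motif, counts_by_category)


# ---------------------------------------------------------------------------
# I/O

def read_motif_table(stream: Union[str, TextIO, None] = None) -> list[Motif]:
    """Load the motif dictionary TSV; default = the bundled table."""
    if stream is None:
        text = (
            resources.files("utrsurvey.data").joinpath("motifs.tsv").read_text()
        )
    elif isinstance(stream, str):
        text = stream
    else:
        text = stream.read()
    table = pd.read_csv(io.StringIO(text), sep="\t", comment="#")
    required = {"name", "consensus", "category"}
    if not required.issubset(table.columns):
        raise ScanError(f"motif table needs columns {sorted(required)}")
    return [
        Motif(
            name=row["name"],
            consensus=str(row["consensus"]),
            category=row["category"],
            description=str(row.get("description", "")),
        )
        for _, row in table.iterrows()
    ]


def scan_fasta(
    fasta: Union[str, TextIO],
    motifs: Optional[Iterable[Motif]] = None,
    strands: str = "both",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every record of a FASTA; return (hits table, category matrix)."""
    motif_list = list(motifs) if motifs is not None else read_motif_table()
    handle = io.StringIO(fasta) if isinstance(fasta, str) else fasta
    hit_rows = []
    profile_rows = []
    for record in SeqIO.parse(handle, "fasta"):
        hits = scan_motifs(
            str(record.seq), motif_list, sequence_id=record.id, strands=strands
        )
        profile = profile_elements(hits, motif_list, sequence_id=record.id)
        hit_rows.extend(
            {"sequence_id": h.sequence_id, "motif": h.motif,
             "position": h.position, "strand": h.strand, "matched": h.matched}
            for h in hits
        )
        profile_rows.append(
            {"sequence_id": record.id, **profile.counts_by_category}
        )
    hits_table = pd.DataFrame(
        hit_rows,
        columns=["sequence_id", "motif", "position", "strand", "matched"],
    )
    profile_table = pd.DataFrame(profile_rows)
    return hits_table, profile_table
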