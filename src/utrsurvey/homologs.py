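"""Unique best-hit gene mapping from tabular alignment output.

Consumes BLAST/DIAMOND outfmt-6 style TSV (12 standard columns) and keeps,
for each query gene, the single subject with the highest bitscore — the
cross-species "target gene" convention.  Reciprocal filtering is optional
and off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO, Union

OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore"
).split()


class HomologError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentHit:
    query: str
    subject: str
    identity: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise HomologError(
                f"negative bitscore {self.bitscore} for {self.query}->{self.subject}"
            )
        if self.evalue < 0:
            raise HomologError(
                f"negative evalue {self.evalue} for {self.query}->{self.subject}"
            )


@dataclass
class OrthologMap:
    pairs: dict[str, str]
    query_species: str = ""
    subject_species: str = ""
    source: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, query: str) -> bool:
        return query in self.pairs


def read_outfmt6(stream: Union[str, TextIO, Iterable[str]]) -> list[AlignmentHit]:
    """Parse outfmt-6 TSV into hits; malformed rows raise naming the row."""
    if isinstance(stream, str):
        lines: Iterable[str] = stream.splitlines()
    elif hasattr(stream, "read"):
        lines = stream  # type: ignore[assignment]
    else:
        lines = stream
    hits = []
    for rowno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise HomologError(
                f"row {rowno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            hits.append(
                AlignmentHit(
                    query=fields[0],
                    subject=fields[1],
                    identity=float(fields[2]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
        except (ValueError, IndexError) as exc:
            if isinstance(exc, HomologError):
                raise
            raise HomologError(f"row {rowno}: malformed numeric field") from exc
    return hits


def best_hit_map(
    hits: Iterable[AlignmentHit],
    query_species: str = "",
    subject_species: str = "",
    source: str = "",
) -> OrthologMap:
    """For each query keep the subject with maximal bitscore.

    Ties break by smaller evalue, then lexicographically smallest subject
    id, so the map is invariant under input row order.
    """
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        cur = best.get(hit.query)
        if cur is None or _rank(hit) < _rank(cur):
            best[hit.query] = hit
    return OrthologMap(
        pairs={q: h.subject for q, h in sorted(best.items())},
        query_species=query_species,
        subject_species=subject_species,
        source=source,
    )


def _rank(hit: AlignmentHit) -> tuple[float, float, str]:
    return (-hit.bitscore, hit.evalue, hit.subject)


def reciprocal_filter(forward: OrthologMap, backward: OrthologMap) -> OrthologMap:
    """Keep pairs where the subject's best hit is the query (RBH)."""
    pairs = {
        q: s for q, s in forward.pairs.items() if backward.pairs.get(s) == q
    }
    return OrthologMap(
        pairs=pairs,
        query_species=forward.query_species,
        subject_species=forward.subject_species,
        source=f"reciprocal({forward.source},{backward.source})",
    )


def intersect_maps(map_ab: OrthologMap, map_ac: OrthologMap) -> set[str]:
    """Query genes mapped in both maps (e.g. maize genes with homologs in
    both rice and arabidopsis)."""
    if (
        map_ab.query_species
        and map_ac.query_species
        and map_ab.query_species != map_ac.query_species
    ):
        raise HomologError(
            f"query species differ: {map_ab.query_species!r} vs "
            f"{map_ac.query_species!r}"
        )
    return set(map_ab.pairs) & set(map_ac.pairs)


def map_tsv(m: OrthologMap) -> str:
    lines = [f"{q}\t{s}" for q, s in m.pairs.items()]
    return "\n".join(lines) + ("\n" if lines else "")
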