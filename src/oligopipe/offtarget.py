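"""Mismatch-tolerant off-target search and gene-level counting.

The engine is a pigeonhole seed-and-verify scheme: a query of length k
is split into ``seg_count`` (default 3) segments; any occurrence with at
most ``seg_count - 1`` mismatches must match at least one segment
exactly, so exact lookup of each segment in a hashed k-mer table
followed by full Hamming verification finds every hit with <= 2
mismatches.  Verification applies the conservative ambiguity rule (``N``
never matches), so spurious string-equal seeds over ``N`` are rejected.

Gene-level summaries count distinct genes at their *minimum* mismatch
level only, and always exclude the intended target gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .core import DesignType, OligoCandidate, Transcript, hamming
from .errors import (
    ConfigurationError,
    EmptyDatabaseError,
    QueryTooShortError,
)

__all__ = [
    "Hit",
    "OffTargetSummary",
    "SeedIndex",
    "build_index",
    "search",
    "summarize",
    "offtarget_profile",
]


class Hit(NamedTuple):
    """One verified occurrence of a query in a database sequence."""

    transcript_id: str
    gene_id: str
    offset: int
    strand_searched: str  # always "+": the caller supplies the text-space query
    mismatches: int


@dataclass
class OffTargetSummary:
    """Distinct-gene counts at exactly 0, 1, 2 mismatches for one database.

    A gene is counted once, at the minimum mismatch level among its hits;
    the intended target gene never contributes.
    """

    db_name: str
    genes_mm0: int = 0
    genes_mm1: int = 0
    genes_mm2: int = 0

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.genes_mm0, self.genes_mm1, self.genes_mm2)


class SeedIndex:
    """Exact-lookup seed tables over a transcript database.

    Seed tables are keyed by segment length and built lazily on first
    use, so one index serves queries of any length.
    """

    def __init__(self, transcripts: list[Transcript], db_name: str = "cdna",
                 seg_count: int = 3):
        if not transcripts:
            raise EmptyDatabaseError(f"database {db_name!r} has no sequences")
        if seg_count < 1:
            raise ValueError("seg_count must be >= 1")
        self.db_name = db_name
        self.seg_count = seg_count
        self.transcripts = list(transcripts)
        self._tables: dict[int, dict[str, list[tuple[int, int]]]] = {}

    def _table(self, s: int) -> dict[str, list[tuple[int, int]]]:
        table = self._tables.get(s)
        if table is None:
            table = {}
            for tidx, t in enumerate(self.transcripts):
                seq = t.sequence
                for off in range(len(seq) - s + 1):
                    table.setdefault(seq[off:off + s], []).append((tidx, off))
            self._tables[s] = table
        return table


def build_index(transcripts: list[Transcript], db_name: str = "cdna",
                seg_count: int = 3) -> SeedIndex:
    """Build a :class:`SeedIndex` over *transcripts*."""
    return SeedIndex(transcripts, db_name=db_name, seg_count=seg_count)


def search(index: SeedIndex, query: str, max_mm: int = 2) -> list[Hit]:
    """Every occurrence of *query* in the database with Hamming distance
    <= *max_mm*, each reported exactly once.

    Forward-strand text search only: the caller supplies the sequence
    expected to occur verbatim in the database text.
    """
    k = len(query)
    seg = index.seg_count
    if k < 3 * seg:
        raise QueryTooShortError(
            f"query length {k} < {3 * seg} required for {seg}-segment seeding"
        )
    s = k // seg
    # segment start offsets; the last segment absorbs the remainder but is
    # seeded by its first s bases (an exact segment match implies an exact
    # match of any prefix of it).
    seg_starts = [i * s for i in range(seg)]
    table = index._table(s)
    seen: set[tuple[int, int]] = set()
    hits: list[Hit] = []
    for seg_start in seg_starts:
        seed = query[seg_start:seg_start + s]
        for tidx, off in table.get(seed, ()):
            win_start = off - seg_start
            if win_start < 0:
                continue
            t = index.transcripts[tidx]
            if win_start + k > len(t.sequence):
                continue
            key = (tidx, win_start)
            if key in seen:
                continue
            seen.add(key)
            mm = hamming(query, t.sequence[win_start:win_start + k])
            if mm <= max_mm:
                hits.append(Hit(t.transcript_id, t.gene_id, win_start, "+", mm))
    hits.sort(key=lambda h: (h.transcript_id, h.offset))
    return hits


def summarize(hits: Iterable[Hit], target_gene_id: str,
              db_name: str = "cdna") -> OffTargetSummary:
    """Gene-level summary: per gene take the minimum mismatch, drop the
    target gene, count distinct genes per level."""
    best: dict[str, int] = {}
    for h in hits:
        if h.gene_id == target_gene_id:
            continue
        prev = best.get(h.gene_id)
        if prev is None or h.mismatches < prev:
            best[h.gene_id] = h.mismatches
    summary = OffTargetSummary(db_name=db_name)
    for mm in best.values():
        if mm == 0:
            summary.genes_mm0 += 1
        elif mm == 1:
            summary.genes_mm1 += 1
        elif mm == 2:
            summary.genes_mm2 += 1
    return summary


def offtarget_profile(
    c: OligoCandidate,
    cdna_index: SeedIndex,
    gene_index: SeedIndex | None,
    *,
    target_gene_id: str,
    max_mm: int = 2,
) -> None:
    """Annotate *c* with its off-target profile.

    siRNA: the guide base-pairs transcript text equal to the sense window,
    the passenger base-pairs text equal to the antisense sequence; both
    are searched against the cDNA database only.  Properties
    ``cdna_mm0/1/2`` (guide) and ``cdna_pass_mm0/1/2`` (passenger).

    ASO: the sense window is searched against both the cDNA and the
    unspliced-gene databases.  Properties ``cdna_mm0/1/2`` and
    ``gene_mm0/1/2``.
    """
    if c.design_type is DesignType.SIRNA:
        guide = summarize(
            search(cdna_index, c.sense_seq, max_mm), target_gene_id, "cdna"
        )
        passenger = summarize(
            search(cdna_index, c.antisense_seq, max_mm), target_gene_id, "cdna"
        )
        (c.properties["cdna_mm0"], c.properties["cdna_mm1"],
         c.properties["cdna_mm2"]) = guide.as_tuple()
        (c.properties["cdna_pass_mm0"], c.properties["cdna_pass_mm1"],
         c.properties["cdna_pass_mm2"]) = passenger.as_tuple()
    else:
        if gene_index is None:
            raise ConfigurationError(
                "ASO off-target profiling requires an unspliced-gene index"
            )
        cdna = summarize(
            search(cdna_index, c.sense_seq, max_mm), target_gene_id, "cdna"
        )
        gene = summarize(
            search(gene_index, c.sense_seq, max_mm), target_gene_id, "gene"
        )
        (c.properties["cdna_mm0"], c.properties["cdna_mm1"],
         c.properties["cdna_mm2"]) = cdna.as_tuple()
        (c.properties["gene_mm0"], c.properties["gene_mm1"],
         c.properties["gene_mm2"]) = gene.as_tuple()
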