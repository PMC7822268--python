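"""Per-candidate sequence annotations.

GC content, SNP overlap, exon-junction spanning, and conservation
against splice variants and ortholog transcripts.  Conservation is
computed in target space (on the sense window): the minimum Hamming
distance of the window over all equal-length windows of each other
transcript, capped at 2 mismatches and reported as absent beyond that.
"""

from __future__ import annotations

from .core import OligoCandidate, SnpRecord, Transcript, gc_content
from .offtarget import SeedIndex, build_index, search

__all__ = [
    "annotate_gc",
    "annotate_snps",
    "annotate_junction",
    "annotate_conservation",
    "build_conservation_indexes",
]


def annotate_gc(c: OligoCandidate) -> None:
    """Store the sense-window G+C percentage as ``gc_percent``."""
    c.properties["gc_percent"] = gc_content(c.sense_seq)


def annotate_snps(c: OligoCandidate, snps: list[SnpRecord],
                  primary_id: str) -> None:
    """Count SNPs falling inside the candidate window.

    A SNP at 1-based position p overlaps the window iff
    ``start_1based <= p <= end_1based``.  IDs are joined with ';' in
    ascending position order.  SNPs on other transcripts are ignored.
    """
    inside = sorted(
        (s for s in snps
         if s.transcript_id == primary_id
         and c.start_1based <= s.pos <= c.end_1based),
        key=lambda s: s.pos,
    )
    c.properties["snp_count"] = len(inside)
    c.properties["snp_ids"] = ";".join(s.snp_id for s in inside)


def annotate_junction(c: OligoCandidate, primary: Transcript) -> None:
    """Flag windows that span an exon-exon junction.

    A junction at offset e is spanned iff it is strictly interior to the
    window (start < e < end): an oligo merely abutting a junction does
    not cross it.
    """
    interior = [e for e in primary.exon_ends if c.start < e < c.end]
    c.properties["junction_count"] = len(interior)
    c.properties["spans_junction"] = bool(interior)


def build_conservation_indexes(
    others: list[Transcript],
) -> dict[str, SeedIndex]:
    """One single-transcript seed index per comparison transcript."""
    return {
        t.transcript_id: build_index([t], db_name=t.transcript_id)
        for t in others
    }


def annotate_conservation(
    c: OligoCandidate,
    others: list[Transcript],
    indexes: dict[str, SeedIndex] | None = None,
) -> None:
    """Minimum mismatch of the sense window to each other transcript.

    Stores ``mm_<transcript_id>`` in {0,1,2} (absent when every window is
    >2 mismatches away) and ``conserved_<species>`` = True iff some
    transcript of that species matches with 0 mismatches.
    """
    if indexes is None:
        indexes = build_conservation_indexes(others)
    species_conserved: dict[str, bool] = {}
    for t in others:
        hits = search(indexes[t.transcript_id], c.sense_seq, max_mm=2)
        species_conserved.setdefault(t.species, False)
        if hits:
            mm = min(h.mismatches for h in hits)
            c.properties[f"mm_{t.transcript_id}"] = mm
            if mm == 0:
                species_conserved[t.species] = True
    for species, flag in species_conserved.items():
        c.properties[f"conserved_{species}"] = flag
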