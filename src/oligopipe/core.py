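"""Domain types and elementary sequence operations.

The whole package works on a single canonical alphabet: DNA over
``{A, C, G, T, N}``.  RNA input (``U``) is normalised to ``T`` on load and
rendered back to RNA only at output time.  Coordinates are 0-based
half-open internally; user-facing CSV uses 1-based inclusive.

``N`` is treated conservatively throughout: it never matches any base
(including another ``N``) in mismatch counting, and it is never counted
as G/C.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Union

from .errors import (
    EmptyInputError,
    InvalidSequenceError,
    LengthMismatchError,
)

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PropertyValue = Union[int, float, str, bool]


class DesignType(enum.Enum):
    """Which kind of oligonucleotide a run designs."""

    ASO = "ASO"
    SIRNA = "SIRNA"


def _validate(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in DNA_ALPHABET:
            raise InvalidSequenceError(
                f"invalid character {ch!r} at position {i} (0-based); "
                f"expected one of A,C,G,T,N"
            )


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence; ``N`` maps to ``N``.

    Involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    _validate(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """Render a DNA-alphabet sequence as RNA (``T`` -> ``U``)."""
    _validate(seq)
    return seq.replace("T", "U")


def gc_content(seq: str) -> float:
    """G+C percentage of *seq*.

    ``N`` counts in the denominator but never as G/C.
    """
    if not seq:
        raise EmptyInputError("gc_content of an empty sequence is undefined")
    _validate(seq)
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def hamming(a: str, b: str) -> int:
    """Positionwise mismatch count; any comparison involving ``N`` mismatches."""
    if len(a) != len(b):
        raise LengthMismatchError(
            f"sequences differ in length: {len(a)} vs {len(b)}"
        )
    _validate(a)
    _validate(b)
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def normalize_sequence(seq: str) -> str:
    """Uppercase and U->T normalise raw sequence text, then validate."""
    seq = seq.upper().replace("U", "T")
    _validate(seq)
    return seq


@dataclass
class Transcript:
    """An identified nucleotide sequence with gene/species labels.

    ``exon_ends`` are 0-based transcript offsets where an exon ends
    (junction positions).  A single-exon transcript has an empty list:
    the transcript end itself is never a junction.
    """

    transcript_id: str
    gene_id: str
    species: str = "unknown"
    sequence: str = ""
    exon_ends: list[int] = field(default_factory=list)
    is_primary: bool = False

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        prev = 0
        for e in self.exon_ends:
            if not (0 < e < len(self.sequence)):
                raise ValueError(
                    f"exon end {e} outside (0, {len(self.sequence)}) "
                    f"for transcript {self.transcript_id}"
                )
            if e <= prev:
                raise ValueError(
                    f"exon_ends not strictly increasing for {self.transcript_id}"
                )
            prev = e

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OligoCandidate:
    """One enumerated design anchored to a window on the primary transcript.

    ``sense_seq`` is the transcript window (the siRNA passenger in target
    space); ``antisense_seq`` is its reverse complement — the ASO, or the
    siRNA guide.  ``properties`` is an open map filled by the annotation,
    off-target, thermodynamics and scoring stages.
    """

    oligo_id: str
    design_type: DesignType
    start: int
    end: int
    sense_seq: str
    antisense_seq: str
    properties: dict[str, PropertyValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = self.end - self.start
        if not (k == len(self.sense_seq) == len(self.antisense_seq)):
            raise ValueError(
                f"{self.oligo_id}: window [{self.start},{self.end}) does not "
                f"match sequence lengths"
            )
        if reverse_complement(self.sense_seq) != self.antisense_seq:
            raise ValueError(
                f"{self.oligo_id}: antisense_seq is not the reverse "
                f"complement of sense_seq"
            )

    @property
    def k(self) -> int:
        return self.end - self.start

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        # half-open exclusive end == 1-based inclusive end
        return self.end


@dataclass
class SnpRecord:
    """A single-nucleotide variant in transcript coordinates (1-based)."""

    transcript_id: str
    pos: int
    snp_id: str
    ref_allele: str
    alt_alleles: list[str]
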