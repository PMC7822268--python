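"""Candidate enumeration: every k-mer window tiling the primary transcript.

A transcript of length L yields exactly L - k + 1 candidates, one per
start offset.  Windows containing ``N`` are kept but flagged
(``has_ambiguity``); dropping them is the selection stage's decision,
not the enumerator's.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import DesignType, OligoCandidate, Transcript, reverse_complement, to_rna
from .errors import DesignTypeError, EmptyEnumerationError

__all__ = ["EnumerationConfig", "enumerate_candidates", "sirna_strands"]


@dataclass
class EnumerationConfig:
    """Length and design-type choices for enumeration."""

    k: int
    design_type: DesignType = DesignType.ASO
    add_tt_overhang: bool = False  # siRNA only; dTdT appended at render time

    def __post_init__(self) -> None:
        if isinstance(self.design_type, str):
            self.design_type = DesignType(self.design_type.upper())
        if self.k < 8:
            raise ValueError(f"k must be >= 8, got {self.k}")


def enumerate_candidates(
    primary: Transcript, cfg: EnumerationConfig
) -> list[OligoCandidate]:
    """All L - k + 1 candidate windows of *primary*, in ascending start order.

    ``oligo_id`` is ``<transcript_id>_<start_1based>``.
    """
    seq = primary.sequence
    L, k = len(seq), cfg.k
    if L < k:
        raise EmptyEnumerationError(
            f"transcript {primary.transcript_id} has length {L} < k = {k}"
        )
    candidates = []
    for start in range(L - k + 1):
        window = seq[start:start + k]
        c = OligoCandidate(
            oligo_id=f"{primary.transcript_id}_{start + 1}",
            design_type=cfg.design_type,
            start=start,
            end=start + k,
            sense_seq=window,
            antisense_seq=reverse_complement(window),
        )
        if "N" in window:
            c.properties["has_ambiguity"] = True
        candidates.append(c)
    return candidates


def sirna_strands(
    c: OligoCandidate, cfg: EnumerationConfig
) -> tuple[str, str]:
    """Render (guide, passenger) RNA strands of an siRNA duplex.

    The guide is the RNA rendering of the antisense sequence, the
    passenger of the sense sequence.  With ``add_tt_overhang`` a dTdT
    3' overhang ("TT", DNA alphabet) is appended to both strands; the
    overhang never participates in search or annotation windows, which
    operate on the duplex region only.
    """
    if c.design_type is not DesignType.SIRNA:
        raise DesignTypeError(
            f"sirna_strands called on {c.design_type.value} candidate {c.oligo_id}"
        )
    guide = to_rna(c.antisense_seq)
    passenger = to_rna(c.sense_seq)
    if cfg.add_tt_overhang:
        guide += "TT"
        passenger += "TT"
    return guide, passenger
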