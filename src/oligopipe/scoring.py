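"""Efficacy and liability scoring.

Three scorers:

* ``sirna_point_score`` — a fixed point-based (Reynolds-style) checklist
  on the 19-nt sense strand, returning an integer in [0, 10].  It is
  registered behind the pluggable ``efficacy_scorer`` interface so a
  trained model can replace it without touching the pipeline.
* ``aso_score`` — target affinity on a 0..1 scale minus penalties for
  toxicity/promiscuity motifs and for strong self-structure.
* ``composite_score`` — the user-weighted linear combination of any
  numeric candidate properties.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable

from .core import DesignType, OligoCandidate, gc_content
from .errors import DependencyError, DesignTypeError, MissingPropertyError
from .thermo import ThermoProfile, hairpin_screen

__all__ = [
    "MotifRule",
    "ScoreWeights",
    "DEFAULT_ASO_MOTIFS",
    "sirna_point_score",
    "aso_score",
    "composite_score",
    "get_efficacy_scorer",
    "register_efficacy_scorer",
]


_RUN_SPEC = re.compile(r"^run\(([ACGT]),\s*(\d+)\)$")


@dataclass
class MotifRule:
    """A penalized sequence motif: a literal DNA string or ``run(X,n)``.

    ``run(X,n)`` matches n or more consecutive copies of base X.
    """

    pattern: str
    penalty: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError(f"motif penalty must be >= 0, got {self.penalty}")
        m = _RUN_SPEC.match(self.pattern)
        if m:
            base, n = m.group(1), int(m.group(2))
            self._regex = re.compile(f"{base}{{{n},}}")
        else:
            self._regex = re.compile(re.escape(self.pattern))
        if not self.label:
            self.label = self.pattern

    def matches(self, seq: str) -> bool:
        return bool(self._regex.search(seq))


DEFAULT_ASO_MOTIFS = [
    MotifRule("run(G,4)", 1.0, "poly-G/toxic"),
    MotifRule("run(A,4)", 0.5, "poly-A"),
    MotifRule("run(T,4)", 0.5, "poly-T"),
    MotifRule("run(C,4)", 0.5, "poly-C"),
]

ScoreWeights = dict[str, float]


def sirna_point_score(c: OligoCandidate) -> int | None:
    """Point-based siRNA functionality score on the 19-nt sense strand.

    Rules (positions 1-based on the sense/passenger strand):

    a. +1 if 30% <= GC <= 52%
    b. +1 per A/T at each of positions 15-19 (3' duplex end instability)
    c. +1 if no inverted-repeat stem of >= 4 bp (internal structure)
    d. +1 if position 19 is A
    e. +1 if position 3 is A
    f. +1 if position 10 is T
    g. -1 if position 19 is G or C
    h. -1 if position 13 is G

    Floored at 0; range [0, 10].  Defined for k == 19 only: other
    lengths return None and the property is omitted.
    """
    if c.design_type is not DesignType.SIRNA:
        raise DesignTypeError(
            f"sirna_point_score called on {c.design_type.value} "
            f"candidate {c.oligo_id}"
        )
    s = c.sense_seq
    if len(s) != 19 or "N" in s:
        return None
    score = 0
    if 30.0 <= gc_content(s) <= 52.0:
        score += 1
    score += sum(1 for b in s[14:19] if b in "AT")
    if hairpin_screen(s, min_stem=4) == 0:
        score += 1
    if s[18] == "A":
        score += 1
    if s[2] == "A":
        score += 1
    if s[9] == "T":
        score += 1
    if s[18] in "GC":
        score -= 1
    if s[12] == "G":
        score -= 1
    return max(score, 0)


def aso_score(
    c: OligoCandidate,
    thermo: ThermoProfile,
    motifs: list[MotifRule] | None = None,
    a_min: float = 10.0,
    a_max: float = 25.0,
    self_dimer_threshold: float = -8.0,
    hairpin_threshold: int = 6,
) -> float:
    """ASO liability-penalized affinity score (higher is better).

    score = S_affinity − P_motif − P_self, where S_affinity linearly
    rescales the duplex binding energy −ΔG37 from [a_min, a_max]
    kcal/mol onto [0, 1] (clamped); P_motif sums the penalties of motif
    rules matching the antisense sequence; P_self adds 0.5 for a strong
    self-dimer (ΔG37 below *self_dimer_threshold*) and 0.5 for a long
    hairpin stem (>= *hairpin_threshold* bp).
    """
    if c.design_type is not DesignType.ASO:
        raise DesignTypeError(
            f"aso_score called on {c.design_type.value} candidate {c.oligo_id}"
        )
    if thermo is None:
        raise DependencyError(
            f"aso_score for {c.oligo_id} requires a computed thermo profile"
        )
    if motifs is None:
        motifs = DEFAULT_ASO_MOTIFS
    affinity = (-thermo.duplex_dg37 - a_min) / (a_max - a_min)
    affinity = min(max(affinity, 0.0), 1.0)
    p_motif = sum(rule.penalty for rule in motifs
                  if rule.matches(c.antisense_seq))
    p_self = 0.0
    if thermo.self_dimer_dg37 < self_dimer_threshold:
        p_self += 0.5
    if thermo.hairpin_stem_max >= hairpin_threshold:
        p_self += 0.5
    return affinity - p_motif - p_self


def composite_score(c: OligoCandidate, weights: ScoreWeights) -> float:
    """Weighted linear combination of named numeric properties.

    Every weighted property must be present and numeric; a missing or
    non-numeric property raises rather than silently contributing zero.
    """
    total = 0.0
    for name, weight in weights.items():
        if name not in c.properties:
            raise MissingPropertyError(
                f"candidate {c.oligo_id} lacks property {name!r}"
            )
        value = c.properties[name]
        if isinstance(value, bool):
            value = int(value)
        if not isinstance(value, (int, float)):
            raise MissingPropertyError(
                f"property {name!r} of {c.oligo_id} is not numeric: {value!r}"
            )
        total += weight * value
    return total


_EFFICACY_SCORERS: dict[str, Callable[[OligoCandidate], int | float | None]] = {
    "point": sirna_point_score,
}


def register_efficacy_scorer(
    name: str, fn: Callable[[OligoCandidate], int | float | None]
) -> None:
    """Register a replacement efficacy scorer (e.g. a trained model)."""
    _EFFICACY_SCORERS[name] = fn


def get_efficacy_scorer(name: str) -> Callable[[OligoCandidate], int | float | None]:
    try:
        return _EFFICACY_SCORERS[name]
    except KeyError:
        raise MissingPropertyError(
            f"unknown efficacy scorer {name!r}; registered: "
            f"{sorted(_EFFICACY_SCORERS)}"
        ) from None
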