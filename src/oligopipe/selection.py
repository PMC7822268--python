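"""The selection funnel: hard filters plus a positional-diversity pick.

Filters run in a fixed order (snp, motif, offtarget, conservation,
score) and a rejected candidate is reported with *every* reason that
applies, so the funnel accounting is reproducible.  Survivors are then
optionally reduced to ``n_select`` by a greedy max-min spread on start
positions, so the chosen oligos tile the transcript instead of
clustering in one permissive region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import OligoCandidate
from .errors import ConfigurationError
from .scoring import MotifRule

logger = logging.getLogger(__name__)

__all__ = ["SelectionConfig", "SelectionResult", "apply_filters",
           "diversity_pick", "select"]

DEFAULT_MOTIF_FILTERS = ["run(G,4)", "run(T,4)"]


@dataclass
class SelectionConfig:
    """Thresholds and switches for the funnel.

    ``max_perfect_offtargets`` bounds the distinct-gene count at 0
    mismatches in the cDNA database (the "low complexity / promiscuous"
    filter).  ``min_score`` applies to the property named by
    ``score_property`` when set.
    """

    filter_snps: bool = True
    motif_filters: list[str] = field(
        default_factory=lambda: list(DEFAULT_MOTIF_FILTERS)
    )
    max_perfect_offtargets: int = 0
    require_conserved_species: list[str] = field(default_factory=list)
    min_score: float | None = None
    score_property: str = "sirna_score"
    n_select: int = 10
    diversity_pick: bool = True

    def __post_init__(self) -> None:
        if self.n_select < 1:
            raise ConfigurationError("n_select must be >= 1")
        if self.max_perfect_offtargets < 0:
            raise ConfigurationError("max_perfect_offtargets must be >= 0")


@dataclass
class SelectionResult:
    """Ordered survivors plus a per-candidate rejection-reason map."""

    selected: list[str]
    rejected: dict[str, list[str]]


def _require(c: OligoCandidate, prop: str, filter_name: str):
    if prop not in c.properties:
        raise ConfigurationError(
            f"filter {filter_name!r} enabled but candidate {c.oligo_id} "
            f"lacks property {prop!r}; run the producing stage first"
        )
    return c.properties[prop]


def apply_filters(
    candidates: list[OligoCandidate], cfg: SelectionConfig
) -> SelectionResult:
    """Run the hard filters; survivors keep input order.

    Reasons are evaluated in the fixed order snp, motif, offtarget,
    conservation, score, and a candidate collects all that apply.
    """
    motif_rules = [MotifRule(p, 0.0, p) for p in cfg.motif_filters]
    survivors: list[str] = []
    rejected: dict[str, list[str]] = {}
    for c in candidates:
        reasons: list[str] = []
        if cfg.filter_snps:
            if _require(c, "snp_count", "snp") > 0:
                reasons.append("snp")
        if motif_rules and any(r.matches(c.antisense_seq) for r in motif_rules):
            reasons.append("motif")
        if cfg.max_perfect_offtargets is not None:
            if _require(c, "cdna_mm0", "offtarget") > cfg.max_perfect_offtargets:
                reasons.append("offtarget")
        for species in cfg.require_conserved_species:
            if not _require(c, f"conserved_{species}", "conservation"):
                reasons.append("conservation")
                break
        if cfg.min_score is not None:
            if _require(c, cfg.score_property, "score") < cfg.min_score:
                reasons.append("score")
        if reasons:
            rejected[c.oligo_id] = reasons
        else:
            survivors.append(c.oligo_id)
    logger.info("selection filters: %d in, %d survive, %d rejected",
                len(candidates), len(survivors), len(rejected))
    return SelectionResult(selected=survivors, rejected=rejected)


def diversity_pick(
    survivors: list[OligoCandidate], n_select: int
) -> list[str]:
    """Greedy max-min spread on start positions.

    Seed with the smallest start, then repeatedly add the survivor whose
    minimum distance to the already-picked starts is largest (ties to the
    smaller start).  Returns min(n_select, len(survivors)) oligo IDs
    sorted by start.  The greedy farthest-point rule is a 2-approximation
    of the optimal max-min dispersion.
    """
    if not survivors:
        logger.info("diversity pick on empty survivor set")
        return []
    pool = sorted(survivors, key=lambda c: c.start)
    picked = [pool[0]]
    remaining = pool[1:]
    while remaining and len(picked) < n_select:
        best = max(
            remaining,
            key=lambda c: (min(abs(c.start - p.start) for p in picked),
                           -c.start),
        )
        picked.append(best)
        remaining.remove(best)
    picked.sort(key=lambda c: c.start)
    return [c.oligo_id for c in picked]


def select(
    candidates: list[OligoCandidate], cfg: SelectionConfig
) -> SelectionResult:
    """Filters followed by the optional diversity pick; annotates candidates.

    Sets ``selected`` (0/1) and ``reject_reasons`` on every candidate.
    """
    result = apply_filters(candidates, cfg)
    by_id = {c.oligo_id: c for c in candidates}
    if cfg.diversity_pick:
        final = diversity_pick([by_id[i] for i in result.selected],
                               cfg.n_select)
    else:
        final = result.selected[: cfg.n_select]
    result = SelectionResult(selected=final, rejected=result.rejected)
    for c in candidates:
        c.properties["selected"] = c.oligo_id in final
        c.properties["reject_reasons"] = ";".join(
            result.rejected.get(c.oligo_id, [])
        )
    return result
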