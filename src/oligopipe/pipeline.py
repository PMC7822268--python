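"""Stage orchestration over a workspace directory.

Each stage reads the candidate CSV written by the previous stage,
appends its property columns and rewrites the file, so the workflow can
be run end-to-end or stage by stage and every intermediate is a plain
CSV.  Stages never mutate earlier columns.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import annotation, offtarget, scoring, selection, thermo
from .core import DesignType, OligoCandidate, Transcript
from .enumeration import EnumerationConfig, enumerate_candidates
from .errors import ConfigurationError, DependencyError
from .io_formats import (
    RunConfig,
    read_csv,
    read_exons,
    read_fasta,
    read_snps,
    write_csv,
)
from .scoring import MotifRule, get_efficacy_scorer
from .selection import SelectionConfig, select

logger = logging.getLogger(__name__)

CANDIDATES_FILE = "candidates.csv"


def _load_transcripts(cfg: RunConfig) -> tuple[Transcript, list[Transcript]]:
    transcripts = read_fasta(cfg.transcripts_fasta, is_primary_id=cfg.primary_id)
    primary = next(
        (t for t in transcripts if t.transcript_id == cfg.primary_id), None
    )
    if primary is None:
        raise ConfigurationError(
            f"primary transcript {cfg.primary_id!r} not found in "
            f"{cfg.transcripts_fasta}"
        )
    if cfg.exons_path:
        exon_map = read_exons(cfg.exons_path, cfg.exons_format)
        ends = exon_map.get(primary.transcript_id, [])
        primary = Transcript(primary.transcript_id, primary.gene_id,
                             primary.species, primary.sequence,
                             exon_ends=ends, is_primary=True)
    others = [t for t in transcripts if t.transcript_id != cfg.primary_id]
    return primary, others


def _candidates_path(workspace: str | Path) -> Path:
    return Path(workspace) / CANDIDATES_FILE


def _load_candidates(workspace: str | Path, stage: str) -> list[OligoCandidate]:
    path = _candidates_path(workspace)
    if not path.exists():
        raise DependencyError(
            f"stage {stage!r} needs {path}; run the enumerate stage first"
        )
    return read_csv(path)


def stage_enumerate(cfg: RunConfig, workspace: str | Path) -> list[OligoCandidate]:
    primary, _ = _load_transcripts(cfg)
    candidates = enumerate_candidates(
        primary,
        EnumerationConfig(k=cfg.k, design_type=cfg.design_type,
                          add_tt_overhang=cfg.add_tt_overhang),
    )
    logger.info("enumerate: %d candidates (L=%d, k=%d)",
                len(candidates), len(primary.sequence), cfg.k)
    write_csv(candidates, _candidates_path(workspace))
    return candidates


def stage_annotate(cfg: RunConfig, workspace: str | Path) -> list[OligoCandidate]:
    candidates = _load_candidates(workspace, "annotate")
    primary, others = _load_transcripts(cfg)
    snps = read_snps(cfg.vcf_path) if cfg.vcf_path else []
    indexes = annotation.build_conservation_indexes(others)
    for c in candidates:
        annotation.annotate_gc(c)
        annotation.annotate_snps(c, snps, primary.transcript_id)
        annotation.annotate_junction(c, primary)
        annotation.annotate_conservation(c, others, indexes)
    logger.info("annotate: %d candidates, %d comparison transcripts, %d SNPs",
                len(candidates), len(others), len(snps))
    write_csv(candidates, _candidates_path(workspace))
    return candidates


def stage_offtarget(cfg: RunConfig, workspace: str | Path) -> list[OligoCandidate]:
    candidates = _load_candidates(workspace, "offtarget")
    primary, _ = _load_transcripts(cfg)
    if not cfg.cdna_fasta:
        raise ConfigurationError("offtarget stage requires cdna_fasta")
    cdna_index = offtarget.build_index(read_fasta(cfg.cdna_fasta), "cdna")
    gene_index = None
    if cfg.design_type is DesignType.ASO:
        if not cfg.gene_fasta:
            raise ConfigurationError(
                "ASO off-target search requires gene_fasta (unspliced genes)"
            )
        gene_index = offtarget.build_index(read_fasta(cfg.gene_fasta), "gene")
    for c in candidates:
        offtarget.offtarget_profile(
            c, cdna_index, gene_index,
            target_gene_id=primary.gene_id, max_mm=cfg.max_mismatches,
        )
    logger.info("offtarget: %d candidates profiled", len(candidates))
    write_csv(candidates, _candidates_path(workspace))
    return candidates


def stage_score(cfg: RunConfig, workspace: str | Path) -> list[OligoCandidate]:
    candidates = _load_candidates(workspace, "score")
    params = thermo.load_params(cfg.thermo_params)
    aso_kwargs = dict(cfg.aso_score)
    motifs = None
    if "motifs" in aso_kwargs:
        motifs = [MotifRule(m["pattern"], m["penalty"], m.get("label", ""))
                  for m in aso_kwargs.pop("motifs")]
    scorer = get_efficacy_scorer(cfg.efficacy_scorer)
    for c in candidates:
        if "N" in c.antisense_seq:
            continue  # thermodynamics undefined under ambiguity
        profile = thermo.thermo_profile(c.antisense_seq, params)
        c.properties["duplex_dg37"] = profile.duplex_dg37
        c.properties["duplex_tm"] = profile.duplex_tm
        c.properties["self_dimer_dg37"] = profile.self_dimer_dg37
        c.properties["hairpin_stem_max"] = profile.hairpin_stem_max
        if cfg.design_type is DesignType.SIRNA:
            score = scorer(c)
            if score is not None:
                c.properties["sirna_score"] = score
        else:
            c.properties["aso_score"] = scoring.aso_score(
                c, profile, motifs=motifs, **aso_kwargs
            )
        if cfg.weights:
            c.properties["composite"] = scoring.composite_score(c, cfg.weights)
    logger.info("score: %d candidates scored", len(candidates))
    write_csv(candidates, _candidates_path(workspace))
    return candidates


def stage_select(cfg: RunConfig, workspace: str | Path):
    candidates = _load_candidates(workspace, "select")
    sel_cfg = SelectionConfig(**cfg.selection)
    result = select(candidates, sel_cfg)
    logger.info("select: %d in, %d rejected, %d selected",
                len(candidates), len(result.rejected), len(result.selected))
    write_csv(candidates, _candidates_path(workspace))
    return result


def stage_export(cfg: RunConfig, workspace: str | Path,
                 out: str | Path | None = None) -> Path:
    candidates = _load_candidates(workspace, "export")
    out = Path(out) if out else Path(workspace) / "results.csv"
    write_csv(candidates, out)
    logger.info("export: wrote %d candidates to %s", len(candidates), out)
    return out


def run_all(cfg: RunConfig, workspace: str | Path,
            out: str | Path | None = None) -> Path:
    """Chain all stages: enumerate, annotate, offtarget, score, select, export."""
    stage_enumerate(cfg, workspace)
    stage_annotate(cfg, workspace)
    stage_offtarget(cfg, workspace)
    stage_score(cfg, workspace)
    stage_select(cfg, workspace)
    return stage_export(cfg, workspace, out)
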