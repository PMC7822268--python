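"""Readers and writers for the pipeline's file formats.

FASTA headers follow ``>transcriptID|geneID|species`` (species optional,
defaults to ``unknown``).  Exon structures come as BED3 (0-based
half-open) or GFF3 ``exon`` features (1-based inclusive), both in
transcript coordinates (seqid = transcript ID).  SNPs come as VCF with
CHROM = transcript ID and POS = 1-based transcript coordinate.

The candidate CSV is the pipeline's on-disk state: six fixed core
columns followed by property columns; floats printed with 4 decimals,
missing properties as empty cells, LF line endings.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import DesignType, OligoCandidate, SnpRecord, Transcript
from .errors import (
    ConfigurationError,
    DuplicateRecordError,
    FormatError,
)

logger = logging.getLogger(__name__)

CORE_COLUMNS = (
    "oligo_id",
    "design_type",
    "start_1based",
    "end_1based",
    "sense_seq",
    "antisense_seq",
)


def read_fasta(path: str | Path, is_primary_id: str | None = None) -> list[Transcript]:
    """Read transcripts from FASTA with ``transcriptID|geneID|species`` headers.

    Sequences are uppercased and U->T normalised; record order is preserved.
    """
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for n, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        parts = rec.description.split()[0].split("|") if rec.description else []
        if not parts or not parts[0]:
            raise FormatError(f"{path}: record {n}: header has no transcript ID")
        tid = parts[0]
        gene = parts[1] if len(parts) > 1 and parts[1] else tid
        species = parts[2] if len(parts) > 2 and parts[2] else "unknown"
        if tid in seen:
            raise DuplicateRecordError(
                f"{path}: duplicate transcript_id {tid!r} (record {n})"
            )
        seen.add(tid)
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_id=gene,
                species=species,
                sequence=str(rec.seq),
                is_primary=(tid == is_primary_id),
            )
        )
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    """Write transcripts with the ``transcriptID|geneID|species`` header convention."""
    records = [
        SeqRecord(
            Seq(t.sequence),
            id=f"{t.transcript_id}|{t.gene_id}|{t.species}",
            description="",
        )
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def _junctions_from_intervals(
    tid: str, intervals: list[tuple[int, int]]
) -> list[int]:
    """Exon intervals (0-based half-open) -> junction offsets, excluding the
    transcript end."""
    intervals = sorted(intervals)
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise FormatError(
                f"overlapping exons for transcript {tid}: "
                f"[{s1},{e1}) and [{s2},{e2})"
            )
    ends = [e for _, e in intervals]
    return ends[:-1]


def read_exons(path: str | Path, fmt: str = "BED") -> dict[str, list[int]]:
    """Read exon structures; returns transcript_id -> ascending junction offsets.

    ``fmt`` is ``"BED"`` (BED3, 0-based half-open) or ``"GFF3"`` (``exon``
    features, 1-based inclusive).  In both cases coordinates are on the
    transcript, so junctions are simply the sorted exon end offsets with
    the final (transcript-end) offset dropped.
    """
    fmt = fmt.upper()
    if fmt not in ("BED", "GFF3"):
        raise ConfigurationError(f"unknown exon format {fmt!r}; use BED or GFF3")
    per_tid: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "BED":
                    tid, start, end = fields[0], int(fields[1]), int(fields[2])
                else:
                    if len(fields) < 5:
                        raise ValueError("fewer than 5 GFF3 columns")
                    if fields[2].lower() != "exon":
                        continue
                    tid = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if end <= start:
                raise FormatError(
                    f"{path}: line {lineno}: empty or inverted interval"
                )
            per_tid.setdefault(tid, []).append((start, end))
    return {
        tid: _junctions_from_intervals(tid, ivals)
        for tid, ivals in per_tid.items()
    }


def read_snps(path: str | Path) -> list[SnpRecord]:
    """Read SNVs from a VCF; CHROM = transcript ID, POS = 1-based offset.

    Multi-allelic ALT is preserved as a list.  Indels are skipped with a
    logged warning.
    """
    snps: list[SnpRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 5 VCF columns, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, snp_id, ref, alt = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer POS {pos_s!r}"
                ) from exc
            alts = alt.split(",")
            if len(ref) != 1 or any(len(a) != 1 for a in alts):
                logger.warning(
                    "%s: line %d: skipping non-SNV record %s (REF=%s ALT=%s)",
                    path, lineno, snp_id, ref, alt,
                )
                continue
            snps.append(SnpRecord(chrom, pos, snp_id, ref.upper(),
                                  [a.upper() for a in alts]))
    return snps


def write_vcf(snps: Iterable[SnpRecord], path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF v4.2 with transcript-coordinate records."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for tid, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={tid},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snps:
            fh.write(
                f"{s.transcript_id}\t{s.pos}\t{s.snp_id}\t{s.ref_allele}\t"
                f"{','.join(s.alt_alleles)}\t.\t.\t.\n"
            )


def _format_cell(value) -> str:
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return f"{value:.4f}"
    return str(value)


def write_csv(
    candidates: list[OligoCandidate],
    path: str | Path,
    column_order: list[str] | None = None,
) -> None:
    """Write annotated candidates as CSV (RFC 4180 quoting, LF endings).

    Core columns first, then property columns in *column_order* (default:
    first-seen order across candidates).  Missing properties render as
    empty cells; floats with 4 decimals.
    """
    if candidates:
        types = {c.design_type for c in candidates}
        if len(types) > 1:
            raise ConfigurationError(
                "candidates mix design types; write them separately"
            )
    if column_order is None:
        column_order = []
        seen = set()
        for c in candidates:
            for name in c.properties:
                if name not in seen:
                    seen.add(name)
                    column_order.append(name)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(list(CORE_COLUMNS) + list(column_order))
        for c in candidates:
            row = [
                c.oligo_id,
                c.design_type.value,
                c.start_1based,
                c.end_1based,
                c.sense_seq,
                c.antisense_seq,
            ]
            for name in column_order:
                if name in c.properties:
                    row.append(_format_cell(c.properties[name]))
                else:
                    row.append("")
            writer.writerow(row)


def _parse_cell(text: str):
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def read_csv(path: str | Path) -> list[OligoCandidate]:
    """Read back a candidate CSV written by :func:`write_csv`.

    Property cells are parsed as int, then float, else kept as string;
    empty cells stay absent.  Flags round-trip as 0/1 integers.
    """
    candidates: list[OligoCandidate] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[: len(CORE_COLUMNS)] != list(CORE_COLUMNS):
            raise FormatError(f"{path}: not a candidate CSV (bad header)")
        prop_names = header[len(CORE_COLUMNS):]
        for row in reader:
            core = row[: len(CORE_COLUMNS)]
            props = {}
            for name, cell in zip(prop_names, row[len(CORE_COLUMNS):]):
                if cell != "":
                    props[name] = _parse_cell(cell)
            candidates.append(
                OligoCandidate(
                    oligo_id=core[0],
                    design_type=DesignType(core[1]),
                    start=int(core[2]) - 1,
                    end=int(core[3]),
                    sense_seq=core[4],
                    antisense_seq=core[5],
                    properties=props,
                )
            )
    return candidates


@dataclass
class RunConfig:
    """Full pipeline configuration, loadable from YAML.

    ``k`` defaults to 20 for ASO and 19 for siRNA when not given.
    All paths are resolved relative to the config file's directory.
    """

    design_type: DesignType = DesignType.ASO
    k: int = 0
    max_mismatches: int = 2
    add_tt_overhang: bool = False
    rng_seed: int = 0
    primary_id: str = ""
    transcripts_fasta: str = ""
    cdna_fasta: str = ""
    gene_fasta: str = ""
    exons_path: str = ""
    exons_format: str = "BED"
    vcf_path: str = ""
    efficacy_scorer: str = "point"
    thermo_params: str = ""  # default chosen per design type
    aso_score: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    weights: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.design_type, str):
            self.design_type = DesignType(self.design_type.upper())
        if not self.k:
            self.k = 20 if self.design_type is DesignType.ASO else 19
        if self.k < 8:
            raise ConfigurationError(f"k must be >= 8, got {self.k}")
        if not 0 <= self.max_mismatches <= 2:
            raise ConfigurationError(
                f"max_mismatches must be 0..2, got {self.max_mismatches}"
            )
        if not self.thermo_params:
            # ASO:target is a DNA:RNA hybrid; siRNA thermo uses RNA-like
            # stacks approximated by the hybrid table on the DNA alphabet.
            self.thermo_params = "dna_rna"


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config, resolving relative paths against its directory."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = RunConfig(**raw)
    base = path.parent
    for attr in ("transcripts_fasta", "cdna_fasta", "gene_fasta",
                 "exons_path", "vcf_path"):
        val = getattr(cfg, attr)
        if val:
            setattr(cfg, attr, str((base / val).resolve()))
    return cfg
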