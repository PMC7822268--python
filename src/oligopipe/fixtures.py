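"""Seeded synthetic-data generator for every input the pipeline consumes.

Emulates the offline substitute for live transcript retrieval: a
multi-exon target gene (unspliced sequence + spliced primary transcript
+ exon structure), splice variants, orthologs at per-species
substitution rates, a decoy off-target transcriptome with optionally
planted near-matches, and transcript-coordinate SNPs.

One integer seed fans out to fixed per-component child seeds (seed XOR
CRC32 of a component tag), so adding a component never perturbs the
random streams of the others.  Two runs with the same spec produce
byte-identical files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import SnpRecord, Transcript
from .io_formats import write_fasta, write_vcf

__all__ = [
    "FixtureSpec",
    "make_gene",
    "make_orthologs",
    "make_splice_variants",
    "make_offtarget_db",
    "make_snps",
    "write_workspace",
]

_BASES = np.array(list("ACGT"))


def _child_rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng(
        (int(seed) ^ zlib.crc32(tag.encode())) % (2**31)
    )


def _random_seq(rng: np.random.Generator, length: int,
                gc_bias: float = 0.5) -> str:
    p_gc = gc_bias / 2.0
    p_at = (1.0 - gc_bias) / 2.0
    return "".join(
        rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    )


@dataclass
class FixtureSpec:
    """Parameters of one synthetic design problem.

    ``ortholog_species`` maps species name to a per-base substitution
    rate.  ``planted_offtargets`` is a list of
    ``(decoy_index, mismatches, window_start)`` tuples: the k-mer window
    of the primary transcript at *window_start* is copied into that
    decoy with exactly *mismatches* substitutions.
    """

    rng_seed: int = 0
    n_exons: int = 3
    exon_len_range: tuple[int, int] = (80, 160)
    intron_len_range: tuple[int, int] = (60, 120)
    n_splice_variants: int = 1
    ortholog_species: dict[str, float] = field(
        default_factory=lambda: {"mouse": 0.08}
    )
    n_decoy_genes: int = 50
    decoy_len: int = 1000
    n_snps: int = 5
    k: int = 19
    planted_offtargets: list[tuple[int, int, int]] = field(default_factory=list)
    gc_bias: float = 0.5

    def __post_init__(self) -> None:
        for rate in self.ortholog_species.values():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"substitution rate {rate} outside [0,1]")
        for count in (self.n_exons, self.n_splice_variants,
                      self.n_decoy_genes, self.n_snps):
            if count < 0:
                raise ValueError("counts must be >= 0")


def make_gene(spec: FixtureSpec) -> tuple[Transcript, Transcript,
                                          list[tuple[int, int]]]:
    """Generate (unspliced gene, spliced primary transcript, exon BED rows).

    The gene is alternating exons and introns of uniformly drawn lengths;
    the transcript is the exon concatenation, with ``exon_ends`` holding
    the junction offsets.  BED rows are in transcript coordinates.
    """
    rng = _child_rng(spec.rng_seed, "gene")
    exon_lens = [int(rng.integers(*spec.exon_len_range, endpoint=True))
                 for _ in range(spec.n_exons)]
    intron_lens = [int(rng.integers(*spec.intron_len_range, endpoint=True))
                   for _ in range(max(spec.n_exons - 1, 0))]
    exons = [_random_seq(rng, ln, spec.gc_bias) for ln in exon_lens]
    introns = [_random_seq(rng, ln, spec.gc_bias) for ln in intron_lens]
    gene_parts = []
    for i, exon in enumerate(exons):
        gene_parts.append(exon)
        if i < len(introns):
            gene_parts.append(introns[i])
    gene_seq = "".join(gene_parts)
    tx_seq = "".join(exons)
    ends = np.cumsum(exon_lens).tolist()
    exon_ends = [int(e) for e in ends[:-1]]
    bed_rows = [(int(ends[i] - exon_lens[i]), int(ends[i]))
                for i in range(len(exon_lens))]
    gene = Transcript("G1_unspliced", "G1", "human", gene_seq)
    primary = Transcript("T1", "G1", "human", tx_seq,
                         exon_ends=exon_ends, is_primary=True)
    return gene, primary, bed_rows


def make_splice_variants(primary: Transcript,
                         spec: FixtureSpec) -> list[Transcript]:
    """Variants of the same gene made by dropping one internal exon each."""
    bounds = [0] + list(primary.exon_ends) + [len(primary.sequence)]
    exons = [primary.sequence[bounds[i]:bounds[i + 1]]
             for i in range(len(bounds) - 1)]
    variants = []
    n = min(spec.n_splice_variants, max(len(exons) - 1, 0))
    for v in range(n):
        drop = 1 + (v % max(len(exons) - 1, 1))  # never drop the first exon
        kept = [e for i, e in enumerate(exons) if i != drop]
        seq = "".join(kept)
        ends = np.cumsum([len(e) for e in kept])[:-1]
        variants.append(
            Transcript(f"{primary.transcript_id}v{v + 2}", primary.gene_id,
                       primary.species, seq,
                       exon_ends=[int(e) for e in ends])
        )
    return variants


def make_orthologs(primary: Transcript, spec: FixtureSpec) -> list[Transcript]:
    """Per species: i.i.d. per-base substitution at the stated rate,
    never to the same base."""
    orthologs = []
    for species, rate in sorted(spec.ortholog_species.items()):
        rng = _child_rng(spec.rng_seed, f"ortholog:{species}")
        seq = np.array(list(primary.sequence))
        hit = rng.random(len(seq)) < rate
        for i in np.flatnonzero(hit):
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = choices[int(rng.integers(0, 3))]
        orthologs.append(
            Transcript(f"{primary.transcript_id}_{species}",
                       f"{primary.gene_id}_{species}", species,
                       "".join(seq))
        )
    return orthologs


def _plant(window: str, n_mm: int, rng: np.random.Generator) -> str:
    """Copy of *window* with exactly *n_mm* substitutions at seeded positions."""
    if n_mm > len(window):
        raise ValueError(
            f"cannot plant {n_mm} mismatches in a {len(window)}-nt window"
        )
    seq = list(window)
    positions = rng.choice(len(seq), size=n_mm, replace=False)
    for p in positions:
        choices = [b for b in "ACGT" if b != seq[p]]
        seq[p] = choices[int(rng.integers(0, 3))]
    return "".join(seq)


def make_offtarget_db(primary: Transcript,
                      spec: FixtureSpec) -> list[Transcript]:
    """The cDNA decoy database: the target transcript itself plus random
    decoy genes, with any planted near-match windows spliced in."""
    rng = _child_rng(spec.rng_seed, "decoys")
    decoys = [
        Transcript(f"D{i + 1}", f"GD{i + 1}", "human",
                   _random_seq(rng, spec.decoy_len, spec.gc_bias))
        for i in range(spec.n_decoy_genes)
    ]
    plant_rng = _child_rng(spec.rng_seed, "plants")
    for decoy_idx, n_mm, win_start in spec.planted_offtargets:
        window = primary.sequence[win_start:win_start + spec.k]
        if len(window) < spec.k:
            raise ValueError(
                f"planted window at {win_start} runs past the transcript end"
            )
        planted = _plant(window, n_mm, plant_rng)
        d = decoys[decoy_idx]
        insert_at = int(plant_rng.integers(0, len(d.sequence) - spec.k + 1))
        seq = (d.sequence[:insert_at] + planted
               + d.sequence[insert_at + spec.k:])
        decoys[decoy_idx] = Transcript(d.transcript_id, d.gene_id,
                                       d.species, seq)
    return [primary] + decoys


def make_snps(primary: Transcript, spec: FixtureSpec) -> list[SnpRecord]:
    """Seeded SNVs at distinct positions; ref always matches the transcript."""
    rng = _child_rng(spec.rng_seed, "snps")
    n = min(spec.n_snps, len(primary.sequence))
    positions = sorted(
        int(p) + 1
        for p in rng.choice(len(primary.sequence), size=n, replace=False)
    )
    snps = []
    for i, pos in enumerate(positions, start=1):
        ref = primary.sequence[pos - 1]
        choices = [b for b in "ACGT" if b != ref]
        alt = choices[int(rng.integers(0, 3))]
        snps.append(SnpRecord(primary.transcript_id, pos, f"rs{i}",
                              ref, [alt]))
    return snps


def write_workspace(spec: FixtureSpec, outdir: str | Path,
                    design_type: str = "SIRNA") -> Path:
    """Write a complete demo workspace: FASTAs, BED, VCF and config.yaml.

    Returns the path of the written config file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene, primary, bed_rows = make_gene(spec)
    variants = make_splice_variants(primary, spec)
    orthologs = make_orthologs(primary, spec)
    cdna_db = make_offtarget_db(primary, spec)
    snps = make_snps(primary, spec)

    write_fasta([primary] + variants + orthologs,
                outdir / "transcripts.fasta")
    write_fasta(cdna_db, outdir / "cdna_db.fasta")
    write_fasta([gene] + [t for t in cdna_db if t.gene_id != primary.gene_id],
                outdir / "gene_db.fasta")
    with open(outdir / "exons.bed", "w", newline="\n") as fh:
        for start, end in bed_rows:
            fh.write(f"{primary.transcript_id}\t{start}\t{end}\n")
    write_vcf(snps, outdir / "snps.vcf",
              {primary.transcript_id: len(primary.sequence)})

    config = {
        "design_type": design_type,
        "k": spec.k,
        "max_mismatches": 2,
        "rng_seed": spec.rng_seed,
        "primary_id": primary.transcript_id,
        "transcripts_fasta": "transcripts.fasta",
        "cdna_fasta": "cdna_db.fasta",
        "gene_fasta": "gene_db.fasta",
        "exons_path": "exons.bed",
        "exons_format": "BED",
        "vcf_path": "snps.vcf",
        "selection": {
            "filter_snps": True,
            "motif_filters": ["run(G,4)", "run(T,4)"],
            "max_perfect_offtargets": 0,
            "n_select": 10,
            "diversity_pick": True,
        },
        "weights": {},
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w", newline="\n") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path
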