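# oligopipe

Offline design of antisense oligonucleotides (ASOs) and small interfering
RNAs (siRNAs) against a target transcript.

Designing an ASO or a 19-bp siRNA duplex means choosing a handful of
sequences from the hundreds of k-mer windows that tile an mRNA, trading
off competing criteria: specificity against the rest of the
transcriptome, avoidance of known SNPs and of toxicity-associated
sequence motifs (poly-G, poly-T runs), duplex thermodynamics,
exon-junction placement, cross-species conservation for in-vivo
validation, and predicted silencing efficacy.  `oligopipe` makes that a
reproducible, scriptable funnel: it enumerates **every** candidate,
annotates each with the properties above, and applies a configurable
filter-and-pick selection — entirely from local files, with no network
access.

## What it computes

* **Enumeration** — all `L − k + 1` windows of the primary transcript;
  for siRNA, guide = reverse complement of the target window (rendered
  as RNA), passenger = the window itself.
* **Off-target search** — each oligo is searched against a cDNA
  database (and, for ASOs, an unspliced-gene database) allowing up to 2
  mismatches, using a pigeonhole seed-and-verify engine: a query split
  into 3 segments must match one segment exactly for any occurrence
  within 2 mismatches, so the search is provably exhaustive.  Hits are
  reduced to **distinct genes at 0/1/2 mismatches** (each gene at its
  minimum level, the intended target excluded).  For siRNA both guide
  and passenger strands are profiled against cDNA; for ASO the window is
  searched against cDNA and unspliced genes.
* **Annotation** — GC%, overlap with transcript-coordinate SNPs,
  exon-junction spanning, and per-transcript conservation
  (minimum mismatches ≤ 2 against splice variants and orthologs).
* **Thermodynamics** — nearest-neighbor duplex ΔG37 and two-state Tm
  (`ΔG37 = ΔH − T·ΔS`, `Tm = ΔH·1000/(ΔS + R·ln(CT/4)) − 273.15`),
  with shipped DNA:DNA and DNA:RNA hybrid parameter tables, plus
  exhaustive self-dimer and hairpin-stem screens.
* **Scoring** — a point-based (Reynolds-style) siRNA checklist score in
  [0, 10] behind a pluggable efficacy-scorer interface; an ASO score
  `S_affinity − P_motif − P_self` penalizing weak binders, toxic motifs
  and self-structure; and a user-weighted composite
  `Σ wᵢ·propertyᵢ`.
* **Selection** — hard filters (SNP overlap, poly-G/poly-T motifs,
  perfect off-target count, conservation, minimum score) with full
  rejection-reason accounting, then a greedy max-min spread on start
  positions so the final picks tile the transcript.
* **Notation** — a HELM-style monomer notation
  (`RNA1{[LR](A)[sP].[dR](C)P...}$$$$`) for chemically modified oligos
  (DNA/RNA/LNA/2'OMe sugars, phosphorothioate backbones), with
  round-tripping parser and two plain-text renderings.

## Worked example

Generate a fully synthetic design problem (3-exon gene, splice variant,
mouse ortholog, 50 decoy genes, 5 SNPs) and run the whole funnel:

```bash
oligopipe fixtures --workspace demo --seed 7 --design sirna
oligopipe run --config demo/config.yaml --workspace demo
```

which logs the funnel accounting:

```
INFO oligopipe.pipeline annotate: 395 candidates, 2 comparison transcripts, 5 SNPs
INFO oligopipe.pipeline offtarget: 395 candidates profiled
INFO oligopipe.pipeline score: 395 candidates scored
INFO oligopipe.selection selection filters: 395 in, 297 survive, 98 rejected
INFO oligopipe.pipeline select: 395 in, 98 rejected, 10 selected
INFO oligopipe.pipeline export: wrote 395 candidates to demo/results.csv
```

The 413-nt transcript yields 395 19-mer candidates; 98 are rejected
(SNP overlap, poly-G/poly-T motifs or perfect off-targets), and the
diversity pick keeps 10 spread along the transcript.  The first
selected rows of `demo/results.csv`:

```
oligo_id,start_1based,antisense_seq,gc_percent,sirna_score,cdna_mm0,snp_count
T1_6,6,CCTCTCCCAGTTTGTCGAT,52.6316,1,0,0
T1_54,54,CGCGAGATGGTTGTTCCAT,52.6316,0,0,0
T1_103,103,GACTTCCCCCTGGCGTGCT,68.4211,2,0,0
```

Each row is one candidate: its 1-based window, the guide/oligo
sequence, GC%, the point-based efficacy score (0–10), the count of
*other* genes hit with zero mismatches (0 = fully specific), and the
number of known SNPs inside the window.  Stages can also be run
individually (`oligopipe enumerate|annotate|offtarget|score|select|export`),
each reading and extending `candidates.csv` in the workspace.

Real inputs use the same formats the fixtures emit: FASTA with
`>transcriptID|geneID|species` headers, BED3/GFF3 exons and VCF SNPs in
transcript coordinates, and a YAML config (see the generated
`demo/config.yaml` for the schema).

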