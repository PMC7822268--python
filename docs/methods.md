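# Methods

This note documents the models, conventions and numerical choices behind
`oligopipe`, and what the synthetic-data tests do and do not establish
about behaviour on real transcriptomes.

## Sequence model and coordinates

All sequences are held internally in the DNA alphabet {A, C, G, T, N};
RNA input is normalised (U→T) on load and rendered back to RNA only for
display, so search, conservation and thermodynamics all operate on one
canonical alphabet.  Coordinates are 0-based half-open internally and
1-based inclusive in every user-facing CSV.  `N` is handled
conservatively: it never matches any base (including another `N`) when
counting mismatches, and never counts as G/C.  This makes off-target
counts an upper bound with respect to any more permissive ambiguity
convention.  Candidate windows containing `N` are enumerated and flagged
(`has_ambiguity`) rather than dropped — whether to exclude them is a
selection decision; they are skipped by the thermodynamics stage, where
stack energies for ambiguous dimers are undefined.

## Off-target search

The engine is a pigeonhole seed-and-verify scheme over an exact-lookup
k-mer table.  A query of length k is split into 3 segments of length
⌊k/3⌋ (remainder absorbed by the last segment); any occurrence with ≤ 2
mismatches must contain at least one mismatch-free segment, so exact
lookup of each segment followed by full Hamming verification of the
implied window is complete for ≤ 2 mismatches.  Seed tables are built
lazily per segment length, so one index serves any query length.
String-equal seeds spanning `N` are false positives of the seed stage
only; verification applies the N-never-matches rule and rejects them.

Gene-level summaries count **distinct genes**, each at the *minimum*
mismatch level among its hits, with the intended target gene excluded by
`gene_id`.  Minimum-level counting is order-free and avoids double
counting a gene at several levels; whether counts should instead be
cumulative across levels is a genuinely open convention, and cumulative
counts are recoverable by summation if wanted.

Strand handling keeps a single search direction: the database is stored
as given (sense text), and the caller supplies the sequence expected to
occur verbatim in that text.  For an siRNA, the guide base-pairs
transcript text equal to the sense window (query = sense), the passenger
base-pairs text equal to the window's reverse complement
(query = antisense); for an ASO the sense window is searched against
both the cDNA and unspliced-gene databases.  All positions weigh equally
in the mismatch count; no seed-region (positions 2–8) weighting is
applied.

## Thermodynamics

Duplex stability uses the standard nearest-neighbor sum
ΔG37 = ΔG_init + Σ stacks (+ terminal-pair terms where the set defines
them), at 310.15 K with R = 1.987 cal/(mol·K).  Two parameter tables
ship as TSV data files and are consistency-checked on load
(ΔG37 vs ΔH − T·ΔS within 0.05 kcal/mol per entry):

* `dna_dna` — the unified DNA:DNA set with terminal A·T / G·C
  initiation terms (16 stacks expanded from the 10 unique values by
  reverse-complement symmetry);
* `dna_rna` — the DNA:RNA hybrid set re-keyed by the DNA (oligo) strand
  5'→3', with a single initiation term.  This is the default for
  scoring, since an ASO:mRNA duplex is a DNA:RNA hybrid.

Melting temperature is the two-state estimate
Tm = ΔH·1000 / (ΔS + R·ln(CT/4)) − 273.15 (CT = total oligo
concentration, default 1 µM), with the 16.6·log10([Na+]) correction when
the salt concentration differs from 1 M.  These values describe
**unmodified** oligos; chemistry that raises Tm substantially (LNA,
2'OMe) is represented in the notation layer but deliberately not in the
energy model.

The intra/inter-molecular screens are exhaustive, desk-scale surrogates
for partition-function structure prediction, chosen for oracle
testability rather than physical completeness: `self_dimer_dg` scores
every maximal complementary run (≥ 2 bp) across all ungapped
antiparallel self-alignments as a standalone nearest-neighbor duplex and
reports the most stable (clamped at 0, so the value is never positive);
`hairpin_screen` reports the longest inverted-repeat stem with loop ≥ 3
nt, returning 0 below a 4-bp minimum stem.  Neither models loop
entropies, bulges or coaxial stacking.

## Scoring

`sirna_point_score` is a fixed point-based checklist on the 19-nt sense
strand (GC window 30–52%, A/T richness at positions 15–19, absence of a
≥ 4-bp internal stem, A at 19, A at 3, U/T at 10, penalties for G/C at
19 and G at 13), floored at 0, range [0, 10].  It is defined only for
k = 19; other lengths omit the property.  The scorer sits behind a
registry (`efficacy_scorer` config key) so a trained model can replace
it without touching the pipeline; the checklist is the shipped default
because it is transparent and has no training-data dependency.

`aso_score = S_affinity − P_motif − P_self`, where S_affinity rescales
−ΔG37 of the oligo:target hybrid linearly from [10, 25] kcal/mol onto
[0, 1] (clamped); P_motif sums penalties of motif rules matching the
oligo strand (defaults: G-run ≥ 4 → 1.0; A-, T-, C-runs ≥ 4 → 0.5 each);
P_self adds 0.5 for a self-dimer below −8 kcal/mol and 0.5 for a hairpin
stem ≥ 6 bp.  The affinity window, motif table and structure thresholds
are config-exposed defaults, not fitted constants: they encode the
qualitative design rules (penalise weak binders, toxic/promiscuous
motifs, strong self-structure) with round numbers on the kcal/mol scale.

`composite_score` is a plain weighted sum over named numeric properties;
a missing property is an error rather than a silent zero, so a weight
typo cannot quietly distort a ranking.

## Selection

Filters run in the fixed order snp → motif → offtarget → conservation →
score, and a rejected candidate records *every* applicable reason, so
funnel accounting is reproducible and order-independent.  Motif filters
are evaluated on the oligo (antisense) strand, consistent with the ASO
motif penalties.  The "low-complexity / promiscuous" criterion is
operationalised as `cdna_mm0 > max_perfect_offtargets` (default 0: any
perfect hit on another gene rejects).  The diversity pick is greedy
farthest-point selection on start positions (seeded at the smallest
start, ties to the smaller start, output sorted by start), a classic
2-approximation of max-min dispersion — exact optimisation is
combinatorial and the guarantee is good enough for spreading picks along
a transcript.

## Notation

The monomer registry (4 sugars, 6 bases, 2 linkers, in
`data/monomers.tsv`) is closed but data-driven.  The string dialect is
deliberately small: one strand per string, single-letter tokens bare,
multi-character tokens bracketed, the trailing `$$$$` sections empty.
`helm_write`/`helm_parse` are exact inverses on this domain (fuzz-tested);
the sequence and block renderings are lossy text views for human
inspection, with `*` standing in for phosphorothioate marks.

## Synthetic data

The fixtures module generates every input format the pipeline reads:
a multi-exon gene (default 3 exons of 80–160 nt, introns of 60–120 nt,
uniform base composition with an optional GC-bias knob), splice variants
made by dropping one internal exon, orthologs by i.i.d. per-base
substitution (default mouse at 0.08/site, a round value in the range of
mammalian mRNA divergence), 50 random 1-kb decoy genes, 5 SNPs with
reference alleles read off the transcript, and optional off-target
windows planted at exactly 0/1/2 mismatches.  A single seed fans out to
fixed per-component child streams (seed ⊕ CRC32 of a component tag), so
outputs are byte-reproducible and adding a component never perturbs the
others.

What passing tests on this data show: the count laws, the completeness
of the ≤ 2-mismatch search (verified against an exhaustive scan),
exact recovery of planted off-targets, correct funnel accounting, and
end-to-end determinism.  What they do not show: behaviour on realistic
transcriptomes (no codon structure, no repeat families, no biased base
composition, no paralog families with intermediate homology), realistic
SNP spectra, or any claim about experimental silencing efficacy — the
scores are design heuristics, not validated activity predictions.

## Problem sizes and degenerate inputs

Default test and demo sizes (≈ 300–400-nt targets, 50 × 1-kb decoys)
keep the exhaustive-oracle comparisons exact and fast; the engine itself
is linear in database size per query and handles larger databases, just
without genome-scale performance engineering.  Degenerate inputs are
explicit errors: transcripts shorter than k, empty databases, queries
too short for 3-segment seeding, empty sequences for GC content,
ambiguous bases in thermodynamics.  An empty survivor set at the
diversity pick is an empty result, not an error.
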