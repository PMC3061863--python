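# Methods

`estpipe` re-creates, as library code, the computational stages of a
Sanger-era EST survey of the desert locust (*Schistocerca gregaria*) central
nervous system: read cleanup, contig assembly, GO annotation transfer,
library-tag screening for phase-differential transcripts, neuropeptide
precursor mining, and qRT-PCR relative quantification. This note records the
models, the parameters that matter, and the design choices made where the
original tooling (Qualtrim, Cross_Match, RepeatMasker, Phrap, Blast2GO,
SignalP, GeNorm) is proprietary, unpublished in detail, or out of scope to
reproduce in full.

## Shared alignment engine

All sequence comparisons go through one local-alignment engine
(`estpipe.align`, backed by Biopython's `PairwiseAligner`): DNA uses
match +1 / mismatch −2 / gap open −5 / extend −1; protein uses BLOSUM62 with
gap open −11 / extend −1 (the opening penalty is charged on the first gap
column). E-values for translated searches use the Karlin–Altschul formula
E = K·m·n·e^(−λS) with ungapped BLOSUM62 constants λ = 0.3176, K = 0.134
applied to gapped scores. This is a deliberate approximation — it avoids any
external lookup service — and is used only for ranking and thresholding; a
null calibration test (200 scrambled queries) checks that random sequences
essentially never reach the E ≤ 1e-3 transfer cutoff.

## Synthetic data (`synthio`)

The generator emulates 5′-sequenced, tagged, vector-flanked ESTs:

* **Tag schemes.** Library 1: 4-mer tags (ACGC/ACCG/TCGC/TCCG) after the
  NotI site of the oligo-dT primer, so the tag sits at the insert's 3′ end
  and is visible only on reads that run through the poly(A) tail. Library 2:
  GGG/AAGGG/TTGGG/GAGGG after the SMART template-switch anchor, at the 5′
  end of every insert. Each tag encodes (tissue, rearing phase).
* **Read geometry.** Lengths from a truncated normal (mean 750, sd 150,
  bounds 200–1100 nt), matching the 600–900 nt high-quality mode of the
  original chromatograms. A configurable 5′ truncation (`start_jitter`)
  models partial cDNAs and gives assemblies staggered layouts.
* **Quality and errors.** A flat high-quality plateau (Q40 by default)
  decays linearly to Q10 from position `decay_start`; substitutions are
  drawn per base with probability 10^(−Q/10). A calibration test checks the
  realized substitution rate against the binomial expectation at Q30.
  Indels and chromatogram traces are not modelled: the trimming and
  assembly tests therefore say nothing about indel robustness.
* **Vector and contaminants.** An 80 nt fixed synthetic vector stub (not a
  real cloning vector) flanks inserts; contaminant reads are copied from
  two fixed-seed decoy references standing in for rRNA and host genomic
  DNA. These exercise masking/screening mechanics only — they carry no real
  biological signal.
* **Planted truth.** Precursor transcripts are back-translated with a fixed
  codon table into a random-UTR context; phase-biased transcripts get
  configurable (crowded, isolated) copy numbers. Every read has a ledger
  row (source, tissue, phase, tag, clean interval, error count), and a
  fixed seed reproduces byte-identical output.

## Read cleanup (`readqc`)

The original trimming tool is unpublished; the windowed rule implemented
here is: the reported high-quality interval is the longest interval in
which every 50-base window contains at most `tolerance` (default 2) bases
below Q20 (for intervals under 50 bases the interval itself is the window).
This realizes "mostly ≥ Q20, a few tolerated exceptions" while staying
checkable against an exhaustive-interval oracle, which the suite runs on
random quality tracks. Vector masking is iterated best-hit local alignment
(≥ 90% identity over ≥ 20 bases, both strands) with accepted hits blanked
out; the library-primer anchors are masked by the same mechanism — leaving
them would join unrelated reads through shared primer sequence. Low
complexity uses a DUST-style trinucleotide score (window 64, threshold 2):
homopolymers score ≈ w/2, random sequence ≈ 1. Contaminant screening
requires ≥ 95% identity over ≥ 100 bases to a contaminant reference. A
k-mer prefilter (k = 11 vector, k = 11/14 internal) skips alignments
against references sharing no seed with the read. Dispositions follow the
classical vocabulary: `low_quality` (no qualifying window interval ≥ 200
bases), `short_insert` (< 200 unmasked bases), `contaminant`, else `clean`.
All intervals are 1-based inclusive.

Small (3–5 nt) tag remnants next to a masked anchor are below the masking
length floor and can survive into the clean region; at contig ends they are
the main source of the residual ≲0.5% consensus error seen in the tests.

## Assembly (`assemble`)

Overlaps: 16-mer seeded candidate pairs (homopolymer-like seeds skipped to
defuse poly(A)), extended by local alignment on both strands; accepted at
≥ 40 aligned columns and ≥ 95% identity — these defaults are package
choices, exposed as parameters, since the original assembler's settings
were not published. Layout is greedy best-overlap-first (identity, then
length); an edge contradicting an existing placement by more than 5 bases
is dropped, so chimeric joins fall apart into separate contigs rather than
silently misassembling. Consensus is per-column majority weighted by count,
then summed Phred quality, then alphabetical base — fully deterministic.
Contig ids are `C{n}` in order of the smallest member read id. The summary
applies the published accounting: uniques = contigs + singletons,
redundancy % = 100·(reads − uniques)/reads.

## GO transfer (`annotate`)

The annotation score keeps the described ingredients with concrete,
configurable weights: direct score = max over hits of (%identity × evidence
weight), with experimental/curated codes at 1.0, other computational codes
at 0.8, IEA at 0.7; ancestors inherit 0.5 × their best child's score
(decaying with distance); +5 per extra supporting hit, capped at 100. Terms
scoring > 45 are kept and pruned to the lowest node per namespace. The
ontology wrapper honours `is_a` only; "level" is the minimum is_a path
length from the namespace root, and level distributions count a sequence
once per qualifying ancestor. These weights cannot be expected to reproduce
the original study's absolute annotation counts (those depended on external
databases); the tests instead pin the formula's fixed points, monotonicity
in identity, the lowest-node invariant, and agreement of the level counts
with a path-enumeration oracle on synthetic ontologies.

## Phase screen (`phasescreen`)

Tag parsing locates a scheme anchor (≤ 1 substitution, gap-free scan — the
anchors are short and the 5′ read region is high quality) on either strand
and then requires an exact tag match, longer tags first; reads with no or
multiple tag matches are unassigned, mirroring that only tag-visible reads
count. The screen selects a contig when tagged members ≥ 5 (total across
both phases; both readings of the rule agree on every published row) and
one phase outnumbers the other at least 5:1, inclusive, with a zero
denominator always passing (9:0 selects). Tissue tags are parsed but not
used by the screen. No statistical test is attached — the screen is a
pre-selection whose candidates the qPCR stage is meant to confirm.

## Peptide mining (`peptidemine`)

* **Signal heuristic.** A stand-in for a dedicated predictor: within the
  first 35 residues, an 8-residue window of mean Kyte–Doolittle hydropathy
  ≥ 1.6, then cleavage after the first position ≥ 10 whose −1 and −3
  residues are small (A/G/S/C/T). Synthetic fixtures are built to satisfy
  it; calls on real sequences should be treated as low-confidence.
* **Sites.** Dibasic {KR, RR, KK, RK} (KK/RK included because published
  alternative-form footnotes treat them as cleavable), monobasic R, furin
  R-X-[RK]-R; at one position furin ≻ dibasic ≻ monobasic.
* **Primary release.** Cuts after dibasic/furin sites only (monobasic R
  contributes only to alternative forms, keeping full-length peptides with
  internal arginines intact). Overlapping motifs are resolved by motif
  preference (furin, then KR > RR > KK > RK, rightmost on ties): in a K-K-R
  run the terminal Lys-Arg is the recognized pair. Each fragment then loses
  exactly the basic residues of its own cleavage motif. This motif-scoped
  trim — rather than stripping every trailing K/R — is what preserves a
  genuine peptide-terminal lysine (the PVKDP case, …AGTK before a KR site)
  while still clearing the site itself; fragments at a siteless precursor
  end get full trailing-basic trimming instead. A fragment then ending in
  Gly loses it and is flagged amidated.
* **Alternative forms.** Tissue-dependent variants are enumerated by
  cutting after every internal basic residue (K or R, regardless of motif
  class — required by the published form sets), emitting every delimited
  stretch; stretches ending inside the fragment get full trailing-basic
  trimming, and only stretches reaching the fragment end can be amidated.
* **Families.** PVK: Leu at n−7 and Arg at n−2 counted on the Gly-extended
  peptide (the published examples fix this indexing, which the original
  description leaves undefined) plus amidation; myotropin −FXPRLamide;
  tachykinin −FXGXRamide (G↔T tolerance off by default); AKH-like:
  amidated, 8–10 residues, N-terminal Gln reported as a pyroGlu candidate
  (the modification itself is not modelled). No monobasic context rule
  (e.g. proline exclusion) is applied.

## qRT-PCR (`qpcr`)

RQ = E^(Cq_cal − Cq_s) per gene with technical replicates averaged on the
Cq scale; efficiency defaults to 2 when absent. Normalized quantity divides
by the geometric mean of the reference genes' RQ per sample, which cancels
any sample-wide loading offset (a tested invariance). Stability is the
geNorm M-value, M(g) = mean over other candidates of the SD across samples
of log2(RQ_g/RQ_h), ranked ascending. Group comparisons use the
pooled-variance Student's t-test at α = 0.05 by default, Welch behind a
flag; multiple-testing correction (Benjamini–Hochberg) is available but
off by default, matching the original per-gene testing convention. A
simulation checks the null rejection rate is 5% ± 1.5% over 1,000 draws.

## Problem sizes in the test suite

The suite exercises every stage at desk scale: the quality-trim oracle runs
on 200 random tracks of 40–220 bases; assembler recovery uses 140
transcripts / 800 reads at a flat 1% substitution rate with ≥ 90% of
transcripts at ≥ 3× read sampling required back as single unmixed contigs;
ontology checks use 200-term random DAGs; the t-test calibration uses 1,000
null replicates at n = 4 vs 4; the end-to-end phase screen plants 9:0 and
0:9 biased transcripts in a 110-read study. Database-scale results of the
original study (tens of thousands of reads, external protein databases)
are inputs the package accepts but are not reproduced in tests.

## Known limitations

* No indel error model, so no indel-aware trimming/assembly guarantees.
* The E-value model uses ungapped constants on gapped scores.
* The signal-peptide heuristic is far weaker than a trained predictor.
* The annotation score reproduces the described mechanism, not the original
  tool's exact numbers.
* Greedy layout can split a true contig when coverage is discontinuous;
  membership conservation, not maximal contiguity, is the invariant.
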