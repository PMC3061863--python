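# estpipe

An EST-processing toolkit modelled on the classical Sanger-era transcriptome
survey of the desert locust (*Schistocerca gregaria*) central nervous
system. The desert locust switches between a solitarious (isolated-reared)
and a gregarious (crowded-reared) phase — two dramatically different
phenotypes from one genome — and expressed sequence tags (ESTs) from CNS
cDNA libraries were the first genome-free window into the transcripts
behind that plasticity. `estpipe` implements the full computational chain
of such a study as tested, reusable library code, for bioinformaticians who
want to rerun, audit or teach this style of analysis:

* **`synthio`** — a synthetic study generator: transcripts (optionally
  carrying planted neuropeptide-precursor reading frames and phase-biased
  copy numbers), 5′-tagged vector-flanked reads with Phred-style quality
  decay and quality-dependent substitution errors, contaminant decoys, Cq
  tables — all with a ground-truth ledger and byte-reproducible seeding.
* **`readqc`** — quality-window trimming (every 50-base window of the kept
  interval has at most 2 bases under Q20), vector/primer masking,
  DUST-style low-complexity masking, contaminant exclusion; reads are
  dispositioned `clean` / `short_insert` / `low_quality` / `contaminant`.
* **`assemble`** — greedy overlap assembly (16-mer seeded local alignments,
  ≥40 bases at ≥95% identity) into contigs with a quality-weighted majority
  consensus, plus the uniques/redundancy accounting
  `redundancy% = 100·(reads − uniques)/reads`.
* **`annotate`** — GO annotation transfer by six-frame translated
  Smith-Waterman search against a GO-labelled reference protein set, a
  Blast2GO-style annotation score (identity × evidence weight, parent decay
  0.5, +5 per extra hit, threshold >45), lowest-node pruning, and GO-level
  distributions.
* **`phasescreen`** — parsing of the library tags embedded in the cDNA
  synthesis primers (tissue × rearing phase), per-contig tag tallies, and
  the selection rule for candidate phase-differential transcripts: ≥5
  tagged ESTs and a crowded:isolated ratio of at least five to one.
* **`peptidemine`** — neuropeptide precursor mining: translated scans with
  known short peptides, a signal-peptide heuristic, prohormone-convertase
  cleavage (dibasic Lys-Arg/Arg-Arg/…, monobasic Arg, furin R-X-[RK]-R),
  carboxypeptidase trimming and C-terminal amidation (exposed Gly),
  alternative cleavage-form enumeration, and family classification by
  C-terminal motifs (periviscerokinin positional rule, −FXPRLamide
  myotropins, −FXGXRamide tachykinins, AKH-like).
* **`qpcr`** — calibrator-relative quantities `RQ = E^(Cq_cal − Cq_s)`,
  normalization by the geometric mean of reference genes, geNorm M-value
  stability ranking, and pooled-variance Student's t-tests.

`docs/methods.md` describes the models, defaults and design decisions in
detail.

## Worked example

A miniature study end to end, via the `estpipe` CLI:

```bash
$ estpipe simulate --seed 7 --n-transcripts 8 --n-reads 80 --out-prefix demo
wrote 80 reads from 8 transcripts
$ estpipe qc demo.reads.fastq --out-prefix demo
80/80 reads clean
$ estpipe assemble demo.clean.fasta --out-prefix demo
80 reads -> 8 contigs + 0 singletons = 8 uniques (redundancy 90.00%)
```

All 80 error-free reads survive cleanup, and the assembler collapses them
onto their 8 source transcripts: 8 uniques from 80 reads means 90% of the
sequencing was redundant re-reads of already-seen transcripts — exactly
what the redundancy statistic measures.

Screening a pre-tallied per-contig tag-count table (here the published
16-row table that ships with the package):

```bash
$ estpipe screen counts.tsv
16 selected (9 crowded-, 7 isolated-enriched)
```

Each selected contig has at least five tagged ESTs with one rearing phase
outnumbering the other at least five to one — candidates for qRT-PCR
confirmation, not statistical calls in themselves.

The same steps are available as library calls (`synthio.simulate_study`,
`readqc.dispose_batch`, `assemble.assemble_reads`, `phasescreen.screen`,
`peptidemine.analyze_precursor`, `qpcr.relative_quantity`, …); the test
suite is the most complete usage reference.

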