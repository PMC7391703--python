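# rbpscore

Annotation and prioritization of single-nucleotide variants in the
post-transcriptional regulome of RNA-binding proteins (RBPs).

Most variant-impact scores are built around transcriptional regulation —
promoters, enhancers, TF motifs. Variants that act *after* transcription, by
changing where RBPs bind their target transcripts, are largely invisible to
them. `rbpscore` is for researchers who have a set of germline or somatic
SNVs and want to ask: *which of these fall in RBP binding sites, and how much
regulatory evidence do they disturb?*

## The scoring model

A frozen **data context** is built once from RBP binding peaks (eCLIP-style
narrowPeak), a gene model, a population variant panel with derived allele
frequencies (DAF), per-base cross-species constraint values, conserved
RNA-structure intervals, binding motifs (PWMs) and knockdown fold-change
tables. Scoring a variant against the context sums six nonnegative
components:

```
universal = S_popcons + S_hub + S_gerp + S_structure + S_kd + S_motif
```

- **Cross-population conservation** `S_popcons = ρ_adj × S_f` per RBP and
  coding/noncoding partition, maximized over the RBPs binding the variant.
  `ρ_adj = ρ / ρ_b^g` is the footprint's rare-variant fraction
  (DAF ≤ 0.005) over the GC-matched genomic background (500-bp bins grouped
  by integer GC percent); values above 1 indicate purifying selection.
  `S_f = 1 + f·log₂f + (1−f)·log₂(1−f)` is the Shannon-entropy weight of the
  footprint's panel coverage `f`, up-weighting rare annotations.
- **Binding hubs** `S_hub`: positions bound by `H` distinct RBPs are scored
  per H-stratum with the same `ρ_adj × S_H` form; strata below the hot
  threshold (top 5% of regulome bases) score 0, the hot range is
  kernel-smoothed, and ultra-hot strata (top 1%) take a constant plateau.
- **Cross-species constraint** `S_gerp`: a logistic squashing of the
  per-base constraint value, centred at 2 and sharp there
  (`k = ln 19`, so 1 → 0.05 and 3 → 0.95).
- **RNA structure** `S_structure`: 1 inside a conserved-structure interval.
- **Motif disruption** `S_motif`: exact PWM match p-values for the reference
  and alternate windows give `D = −10·log₁₀(p_ref/p_alt)`; a disruption
  needs a significant reference match (`p_ref ≤ 5×10⁻⁴`) and `D > 3`, and is
  then weighted by its rarity among panel variants (entropy of
  `f(v, D)`) times `S_popcons`.
- **Knockdown association** `S_kd`: +1 when the variant disrupts the motif
  of an RBP whose depletion changes the host gene's expression ≥ 2.5-fold.

An optional **tissue-specific score** (0–3) adds one point per active
evidence category: the variant's RBP is a key regulator (significant slope
when regressing genes' differential-expression status on the RBP's binary
target-connectivity vector), a containing peak carries excess somatic
mutations (one-sided binomial test against its local 1-Mbp rate,
BH-corrected), or a linked gene is in the key-gene set (user prior list or
differentially expressed genes). `total = universal + tissue`.

## Worked example

`examples/01_worked_example.py` scores a 10-kb hand-checkable context in
which every component can be derived on paper:

```
chr1:1121 T>G  (v1)
  s_popcons    0.131899   (hand: 0.131899)
  s_hub        0.231727   (hand: 0.231727)
  s_gerp       0.950000   (hand: 0.950000)
  s_structure  1.000000   (hand: 1.000000)
  s_kd         1.000000   (hand: 1.000000)
  s_motif      0.131899   (hand: 0.131899)
  universal    3.445525   (hand: 3.445525)

with tissue inputs: tissue=+3 (burden,key_gene,key_rbp), total=6.445525
```

The variant sits in two overlapping peaks (noncoding partition, hub count
H = 2), under a constraint value of 3 and inside a conserved-structure
interval, and destroys a planted 6-mer motif whose consensus is the unique
top-scoring word (`p_ref = 4⁻⁶`). With tissue inputs, all three categories
fire and add exactly +3. A variant outside every peak scores 0 and is
flagged `outside_regulome`.

## Command line

```bash
rbpscore simulate      --seed 7 --out fixtures/          # synthetic world
rbpscore build-context --genome genome.fa --peaks A_K562_rep1.narrowPeak \
    --annotation genes.gtf --panel panel.vcf --conservation gerp.bedgraph \
    --structure structure.bed --motifs motifs.meme --knockdown kd.tsv \
    --blacklist blacklist.bed --out ctx/
rbpscore score  --context ctx/ --variants my.vcf --out scores.tsv
rbpscore tissue --context ctx/ --variants my.vcf --de de.tsv \
    --somatic somatic.vcf --genes priors.tsv --out scores.tsv
```

The context directory is plain TSV/BED/FASTA plus a JSON manifest with
parameters and SHA-256 checksums; scoring runs are bit-reproducible.

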