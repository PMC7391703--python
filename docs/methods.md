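# Methods

## Scope and coordinate conventions

The package scores single-nucleotide substitutions only; indels and
multi-allelic records are dropped on read with a warning, since every
component is defined per substituted base. Internally all coordinates are
0-based half-open; VCF positions are converted on input and output. Peaks
carry strand, but hub counting and regulome membership ignore it (binding
density is a positional property), while motif scanning respects the
strand of the containing peak and scans both strands when a position is
covered by peaks of both orientations.

## Regulome construction

Peak files are filtered by the ENCODE convention `score == 1000`
(configurable to `>=` for other callers), peaks overlapping the blacklist
are removed whole, and replicate files — and by default different cell
lines — of one RBP are unioned and merged per strand, with the merged peak
keeping the maximum constituent score. The regulome is partitioned at the
projected CDS footprint of the gene model: a base is *coding* iff any
transcript's CDS covers it. The partition is exact: per RBP,
|coding| + |noncoding| equals the footprint length in bases, which the
tests assert.

## Cross-population conservation

For an RBP's partitioned footprint with `n_in` panel variants out of a
panel of fixed size `n_total`, the coverage fraction `f = n_in/n_total`
receives the entropy weight `S_f = 1 + f log2 f + (1-f) log2 (1-f)`
(0·log 0 = 0). `S_f` is 1 for vanishingly small or near-total coverage and
0 at f = 0.5; it encodes how surprising it is for a random panel variant
to fall (or not fall) in the annotation.

Selection pressure is the rare-variant fraction `rho = n_r/(n_r+n_c)`
(rare: DAF ≤ 0.005) divided by a GC-matched background `rho_b`: the genome
is tiled into 500-bp bins, bins are grouped by integer-rounded GC percent,
and each group's `rho_b` is estimated from the panel variants in its bins.
Groups with fewer than 50 bins are merged into their nearest GC neighbour
(iteratively, smallest group first; all ties break toward lower GC), and
lookups resolve to the usable group with the closest GC. Footprints
without panel variants score 0 with a warning rather than erroring, so
small contexts stay scoreable. The per-variant score is the maximum
`rho_adj × S_f` over the binding RBPs, using each RBP's partition at the
queried position.

## Binding hubs

`H` is the number of distinct RBPs covering a base (replicates and strands
count once). Hot and ultra-hot thresholds are the smallest H whose
upper-tail base fraction is ≤ 5% and ≤ 1%, computed base-weighted and
separately per partition, because the enrichment strata are per-partition.
Each stratum is scored `rho_adj|H × S_H`; strata below `H_hot` are zeroed,
the hot range is smoothed with a Nadaraya–Watson regression using a
Gaussian kernel of bandwidth 1.0 on the integer H axis (no kernel is
canonical here; this choice is deterministic and configurable), and strata
at or above `H_ultra` take a constant plateau equal to the maximum
smoothed hot value. The zero/smooth/plateau treatment is applied to the
*product* `rho_adj × S_H` rather than to `rho_adj` alone so the plateau is
genuinely constant — applying it to `rho_adj` and then multiplying by a
varying `S_H` could not keep the ultra-hot component flat. On degenerate
tracks where the thresholds coincide (tiny contexts), the table reduces to
a plateau at the maximum raw value of the qualifying strata, with a
warning.

## Cross-species constraint and structure

Per-base constraint values are squashed by the logistic
`1/(1+exp(-k(x-m)))` with midpoint `m = 2` — the conventional constraint
cutoff — and steepness `k = ln 19 ≈ 2.944`, chosen so that m±1 map to 0.05
and 0.95, keeping the curve sharp at the cutoff; both parameters are
configurable. Positions without a value score 0 and set a per-variant
`gerp_missing` flag. Conserved-structure membership is a plain 0/1
indicator with half-open boundaries.

## Motif disruption

Match significance uses the classic exact approach: per-column log2
likelihood-ratio scores against the background composition are rounded to
a common grid of 1/1000 of the total score range, the null score
distribution of one window is built by convolving the four-spike column
distributions, and the p-value of an observed (grid) score is the suffix
sum. Because observed scores live on the same grid, the DP tail equals
full 4^L enumeration exactly, which the tests verify for L ≤ 6 under
uniform and skewed backgrounds. PWMs get a pseudocount of 0.001 per cell
before renormalization; matrices shorter than 3 are rejected.

The disruption score is `D = -10 log10(p_ref/p_alt)` where `p_ref`,
`p_alt` are best-match p-values in a window extending motif-length − 1
bases each side of the variant. Reading the two quantities as match
*p-values* (not match probabilities) is what makes a motif-breaking
variant score positive and makes the `D > 3` significance threshold
coherent. A disruption is only called when the reference allele itself is
a significant match, `p_ref ≤ 5e-4`; the gate direction is configurable
because the opposite reading would only ever call breaks in non-matches.
Per variant the maximum D over the binding RBPs' PWMs is taken after the
gate; the component is the entropy weight of `f(v, D)` — the fraction of
regulome panel variants whose own maximal gated D exceeds it, with
gate-failing variants recorded as −inf — multiplied by the variant's
population-conservation score, so motif evidence never stands without
population support.

## Knockdown association and tissue scoring

Peaks link to genes by overlap with full transcript spans (exons and
introns, since binding is frequently intronic). The knockdown component is
1 when the variant lies in a linked peak of an RBP with gated `D > 3`
whose depletion changes the linked gene's expression at least 2.5-fold *in
either direction* (knockdown can silence or de-repress; a one-sided mode
exists).

The tissue score adds one point per active category, not per hit:

1. **Key regulator** — OLS of the binary DE status vector on the RBP's
   binary connectivity vector; for binary covariates the slope is exactly
   the DE-rate difference between targets and non-targets (asserted in
   tests). Significance is nominal p < 0.05 per (RBP, condition), with BH
   across RBPs available by config. Strata with fewer than two genes make
   the fit undefined and exclude the RBP with a warning. Only the
   cohort-level regression is implemented; a patient-level variant of the
   model would be an extension.
2. **Somatic burden** — each peak's mutation count k against its 1-Mbp
   window (tiled from coordinate 0, peak assigned by midpoint) with the
   one-sided binomial tail `P(X ≥ k)`, `p0` = peak length / window length,
   BH across all tested peaks, burdened iff q < 0.05. Peak bases are not
   excluded from the window background; including them is conservative.
   Windows without mutations give p = 1.
3. **Key gene** — union of the user's prior list and DE genes (q < 0.05),
   tested on genes linked to any containing peak.

## Scoring scope and determinism

Variants outside every peak score zero on all components and are flagged;
the framework prioritizes within the regulome. A config switch enables
genome-wide constraint/structure components for baseline-style scoring.
Components sum unweighted and uncapped (per-component weights are exposed
only through the configuration of each component's own parameters). Ranking
breaks ties by universal score, then genomic coordinate, so outputs are
reproducible byte-for-byte; the serialized context carries a manifest with
parameters and SHA-256 checksums and is verified on load.

## Synthetic worlds and what they show

The fixture generator emits a complete input set (FASTA, narrowPeak with
sub-threshold decoys, panel VCF, bedGraph, BEDs, MEME motifs, TSVs) plus a
ground-truth JSON, deterministically per seed. Defaults: a 200-kb
single-chromosome genome with blockwise GC from 0.30–0.60 (so several GC
groups exist), 8 RBPs × 25 peaks of 100–160 bp with half the peaks drawn
to 5 shared hotspots (creating high-H strata), a 10,000-variant panel with
background rare fraction 0.30 boosted ×1.15 inside the first RBP's peaks,
one planted consensus site in half the peaks, knockdown response in 30% of
(RBP, gene) pairs, DE probabilities 0.40 (targets of three key RBPs) vs
0.10, and somatic mutations at 5×10⁻⁵/bp with a 10× excess in 20
designated peaks. Rare/common status is drawn directly per variant — the
scoring maths consumes only that dichotomy, so no population-genetic
simulator is needed.

Two statistical samplers reproduce single estimators at scale: the
enrichment calibration uses a GC-homogeneous 200-kb genome (the stated
null is a panel *matched in GC* to the background, under which the
estimator concentrates within ±0.05 of 1 at 10,000 variants; GC-group
handling itself is covered by deterministic unit tests), and the burden
sampler draws peaks and Poisson mutation counts for null and planted
runs. What passing these tests does **not** show: real eCLIP peak-size
and clustering distributions, linkage between panel variants, ascertainment
or coverage artifacts in real frequency panels, or realistic somatic
mutational signatures — the fixtures validate the estimators' arithmetic
and calibration, not the biology of any particular dataset.

Test and acceptance problem sizes (200 replicates at 10,000 panel
variants, 80-kb round-trip worlds, 300-variant scoring batches) were
chosen as the smallest sizes at which the statistical properties are
sharp; all run in seconds.

## Known limitations

- The GC adjustment matches a region by its *mean* GC; strongly bimodal
  footprints are matched to a single background group.
- The hub-score invariant "removing an RBP never increases a score" holds
  for the count structure and empirically in tests, but re-estimated
  hot/ultra-hot quantiles can in principle shift thresholds on adversarial
  inputs.
- The disruption background CDF is built from the panel restricted to the
  regulome; panels that barely intersect the regulome give a coarse CDF.
- PWM p-values assume an i.i.d. background; dinucleotide composition is
  not modelled.
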