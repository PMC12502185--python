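# Methods

## The detection model

A UV sex locus is hemizygous: the male assembly's V-SDR haplotype has no
counterpart in the female genome beyond its diverged U homologue, and
vice versa. `uvscan` treats detection as a per-window voting problem on
the focal (same-sex) assembly. Windows are 0-based half-open, 1 kb by
default; a k-mer belongs to the window containing its start position,
so k-mers straddling a boundary count in the left window. k-mers are
canonical (lexicographic minimum of the k-mer and its reverse
complement) with k = 15 by default; windows report statistics as
missing — never zero — when they contain no valid k-mer.

The four detectors and their defaults:

- **Coverage.** Per-window mean depths for the same- and opposite-sex
  read sets. A unit passes when same-sex depth lies within ±25%
  (inclusive) of the same-sex genome-wide median AND opposite-sex depth
  is strictly below 80% of the opposite-sex track's own genome-wide
  median. Using the opposite track's own median is the only
  self-consistent choice when the two libraries differ in depth; a
  switch selects the same-sex median instead. Contig-level calls use
  the median of window depths (robust to repeat spikes).
- **AWK** (sex-specific k-mers per kb). A k-mer is sex-specific when its
  same-sex read count is ≥ 2 (noise floor: error k-mers are mostly
  singletons) and its opposite-sex read count is exactly 0.
- **KQ.** Over window k-mers present in *both* read sets,
  (Σ same counts / same total) ÷ (Σ opposite counts / opposite total).
  Aggregating as a ratio of depth-normalised sums avoids the
  division-by-small-count instability of per-k-mer ratio means (which
  remain available as an option). Note that on a hemizygous SDR the
  k-mers shared by both read sets are precisely the conserved ones, so
  KQ sits near 1 there and the KQ vote rarely fires; the consensus rule
  is designed to tolerate exactly this.
- **YGS%.** Percentage of the window's distinct k-mers absent from the
  opposite-sex assembly (optionally the opposite-sex read set).

Window flag cutoffs (AWK ≥ 20/kb, KQ ≥ 2, YGS ≥ 30%) were calibrated on
the bundled simulator and are plain parameters; the coverage thresholds
(25% band, 80% cut) are the field-standard rule and are likewise
configurable. A unit is retained when at least 3 of the 4 methods vote
for it; a method undefined on a unit counts as a false vote. Retained
windows are merged bridging gaps of ≤ 5 windows; merged runs shorter
than 3 windows are dropped. On a scaffold with a surviving SDR interval
the flanks become PAR; scaffolds without one are autosome end to end.
Raising the consensus threshold can only shrink the called SDR.

Read mapping is deliberately out of scope. Depth tracks are either
loaded from bedGraph/TSV produced by any aligner, or estimated
alignment-free from the read k-mer table: a genomic k-mer's expected
read multiplicity at depth D is D·(L−k+1)/L for read length L, so the
per-window mean k-mer count rescaled by L/(L−k+1) estimates depth.
Multi-copy sequence inflates this estimate exactly as multi-mapping
inflates an aligner's raw depth, which is the behaviour the coverage
rule is built to exploit.

In-silico PCR uses exact string matching of the forward primer and the
reverse complement of the reverse primer, on both strands, within the
stated product-size range; no mismatch model or melting-temperature
recomputation. A marker is sex-specific when amplicons exist in exactly
one of the two assemblies; multiple amplicons in one genome set an
ambiguity flag.

## Divergence estimation

Gametologs are paired by reciprocal best local alignment
(Smith–Waterman–Gotoh, BLOSUM62, gap open −11 / extend −1, raw-score
threshold 50 in place of an E-value; equal best scores break
conservatively to "no pair"). Codon alignments are threaded through the
protein alignment; columns containing a gap or ambiguous base are
removed, a light-weight stand-in for the usual MAFFT + Gblocks codon
pipeline.

Ks/Kn use Nei–Gojobori (1986) counting: per-codon synonymous site
fractions (changes to stop codons count as non-synonymous, so S + N is
exactly 3 per codon), site counts averaged over the two sequences,
multiple-difference codons averaged over all single-step pathway
orderings with stop-passing pathways excluded, and Jukes–Cantor
correction K = −(3/4)·ln(1 − 4p/3). pS ≥ 3/4 is reported as a
saturation flag with Ks missing, reproducing the qualitative
"Ks saturated" behaviour of old gametologs; ω = Kn/Ks is undefined at
Ks = 0 or saturation. Counting NG86 is a transparent, dependency-free
estimator; it does not model transition/transversion bias or codon
frequencies the way ML (codeml-style) estimators do, and will sit
slightly below ML values at high divergence.

The strata scan orders pairs by V-scaffold position (saturated pairs
ranked oldest, plotted at Ks = 3 for segmentation only) and applies
binary segmentation on the mean with a minimum segment of 3 pairs and a
BIC-style penalty (variance × log n per breakpoint). Segmentation of a
handful of noisy Ks values is exploratory; the penalty constant is an
artifact choice, not an inference procedure.

## Composition statistics

Densities are base-fraction percentages over a region; features
straddling a boundary contribute their overlapping bases to each side,
repeat intervals are merged first, GC ignores ambiguous bases, and a
gene is counted in the region holding its midpoint. Permutation tests
relabel the pooled observations (fixed-length windows for density/GC,
genes for gene-level metrics — the resampling unit is a package choice),
use the mean difference as statistic and report
p = (1 + #{|T*| ≥ |T|})/(B+1) with B = 10 000 by default, so the
smallest attainable p is 1/(B+1).

ENC uses Wright's framework with family homozygosity F = Σp̂² (no
small-sample correction): ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆,
averaged within degeneracy classes, families with fewer than 2 codons
excluded from their class mean, a missing 3-fold class interpolated as
(F̄₂+F̄₄)/2, and the result capped at 61. The uncorrected F makes the
boundary cases exact at finite length — uniform usage gives exactly 61
and single-codon usage exactly 20 — at the cost of a small upward bias
for very short genes, which are flagged as unreliable below 100 codons.
ENC′ replaces F by (χ²/n + 1)/m, where χ² measures deviation from
codon usage expected under a background nucleotide composition
(renormalised within each family); with a uniform background ENC′
reduces algebraically to ENC. Gene-age tables (five phylostratum ranks)
are compared across regions by Pearson χ² without continuity
correction, df from the table shape; a 3-region × 5-rank table gives
df = 8.

## Sex-biased expression

The caller is an intentionally simple substitute for a
negative-binomial DE framework, and external DE tables (gene, log2FC,
padj) are accepted verbatim when exact reproduction of published labels
is needed. Per gene it tests male vs female log2(TPM+1): Mann–Whitney
rank-sum with ≥ 4 replicates per sex, Welch's t below that. (The exact
rank null at 2–3 replicates cannot produce p < 0.10, so a rank test
there would silently disable the caller; on log-scale data the t-test
is well calibrated, which the test suite verifies.) p-values are BH
adjusted across genes and a gene is biased only when additionally its
linear mean-TPM ratio is ≥ 2 in that direction. Bias-class comparisons
use pairwise Wilcoxon with Holm step-down; PAR enrichment uses a 2×2
Pearson χ²; the paired t pairs each sex-limited SDR gene with its
single best-scoring autosomal paralog (a species column supports
pooling across species); gametolog expression correlation is Pearson's
r on per-pair mean log2(TPM+1) (per-pair means rather than per-sample
values — the alternative is exposed).

## The synthetic-data generator

`simulate` emits a male/female assembly pair sharing autosomes and PARs
byte-for-byte, with a planted central SDR on the sex scaffold. The
reference scenario (the defaults) is a 1-Mb sex scaffold with a 200-kb
SDR at 5% per-site divergence, five 500-kb autosomes, 20× 100-bp reads
per sex at 0.2% error, three replicate expression libraries per sex and
planted fold changes {2, 4, 8}. Background divergence draws per-site
i.i.d. substitutions, uniform over the three alternatives, matching the
Jukes–Cantor model the Ks estimator inverts. Gametolog partners carry
only synonymous changes, dosed by inverting the JC correction
(pS* = ¾(1 − e^(−4Ks/3))) and applying ⌈pS*·S⌉ single-step synonymous
substitutions to distinct codons, so NG86 recovery of the target is a
genuine parameter-recovery test. Sex-limited genes are insertions
present in one haplotype only; half of them (by default) get a diverged
autosomal paralog planted in both sexes at twice the SDR copy's
expression. Repeats are tandem satellites — 50-bp random monomers × 2–6
copies, 10% of the SDR (5% PAR, 10% autosome) — annotation structure
and mild multi-mapping, not TE biology; heavier, longer arrays would
blank out their windows for every detector exactly as real repeat
arrays do, which is demonstrated nowhere better than by the fact that
detection tolerates bridged gaps of only ≤ 5 windows. Reads are uniform
over positions and strands with constant placeholder qualities; no
indels, inserts or quality model. Expression baselines are log-normal;
biased genes split their log2 fold symmetrically between the sexes;
columns are TPM-normalised to 10⁶, which couples genes through the
closure — negligible at realistic gene counts, visible in toy matrices
with tens of genes (the tests account for it).

All randomness flows from one seed through deterministically spawned
per-stage generators: a fixed seed reproduces every output byte.

What passing on this generator does *not* show: robustness to
alignment artefacts, GC- or mappability-bias, indel/structural
divergence between haplotypes, shared TE families between SDR and
autosomes (which depress AWK/YGS in real data), or library-size and
dispersion structure beyond log-normal noise.

## Problem sizes used by the bundled checks

The test suite exercises a quarter-scale scenario (200-kb sex scaffold,
50-kb SDR, two 100-kb autosomes) with feature counts scaled to keep
density comparable to the reference scenario; the acceptance script
runs the reference scenario itself, the closed-form unmatched-k-mer
check on repeat-free SDRs at divergences {0.01, 0.05, 0.10} (the
closed form 1 − (1−d)^k assumes independent sites, which tandem repeats
violate), Ks recovery on 330-codon gametologs, and permutation
calibration over 1000 null datasets at B = 2000. End-to-end recovery is
sampled at three seeds in the suite; single-seed recovery at the
reference scale is part of the acceptance run.

## Known limitations

- KQ as specified (shared k-mers only) carries little signal on
  strongly hemizygous regions; it is retained for completeness and for
  partially diverged regions.
- NG86 underestimates high divergences relative to ML and ignores
  ts/tv bias.
- The in-silico PCR has no mismatch tolerance: a single SNP under a
  primer abolishes the amplicon, which is conservative for marker
  retention.
- The expression caller is not a replacement for a proper
  negative-binomial framework on real count data; it exists so the
  downstream statistics have a self-contained, calibrated input.
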