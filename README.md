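# uvscan

Detection and characterisation of **UV sex-determining regions (SDRs)**
from male/female haploid genome data.

In organisms with haploid (UV) sex determination — red and brown algae,
bryophytes, some green algae — females carry a U and males a V
chromosome. Neither recombines at the sex locus, and each sex's
gametophyte is hemizygous for its own SDR haplotype. That hemizygosity
leaves a clear footprint in sequencing data: male-assembly SDR windows
attract no female reads and are packed with k-mers the female genome
simply does not contain. `uvscan` implements the standard detection
toolkit built on that footprint, plus the downstream analyses used to
characterise a detected sex locus, and bundles a truth-tracked synthetic
data generator so the whole pipeline can be exercised and validated
without any external data.

## What it computes

**Four detectors over 1-kb windows (or whole contigs), combined by a
≥3-of-4 consensus rule:**

- **Coverage rule** — same-sex read depth within ±25% of the genome-wide
  median *and* opposite-sex depth below 80% of its genome-wide median.
- **AWK** — density per kb of sex-specific k-mers (15-mers present in
  the same-sex reads, absent — "null ratio" — from the opposite-sex
  reads).
- **KQ (k-mer quotient)** — depth-normalised same:opposite frequency
  ratio of the window k-mers shared by both read sets.
- **YGS%** — percentage of distinct window k-mers unmatched in the
  opposite-sex assembly.

Consensus windows are merged into SDR intervals (gap bridging + minimum
run length); the remainder of a sex scaffold is labelled PAR
(pseudoautosomal region) and other scaffolds autosome. Candidate sex
markers are validated by exact-match in-silico PCR against both
assemblies.

**Characterisation of the partition:**

- Region composition (gene density, repeat density, GC) with two-sided
  permutation tests of mean differences, p = (1 + #{|T\*| ≥ |T|})/(B+1).
- Codon-usage bias: ENC and composition-corrected ENC′ (degeneracy-class
  averaged homozygosity F = Σp̂²; bounds 20–61), compared between gene
  sets by Mann–Whitney U.
- Gene-age (phylostratum) composition across regions by Pearson χ².
- Gametologs: reciprocal best Smith–Waterman hits between the sexes'
  proteomes, codon alignments threaded through the protein alignment,
  and synonymous/non-synonymous divergence by Nei–Gojobori (1986)
  counting with Jukes–Cantor correction,
  K = −(3/4)·ln(1 − 4p/3), with explicit saturation flagging
  (pS ≥ 3/4). A Ks-vs-position scan with binary segmentation looks for
  evolutionary strata.
- Sex-biased expression: per-gene male-vs-female tests on log2(TPM+1)
  with Benjamini–Hochberg correction and the usual FC ≥ 2, Padj < 0.05
  gates; gametolog expression correlation (Pearson), paired *t* of
  sex-limited SDR genes vs their autosomal paralogs, pairwise Wilcoxon
  among bias classes with Holm correction, PAR enrichment χ², and
  cross-species orthogroup turnover counts.

## Worked example

Simulate a small UV genome pair and run the full detection pipeline:

```python
from uvscan.simulate import SimParams
from uvscan.pipeline import run_detection, jaccard

params = SimParams(
    seed=1,
    n_autosomes=2, autosome_len=100_000,
    sex_scaffold_len=200_000, sdr_interval=(80_000, 130_000),
    n_gametologs=3, n_sex_limited_male=3, n_sex_limited_female=3,
)
det = run_detection(params)
print(det.partition.sdr_intervals())
truth = det.sim.truth.sdr_interval["male"]
print(round(jaccard(truth[1:], det.partition.sdr_intervals()[0][1:]), 3))
```

prints

```
[('sex_scaffold', 80000, 130000)]
1.0
```

i.e. the consensus caller recovers the planted 50-kb SDR exactly
(Jaccard overlap 1.0 with the truth interval), labels its flanks PAR and
leaves both autosomes untouched. The same steps are exposed on the
command line (`uvscan simulate`, `uvscan kmers`, `uvscan coverage`,
`uvscan callsdr`, `uvscan features`, `uvscan gametologs`,
`uvscan expression`); each command reads and writes plain
FASTA/FASTQ/GFF3/BED/TSV.

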