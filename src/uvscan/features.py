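"""Region-composition statistics and the comparison tests between
SDR, PAR and autosomal sequence.

Covers gene/repeat density and GC per region, two-sided permutation
tests of a difference in means, the effective number of codons (ENC and
its composition-corrected variant ENC'), a rank-sum comparison of codon
bias between gene sets, and a Pearson chi-square test of gene-age
(phylostratum) composition across regions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sdrcall import SdrPartition


# ---------------------------------------------------------------- regions

def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    out: list[list[int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1][1] = max(out[-1][1], end)
        else:
            out.append([start, end])
    return [(a, b) for a, b in out]


def _overlap_bases(intervals: list[tuple[int, int]], lo: int, hi: int) -> int:
    return sum(max(0, min(e, hi) - max(s, lo)) for s, e in intervals)


@dataclass
class RegionStats:
    label: str
    length: int
    gene_density: float | None  # % of bases in gene models
    repeat_density: float | None
    gc: float | None  # % G+C among unambiguous bases
    n_genes: int
    mean_gene_len: float | None


def read_gff_genes(path) -> pd.DataFrame:
    """Gene features from a GFF3 file as a DataFrame
    (gene_id, scaffold, start, end with 0-based half-open coordinates)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("ID", [g.id])[0]
        rows.append((gid, g.seqid, g.start - 1, g.end))
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end"])


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["scaffold", "start", "end"],
    )
    return df


def region_composition(
    assembly,
    genes: pd.DataFrame,
    repeats: pd.DataFrame,
    partition: SdrPartition,
) -> list[RegionStats]:
    """Per-region gene density, repeat density and GC.

    Densities are base-fraction percentages over the region's length;
    features straddling a region boundary contribute their overlapping
    bases to each side. GC ignores ambiguous bases; a region of only N
    reports GC as missing.
    """
    import os
    from . import _seq

    records = dict(
        _seq.read_fasta(assembly)
        if isinstance(assembly, (str, os.PathLike))
        else assembly
    )
    for _, g in genes.iterrows():
        if g.scaffold in records and g.end > len(records[g.scaffold]):
            raise ValueError(f"gene {g.gene_id} outside scaffold {g.scaffold}")

    acc: dict[str, dict] = {}
    for scaf, ivs in partition.scaffolds.items():
        if scaf not in records:
            raise ValueError(f"partition scaffold {scaf} absent from assembly")
        seq = records[scaf]
        gene_ivs = merge_intervals(
            [(int(r.start), int(r.end)) for r in genes[genes.scaffold == scaf].itertuples()]
        )
        rep_ivs = merge_intervals(
            [(int(r.start), int(r.end)) for r in repeats[repeats.scaffold == scaf].itertuples()]
        )
        gene_rows = genes[genes.scaffold == scaf]
        for iv in ivs:
            a = acc.setdefault(
                iv.label,
                {"len": 0, "gene_bp": 0, "rep_bp": 0, "gc": 0, "acgt": 0,
                 "n_genes": 0, "gene_lens": []},
            )
            a["len"] += iv.end - iv.start
            a["gene_bp"] += _overlap_bases(gene_ivs, iv.start, iv.end)
            a["rep_bp"] += _overlap_bases(rep_ivs, iv.start, iv.end)
            sub = seq[iv.start : iv.end].upper()
            a["gc"] += sub.count("G") + sub.count("C")
            a["acgt"] += sum(sub.count(b) for b in "ACGT")
            # a gene is counted in the region holding its midpoint
            for r in gene_rows.itertuples():
                mid = (r.start + r.end) // 2
                if iv.start <= mid < iv.end:
                    a["n_genes"] += 1
                    a["gene_lens"].append(r.end - r.start)

    out = []
    for label, a in acc.items():
        if a["len"] == 0:
            continue
        out.append(
            RegionStats(
                label=label,
                length=a["len"],
                gene_density=100.0 * a["gene_bp"] / a["len"],
                repeat_density=100.0 * a["rep_bp"] / a["len"],
                gc=(100.0 * a["gc"] / a["acgt"]) if a["acgt"] else None,
                n_genes=a["n_genes"],
                mean_gene_len=float(np.mean(a["gene_lens"])) if a["gene_lens"] else None,
            )
        )
    return out


# ----------------------------------------------------------- permutation

@dataclass
class PermResult:
    observed: float
    B: int
    p: float
    seed: int | None = None


def perm_test_mean_diff(
    a: Sequence[float],
    b: Sequence[float],
    B: int = 10000,
    seed: int | None = None,
    chunk: int = 200,
) -> PermResult:
    """Two-sided permutation test of mean(a) - mean(b).

    The null is built by random relabelling of the pooled values;
    p = (1 + #{|T*| >= |T|}) / (B + 1), so the smallest attainable
    p-value is 1/(B+1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    obs = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return PermResult(observed=obs, B=B, p=1.0, seed=seed)
    rng = np.random.default_rng(seed)
    na = len(a)
    n_extreme = 0
    done = 0
    while done < B:
        m = min(chunk, B - done)
        mat = np.tile(pooled, (m, 1))
        mat = rng.permuted(mat, axis=1)
        t = mat[:, :na].mean(axis=1) - mat[:, na:].mean(axis=1)
        n_extreme += int((np.abs(t) >= abs(obs) - 1e-12).sum())
        done += m
    return PermResult(observed=obs, B=B, p=(1 + n_extreme) / (B + 1), seed=seed)


# ------------------------------------------------------------ codon bias

from Bio.Data.CodonTable import standard_dna_table

_STOPS = set(standard_dna_table.stop_codons)
CODON_TO_AA = dict(standard_dna_table.forward_table)

# synonymous families keyed by amino acid, only sense codons
SYN_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in CODON_TO_AA.items():
    SYN_FAMILIES.setdefault(_aa, []).append(_codon)
for _fam in SYN_FAMILIES.values():
    _fam.sort()

# degeneracy class -> number of families (Wright: 9x2, 1x3, 5x4, 3x6)
_DEGEN_CLASSES = (2, 3, 4, 6)


@dataclass
class CodonUsageRecord:
    gene_id: str
    enc: float | None
    enc_prime: float | None
    n_codons: int
    codon_counts: dict[str, int]
    unreliable: bool = False  # < 100 codons


def _family_homozygosity(counts: np.ndarray) -> float | None:
    """F = sum p_hat^2 over a synonymous family; None below 2 codons."""
    n = counts.sum()
    if n < 2:
        return None
    p = counts / n
    return float((p**2).sum())


def _family_chisq_f(counts: np.ndarray, expected: np.ndarray) -> float | None:
    """Composition-corrected homozygosity F' = (chi2/n + 1) / m.

    chi2 measures the deviation of observed codon usage from the
    background-expected usage; under a uniform background F' reduces
    exactly to sum p_hat^2.
    """
    n = counts.sum()
    m = len(counts)
    if n < 2:
        return None
    e = expected / expected.sum()
    chi2 = float((((counts / n - e) ** 2) / e).sum()) * n
    return (chi2 / n + 1.0) / m


def _enc_from_F(fam_F: dict[str, float | None]) -> float | None:
    """Combine per-family homozygosities into ENC, averaging within a
    degeneracy class over families with data and falling back across
    classes when one is empty."""
    by_class: dict[int, list[float]] = {c: [] for c in _DEGEN_CLASSES}
    n_families = {c: 0 for c in _DEGEN_CLASSES}
    for aa, fam in SYN_FAMILIES.items():
        m = len(fam)
        if m == 1:
            continue
        n_families[m] += 1
        F = fam_F.get(aa)
        if F is not None and F > 0:
            by_class[m].append(F)
    mean_F: dict[int, float | None] = {
        c: (float(np.mean(v)) if v else None) for c, v in by_class.items()
    }
    if mean_F[3] is None:  # Ile missing: interpolate from 2- and 4-fold
        if mean_F[2] is not None and mean_F[4] is not None:
            mean_F[3] = (mean_F[2] + mean_F[4]) / 2
    if any(mean_F[c] is None for c in (2, 4, 6)):
        return None
    enc = 2.0
    for c in _DEGEN_CLASSES:
        if mean_F[c] is None:
            return None
        enc += n_families[c] / mean_F[c]
    return min(enc, 61.0)


def enc_prime(cds: str, background="uniform", gene_id: str = "") -> CodonUsageRecord:
    """ENC (Wright) and ENC' (background-corrected) for one CDS.

    ``background`` is "uniform" or nucleotide frequencies as a mapping
    {A,C,G,T} -> probability; the expected usage of each codon in a
    family is the product of its base frequencies, renormalised within
    the family. A terminal stop codon is allowed and dropped; internal
    stops are an error.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError("CDS length not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    counts: dict[str, int] = {}
    for i, c in enumerate(codons):
        if c in _STOPS:
            raise ValueError(f"internal stop codon at codon {i}")
        if set(c) - set("ACGT"):
            continue  # ambiguous codon skipped
        counts[c] = counts.get(c, 0) + 1

    if background == "uniform":
        freqs = {b: 0.25 for b in "ACGT"}
    else:
        tot = sum(background[b] for b in "ACGT")
        freqs = {b: background[b] / tot for b in "ACGT"}

    fam_F: dict[str, float | None] = {}
    fam_Fp: dict[str, float | None] = {}
    for aa, fam in SYN_FAMILIES.items():
        if len(fam) == 1:
            continue
        obs = np.array([counts.get(c, 0) for c in fam], dtype=float)
        expected = np.array(
            [freqs[c[0]] * freqs[c[1]] * freqs[c[2]] for c in fam]
        )
        fam_F[aa] = _family_homozygosity(obs)
        fam_Fp[aa] = _family_chisq_f(obs, expected)

    n_codons = sum(counts.values())
    return CodonUsageRecord(
        gene_id=gene_id,
        enc=_enc_from_F(fam_F),
        enc_prime=_enc_from_F(fam_Fp),
        n_codons=n_codons,
        codon_counts=counts,
        unreliable=n_codons < 100,
    )


def compare_codon_bias(
    sdr_records: Sequence[CodonUsageRecord],
    autosomal_records: Sequence[CodonUsageRecord],
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on ENC' between two gene sets.

    Exact null when both groups have <= 8 genes and no ties; tie-corrected
    normal approximation otherwise. Returns (U, p).
    """
    x = np.array([r.enc_prime for r in sdr_records if r.enc_prime is not None])
    y = np.array([r.enc_prime for r in autosomal_records if r.enc_prime is not None])
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need >= 3 genes with defined ENC' per group")
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(len(x) * len(y) / 2), 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# -------------------------------------------------------------- gene age

def age_chisq(ages: pd.DataFrame, regions: Sequence[str] | None = None) -> tuple[float, int, float]:
    """Pearson chi-square of phylostratum composition across regions.

    ``ages`` has columns gene_id, rank (1..5), region. Returns
    (chi2, df, p) with df from the table shape, no continuity correction.
    """
    df = ages if regions is None else ages[ages.region.isin(list(regions))]
    if not df["rank"].between(1, 5).all():
        raise ValueError("phylostratum ranks must be in 1..5")
    table = pd.crosstab(df.region, df["rank"]).reindex(columns=range(1, 6), fill_value=0)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("empty margin in contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(table.values, correction=False)
    return float(chi2), int(dof), float(p)


def chisq_2x2(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction on any r x c table."""
    chi2, p, dof, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), int(dof), float(p)
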