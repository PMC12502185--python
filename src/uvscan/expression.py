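"""Sex-biased expression calling and downstream statistics.

The caller is a deliberately simple substitute for a negative-binomial
DE framework: per gene it tests male vs female log2(TPM+1) and applies
the standard cut-offs (fold change >= 2 on the linear mean-TPM scale and
Benjamini-Hochberg adjusted p < 0.05). Externally computed DE tables
(gene, log2FC, padj) are accepted to reproduce published labels exactly.

Downstream statistics: Pearson correlation of gametolog expression
between sexes, a paired t-test of sex-limited SDR genes against their
autosomal paralogs, pairwise Wilcoxon comparisons among bias classes
with Holm correction, chi-square enrichment of biased genes in the PAR,
and cross-species orthogroup turnover (Venn cell) counts.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionMatrix:
    """genes x samples expression with sample sex labels."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    sex: dict[str, str]  # sample -> "male" | "female"
    species: str = ""
    is_tpm: bool = True

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.sex)
        if missing:
            raise ValueError(f"samples without a sex label: {sorted(missing)}")
        if (self.values.values < 0).any():
            raise ValueError("negative expression values")
        if self.is_tpm:
            sums = self.values.sum(axis=0)
            bad = sums[(sums - 1e6).abs() > 1e-3 * 1e6]
            if len(bad):
                raise ValueError(f"TPM columns do not sum to 1e6: {list(bad.index)}")

    def samples_of(self, sex: str) -> list[str]:
        return [s for s in self.values.columns if self.sex[s] == sex]

    @classmethod
    def from_tsv(cls, tpm_path, samples_path, species: str = "", is_tpm: bool = True):
        values = pd.read_csv(tpm_path, sep="\t", index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t")
        sex = dict(zip(sheet["sample"], sheet["sex"]))
        return cls(values=values, sex=sex, species=species, is_tpm=is_tpm)


@dataclass
class BiasLabel:
    gene_id: str
    label: str  # male_biased | female_biased | unbiased
    log2_fc: float | None  # log2(male mean TPM / female mean TPM)
    padj: float | None
    p_raw: float | None = None


def _gene_pvalue(m: np.ndarray, f: np.ndarray, method: str) -> float:
    lm, lf = np.log2(m + 1), np.log2(f + 1)
    if np.ptp(np.concatenate([lm, lf])) == 0:
        return 1.0
    if method == "ranksum":
        return float(stats.mannwhitneyu(lm, lf, alternative="two-sided").pvalue)
    if method == "ttest":
        return float(stats.ttest_ind(lm, lf, equal_var=False).pvalue)
    if method == "permutation":
        pooled = np.concatenate([lm, lf])
        obs = abs(lm.mean() - lf.mean())
        n, nm = len(pooled), len(lm)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), nm):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx)] = True
            if abs(pooled[sel].mean() - pooled[~sel].mean()) >= obs - 1e-12:
                count += 1
            total += 1
        return count / total
    raise ValueError(f"unknown method {method!r}")


def call_sex_bias(
    expr: ExpressionMatrix,
    fc: float = 2.0,
    alpha: float = 0.05,
    method: str = "auto",
) -> list[BiasLabel]:
    """Label each gene male-/female-biased or unbiased.

    A gene is biased when its linear mean-TPM ratio is >= fc in one
    direction AND the BH-adjusted p of the male-vs-female test is
    < alpha. ``method='auto'`` uses the rank-sum test with >= 4
    replicates per sex and Welch's t on log2(TPM+1) below that (the
    exact rank null is too coarse at 2-3 replicates to ever reach
    alpha); 'ranksum', 'ttest' and 'permutation' force a choice.
    """
    males = expr.samples_of("male")
    females = expr.samples_of("female")
    if len(males) < 2 or len(females) < 2:
        raise ValueError("need >= 2 replicates per sex")
    if method == "auto":
        method = "ranksum" if min(len(males), len(females)) >= 4 else "ttest"

    M = expr.values[males].values
    F = expr.values[females].values
    genes = list(expr.values.index)
    pvals = np.full(len(genes), np.nan)
    log2fc = np.full(len(genes), np.nan)
    for i in range(len(genes)):
        m, f = M[i], F[i]
        if m.max() == 0 and f.max() == 0:
            continue  # all-zero gene: unbiased with missing p
        mm, fm = m.mean(), f.mean()
        if mm > 0 and fm > 0:
            log2fc[i] = np.log2(mm / fm)
        elif mm > 0:
            log2fc[i] = np.inf
        elif fm > 0:
            log2fc[i] = -np.inf
        pvals[i] = _gene_pvalue(m, f, method)

    tested = ~np.isnan(pvals)
    padj = np.full(len(genes), np.nan)
    if tested.any():
        padj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    out = []
    thresh = np.log2(fc)
    for i, g in enumerate(genes):
        lab = "unbiased"
        if tested[i] and padj[i] < alpha and not np.isnan(log2fc[i]):
            if log2fc[i] >= thresh:
                lab = "male_biased"
            elif log2fc[i] <= -thresh:
                lab = "female_biased"
        out.append(
            BiasLabel(
                g,
                lab,
                None if np.isnan(log2fc[i]) else float(log2fc[i]),
                None if np.isnan(padj[i]) else float(padj[i]),
                None if np.isnan(pvals[i]) else float(pvals[i]),
            )
        )
    return out


def load_de_table(path, fc: float = 2.0, alpha: float = 0.05) -> list[BiasLabel]:
    """Adopt labels from an external DE table (gene, log2FC, padj)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    thresh = np.log2(fc)
    for r in df.itertuples():
        lab = "unbiased"
        if r.padj < alpha:
            if r.log2FC >= thresh:
                lab = "male_biased"
            elif r.log2FC <= -thresh:
                lab = "female_biased"
        out.append(BiasLabel(r.gene, lab, float(r.log2FC), float(r.padj)))
    return out


def _mean_log_expr(expr: ExpressionMatrix, gene: str, sex: str) -> float:
    cols = expr.samples_of(sex)
    return float(np.log2(expr.values.loc[gene, cols].values.astype(float) + 1).mean())


def gametolog_expr_correlation(
    pairs,
    expr_m: ExpressionMatrix,
    expr_f: ExpressionMatrix,
) -> tuple[float, float]:
    """Pearson r between male-gametolog expression in males and
    female-gametolog expression in females (per-pair mean log2(TPM+1));
    two-sided p from the t-distribution with n-2 df."""
    x, y = [], []
    for p in pairs:
        mg = p.male_gene if hasattr(p, "male_gene") else p[0]
        fg = p.female_gene if hasattr(p, "female_gene") else p[1]
        if mg in expr_m.values.index and fg in expr_f.values.index:
            x.append(_mean_log_expr(expr_m, mg, "male"))
            y.append(_mean_log_expr(expr_f, fg, "female"))
    if len(x) < 3:
        raise ValueError("need >= 3 gametolog pairs with expression in both sexes")
    x, y = np.array(x), np.array(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an expression vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_t_sdr_vs_paralog(
    sdr_values: np.ndarray | list,
    paralog_values: np.ndarray | list,
) -> dict:
    """Two-sided paired t on log-scale expression differences
    (SDR gene - autosomal paralog), df = n - 1.

    Inputs are matched vectors of per-gene expression summaries (already
    on the log2(TPM+1) scale). A zero-variance difference vector is
    reported as undefined with a flag, never as p = 0.
    """
    a = np.asarray(sdr_values, dtype=float)
    b = np.asarray(paralog_values, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need >= 2 matched pairs")
    d = a - b
    if np.ptp(d) == 0:
        return {"t": None, "df": len(d) - 1, "p": None, "zero_variance": True}
    res = stats.ttest_rel(a, b)
    return {
        "t": float(res.statistic),
        "df": len(d) - 1,
        "p": float(res.pvalue),
        "zero_variance": False,
    }


def expression_of_classified(
    classified,
    expr_m: ExpressionMatrix,
    expr_f: ExpressionMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Matched log2(TPM+1) vectors for sex-limited SDR genes and their
    autosomal paralogs, each measured in the sex that carries the SDR
    gene."""
    sdr_vals, par_vals = [], []
    for rec in classified:
        if rec.gene_class != "sex_limited_with_autosomal_paralog":
            continue
        for expr, sex in ((expr_m, "male"), (expr_f, "female")):
            if rec.gene_id in expr.values.index and rec.partner in expr.values.index:
                sdr_vals.append(_mean_log_expr(expr, rec.gene_id, sex))
                par_vals.append(_mean_log_expr(expr, rec.partner, sex))
                break
    return np.array(sdr_vals), np.array(par_vals)


def holm_adjust(pvals) -> np.ndarray:
    return multipletests(np.asarray(pvals, dtype=float), method="holm")[1]


def bias_group_comparison(
    expr: ExpressionMatrix,
    labels: list[BiasLabel],
    sex: str,
) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum among bias classes with Holm correction.

    Compares mean log2(TPM+1) within ``sex`` between the three gene
    groups; groups with < 3 genes are skipped and recorded with missing
    p. Returns a DataFrame (group_a, group_b, p_raw, p_holm, skipped).
    """
    by_class: dict[str, list[float]] = {"male_biased": [], "female_biased": [], "unbiased": []}
    label_of = {l.gene_id: l.label for l in labels}
    cols = expr.samples_of(sex)
    logv = np.log2(expr.values[cols].values.astype(float) + 1).mean(axis=1)
    for gene, v in zip(expr.values.index, logv):
        lab = label_of.get(gene)
        if lab in by_class:
            by_class[lab].append(float(v))

    combos = list(itertools.combinations(["male_biased", "female_biased", "unbiased"], 2))
    rows = []
    raw = []
    for a, b in combos:
        va, vb = by_class[a], by_class[b]
        if len(va) < 3 or len(vb) < 3:
            rows.append([a, b, np.nan, True])
            continue
        if np.ptp(np.concatenate([va, vb])) == 0:
            p = 1.0
        else:
            n = max(len(va), len(vb))
            method = "exact" if n <= 8 else "asymptotic"
            try:
                p = float(stats.mannwhitneyu(va, vb, alternative="two-sided", method=method).pvalue)
            except ValueError:
                p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        rows.append([a, b, p, False])
        raw.append(p)
    adj = iter(holm_adjust(raw)) if raw else iter([])
    table = []
    for a, b, p, skipped in rows:
        table.append(
            {"group_a": a, "group_b": b, "p_raw": p,
             "p_holm": (np.nan if skipped else float(next(adj))), "skipped": skipped}
        )
    return pd.DataFrame(table)


def turnover_counts(bias_by_species: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Venn intersection cells of biased orthogroup sets across species.

    Returns {tuple of member species (sorted): count of orthogroups
    biased in exactly that species combination}. Refuses > 6 species.
    """
    species = sorted(bias_by_species)
    if len(species) > 6:
        raise ValueError("more than 6 species: Venn cells explode")
    universe = set().union(*bias_by_species.values()) if bias_by_species else set()
    cells: dict[tuple[str, ...], int] = {}
    for r in range(1, len(species) + 1):
        for members in itertools.combinations(species, r):
            exact = set(universe)
            for sp in species:
                if sp in members:
                    exact &= bias_by_species[sp]
                else:
                    exact -= bias_by_species[sp]
            cells[members] = len(exact)
    return cells


def par_enrichment(
    labels: list[BiasLabel],
    region_of_gene: dict[str, str],
    region: str = "PAR",
    baseline: str = "autosome",
) -> tuple[float, float]:
    """Chi-square test of sex-biased gene enrichment in a region.

    Builds the biased/unbiased x region/baseline 2x2 table and applies
    Pearson chi-square (df = 1, no continuity correction). Returns
    (chi2, p).
    """
    table = np.zeros((2, 2), dtype=int)
    for l in labels:
        reg = region_of_gene.get(l.gene_id)
        if reg == region:
            j = 0
        elif reg == baseline:
            j = 1
        else:
            continue
        i = 0 if l.label != "unbiased" else 1
        table[i, j] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate margin in 2x2 table: {table.tolist()}")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
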