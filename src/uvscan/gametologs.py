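"""Gametolog inference and synonymous divergence.

Male and female proteomes are paired by reciprocal best Smith-Waterman
hits; SDR genes are classified as gametologs (partner in the
opposite-sex SDR), sex-limited genes with an autosomal paralog, or
orphans. Coding alignments are threaded through the protein alignment,
gap/ambiguity columns removed, and synonymous (Ks) and non-synonymous
(Kn) divergence estimated by Nei-Gojobori counting with Jukes-Cantor
correction. A Ks-vs-position scan along the sex scaffold with optional
change-point segmentation looks for evolutionary strata (discrete Ks
levels reflecting successive recombination-suppression events).
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from ._seq import revcomp  # noqa: F401  (re-exported convenience)

_STOPS = set(standard_dna_table.stop_codons)
_CODON_AA = dict(standard_dna_table.forward_table)
SENSE_CODONS = sorted(_CODON_AA)
_BASES = "ACGT"


# ------------------------------------------------------------- alignment

def make_aligner(
    matrix: str | None = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    match: float | None = None,
    mismatch: float | None = None,
) -> Align.PairwiseAligner:
    """Local affine-gap aligner (Smith-Waterman-Gotoh)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if match is not None:
        aligner.match_score = match
        aligner.mismatch_score = mismatch if mismatch is not None else 0.0
    else:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def local_align(a: str, b: str, aligner: Align.PairwiseAligner | None = None):
    """Optimal local alignment of two protein sequences.

    Returns (score, alignment); the alignment is the aligner's first
    optimal traceback, which is deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if aligner is None:
        aligner = make_aligner()
    alignments = aligner.align(a, b)
    best = alignments[0]
    return float(best.score), best


def rbh_pairs(
    male,
    female,
    min_score: float = 50.0,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Reciprocal best hits between two proteomes.

    Proteomes are id -> sequence mappings or (id, sequence) iterables.
    (m, f) is a pair iff each is the other's unique best-scoring hit with
    score >= min_score. An equal best score shared by two subjects breaks
    to "no pair"; the tied query ids are returned alongside the pairs.
    """

    def _as_dict(prot):
        if isinstance(prot, dict):
            return prot
        pairs = list(prot)
        if len({i for i, _ in pairs}) != len(pairs):
            raise ValueError("duplicate sequence ids")
        return dict(pairs)

    male, female = _as_dict(male), _as_dict(female)
    if aligner is None:
        aligner = make_aligner()
    m_ids = sorted(male)
    f_ids = sorted(female)
    scores = np.full((len(m_ids), len(f_ids)), -np.inf)
    for i, m in enumerate(m_ids):
        for j, f in enumerate(f_ids):
            scores[i, j] = aligner.score(male[m], female[f])

    ties: list[str] = []

    def _best(row: np.ndarray) -> int | None:
        top = row.max()
        if top < min_score:
            return None
        hits = np.flatnonzero(row >= top - 1e-9)
        if len(hits) > 1:
            return -1  # tie sentinel
        return int(hits[0])

    best_m = [_best(scores[i]) for i in range(len(m_ids))]
    best_f = [_best(scores[:, j]) for j in range(len(f_ids))]
    pairs = []
    for i, j in enumerate(best_m):
        if j == -1:
            ties.append(m_ids[i])
            continue
        if j is None:
            continue
        if best_f[j] == -1:
            ties.append(f_ids[j])
            continue
        if best_f[j] == i:
            pairs.append((m_ids[i], f_ids[j]))
    return pairs, ties


# ---------------------------------------------------------- codon align

def translate(cds: str) -> str:
    cds = cds.upper().replace("U", "T")
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if codon in _STOPS:
            if i == len(cds) - 3:
                break
            raise ValueError(f"internal stop codon at {i}")
        aas.append(_CODON_AA.get(codon, "X"))
    return "".join(aas)


def codon_align(cds_a: str, cds_b: str, alignment) -> tuple[str, str]:
    """Thread codons through a protein alignment, dropping gap and
    ambiguous-base columns (a light-weight stand-in for the usual
    MAFFT + Gblocks codon pipeline).

    ``alignment`` is a Bio.Align local protein alignment of
    translate(cds_a) vs translate(cds_b). Returns two gap-free,
    equal-length, in-frame nucleotide strings.
    """
    cds_a = cds_a.upper().replace("U", "T")
    cds_b = cds_b.upper().replace("U", "T")
    if len(cds_a) % 3 or len(cds_b) % 3:
        raise ValueError("CDS length not a multiple of 3")
    prot_a, prot_b = translate(cds_a), translate(cds_b)
    if str(alignment.target).replace("-", "") not in prot_a or str(
        alignment.query
    ).replace("-", "") not in prot_b:
        raise ValueError("alignment does not match translated CDS")
    out_a: list[str] = []
    out_b: list[str] = []
    blocks_a, blocks_b = alignment.aligned
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        for oa, ob in zip(range(sa, ea), range(sb, eb)):
            ca = cds_a[3 * oa : 3 * oa + 3]
            cb = cds_b[3 * ob : 3 * ob + 3]
            if set(ca + cb) - set("ACGT"):
                continue
            out_a.append(ca)
            out_b.append(cb)
    return "".join(out_a), "".join(out_b)


# ----------------------------------------------------------------- NG86

@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """Nei-Gojobori synonymous/non-synonymous site counts for one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes to stop codons count as non-synonymous,
    so S + N = 3 exactly.
    """
    aa = _CODON_AA[codon]
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in _STOPS and _CODON_AA[alt] == aa:
                s += 1 / 3
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _codon_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/non-synonymous difference counts between two codons,
    averaged over all orderings of single-step mutational pathways;
    pathways passing through a stop codon are excluded."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    sd_tot, nd_tot, n_paths = 0.0, 0.0, 0
    for order in itertools.permutations(diffs):
        cur = c1
        sd, nd = 0.0, 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _CODON_AA[cur] == _CODON_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            sd_tot += sd
            nd_tot += nd
            n_paths += 1
    if n_paths == 0:
        # all pathways blocked by stops: split evenly (degenerate, rare)
        return len(diffs) / 2, len(diffs) / 2
    return sd_tot / n_paths, nd_tot / n_paths


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when saturated (4p/3 >= 1)."""
    if p < 0:
        raise ValueError("negative p-distance")
    if 4 * p / 3 >= 1:
        return None
    if p == 0:
        return 0.0
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass
class Ng86Result:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float | None
    pN: float | None
    Ks: float | None
    Kn: float | None
    omega: float | None
    saturated: bool


def ng86(aln_a: str, aln_b: str) -> Ng86Result:
    """Nei-Gojobori (1986) Ks/Kn on a gap-free in-frame codon alignment.

    Site counts are averaged over the two sequences; multiple-difference
    codons average over all single-step pathway orderings (stop-passing
    pathways excluded); JC69 corrects for multiple hits. ``saturated``
    marks a synonymous p-distance at or beyond 3/4, where the correction
    is undefined and Ks is reported missing.
    """
    if len(aln_a) != len(aln_b) or len(aln_a) % 3:
        raise ValueError("alignment rows must be equal length multiples of 3")
    n_codons = len(aln_a) // 3
    if n_codons < 10:
        warnings.warn(f"only {n_codons} codons: NG86 estimates will be noisy")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(aln_a), 3):
        ca, cb = aln_a[i : i + 3], aln_b[i : i + 3]
        if ca in _STOPS or cb in _STOPS:
            raise ValueError(f"stop codon inside alignment at {i}")
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _codon_path_counts(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    Ks = jukes_cantor(pS) if pS is not None else None
    Kn = jukes_cantor(pN) if pN is not None else None
    saturated = pS is not None and 4 * pS / 3 >= 1
    omega = None
    if Ks is not None and Ks > 0 and Kn is not None and not saturated:
        omega = Kn / Ks
    return Ng86Result(S, N, Sd, Nd, pS, pN, Ks, Kn, omega, saturated)


# ------------------------------------------------------- classification

@dataclass
class GametologPair:
    male_gene: str
    female_gene: str
    ks: float | None
    kn: float | None
    omega: float | None
    saturated: bool
    v_position: int | None = None  # bp on the male (V) scaffold


@dataclass
class SdrGeneClass:
    gene_id: str
    gene_class: str  # gametolog | sex_limited_with_autosomal_paralog | sex_limited_orphan
    partner: str | None = None


def classify_sdr_genes(
    sdr_m: list[str],
    sdr_f: list[str],
    rbh: list[tuple[str, str]],
    self_hits: dict[str, str | None],
    proteome_ids: set[str] | None = None,
) -> list[SdrGeneClass]:
    """Classify SDR genes of both sexes.

    gametolog: reciprocal-best-hit partner lies in the opposite-sex SDR;
    sex_limited_with_autosomal_paralog: no such partner but a
    within-genome non-SDR hit exists (``self_hits[gene]``); otherwise
    sex_limited_orphan.
    """
    if proteome_ids is not None:
        missing = (set(sdr_m) | set(sdr_f)) - proteome_ids
        if missing:
            raise ValueError(f"genes absent from proteome: {sorted(missing)[:5]}")
    partner_of = {}
    for m, f in rbh:
        partner_of[m] = f
        partner_of[f] = m
    sdr_f_set, sdr_m_set = set(sdr_f), set(sdr_m)
    out = []
    for gene, opp_set in [(g, sdr_f_set) for g in sdr_m] + [(g, sdr_m_set) for g in sdr_f]:
        partner = partner_of.get(gene)
        if partner is not None and partner in opp_set:
            out.append(SdrGeneClass(gene, "gametolog", partner))
        elif self_hits.get(gene):
            out.append(SdrGeneClass(gene, "sex_limited_with_autosomal_paralog", self_hits[gene]))
        else:
            out.append(SdrGeneClass(gene, "sex_limited_orphan", None))
    return out


# ----------------------------------------------------------- strata scan

def _binary_segment(values: np.ndarray, min_size: int, penalty: float) -> list[int]:
    """Recursive binary segmentation on the mean; returns sorted
    breakpoints (indices where a new segment starts)."""

    def sse(v: np.ndarray) -> float:
        return float(((v - v.mean()) ** 2).sum()) if len(v) else 0.0

    def split(lo: int, hi: int) -> list[int]:
        v = values[lo:hi]
        n = hi - lo
        if n < 2 * min_size:
            return []
        total = sse(v)
        best_gain, best_k = 0.0, None
        for k in range(min_size, n - min_size + 1):
            gain = total - sse(v[:k]) - sse(v[k:])
            if gain > best_gain:
                best_gain, best_k = gain, k
        if best_k is None or best_gain <= penalty:
            return []
        mid = lo + best_k
        return split(lo, mid) + [mid] + split(mid, hi)

    return split(0, len(values))


def strata_scan(
    pairs: list[GametologPair],
    min_segment: int = 3,
    penalty: float | None = None,
    saturated_ks: float = 3.0,
) -> dict:
    """Order gametolog Ks along the V scaffold and segment it.

    Saturated pairs are ranked oldest (assigned ``saturated_ks`` for
    segmentation only). Returns {"table": [(v_position, male_gene,
    female_gene, ks, saturated)], "segments": [(start_idx, end_idx,
    mean_ks)]}; without positional data only the table is returned.
    """
    usable = [p for p in pairs if p.ks is not None or p.saturated]
    if len(usable) < 2:
        raise ValueError("need >= 2 gametolog pairs with defined or saturated Ks")
    have_pos = all(p.v_position is not None for p in usable)
    if have_pos:
        usable.sort(key=lambda p: p.v_position)
    table = [
        (p.v_position, p.male_gene, p.female_gene, p.ks, p.saturated) for p in usable
    ]
    result: dict = {"table": table, "segments": None}
    if not have_pos:
        return result
    ks = np.array([saturated_ks if p.saturated else p.ks for p in usable])
    if penalty is None:
        # BIC-style default: var * log(n) per added breakpoint
        penalty = float(np.var(ks)) * math.log(max(len(ks), 2))
    breaks = _binary_segment(ks, min_segment, penalty)
    bounds = [0] + breaks + [len(ks)]
    result["segments"] = [
        (bounds[i], bounds[i + 1], float(ks[bounds[i] : bounds[i + 1]].mean()))
        for i in range(len(bounds) - 1)
    ]
    return result
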