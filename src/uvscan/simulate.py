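"""Paired male/female synthetic genomes, reads and expression data.

The generator emulates a haploid UV system: male and female assemblies
share autosomes and pseudoautosomal regions (PARs) base-for-base, while
a planted central sex-determining region (SDR) on the sex scaffold
carries diverged U/V haplotypes, gametolog pairs at controlled
synonymous divergence, sex-limited gene insertions and a configurable
repeat load. Short reads per sex and replicate TPM matrices with planted
sex-biased fold changes complete the truth-tracked data set.

All randomness flows from one seed; per-stage generators are spawned
deterministically, so a fixed seed reproduces every output byte.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seq
from .gametologs import _codon_sites, _CODON_AA, _STOPS, SENSE_CODONS

_BASES = "ACGT"


@dataclass
class SimParams:
    """Scenario parameters; the defaults define the package's reference
    simulation (1-Mb sex scaffold with a 200-kb central SDR at 5%
    divergence, five 500-kb autosomes, 20x 100-bp reads per sex)."""

    seed: int = 1
    n_autosomes: int = 5
    autosome_len: int = 500_000
    sex_scaffold_len: int = 1_000_000
    sdr_interval: tuple[int, int] = (400_000, 600_000)
    sdr_divergence: float = 0.05
    n_gametologs: int = 12
    gametolog_ks_levels: tuple[float, ...] = (0.05, 0.2, 0.5)
    n_sex_limited_male: int = 6
    n_sex_limited_female: int = 6
    paralog_fraction: float = 0.5
    repeat_fraction_sdr: float = 0.10
    repeat_fraction_par: float = 0.05
    repeat_fraction_auto: float = 0.10
    gc_content: float = 0.5
    read_depth: float = 20.0
    read_len: int = 100
    err_rate: float = 0.002
    genes_per_autosome: int = 30
    genes_per_par_10kb: float = 1.0  # PAR gene density, genes per 10 kb
    gene_len_codons: int = 300
    expr_n_replicates: int = 3
    expr_fold_changes: tuple[float, ...] = (2.0, 4.0, 8.0)
    expr_n_biased: int = 30
    expr_dispersion: float = 0.25  # sd of log2 expression noise

    def validate(self) -> None:
        s, e = self.sdr_interval
        if not (0 <= s < e <= self.sex_scaffold_len):
            raise ValueError("sdr_interval outside the sex scaffold")
        if self.sdr_divergence > 0.75:
            raise ValueError("divergence > 0.75 is saturated by construction")
        for name in ("sdr_divergence", "paralog_fraction", "gc_content", "err_rate",
                     "repeat_fraction_sdr", "repeat_fraction_par", "repeat_fraction_auto"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_autosomes", "autosome_len", "sex_scaffold_len",
                     "read_len", "gene_len_codons", "expr_n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if any(f <= 0 for f in self.expr_fold_changes):
            raise ValueError("fold changes must be positive")
        if any(k < 0 for k in self.gametolog_ks_levels):
            raise ValueError("Ks targets must be non-negative")


@dataclass
class TruthSet:
    """Ground truth for every planted feature."""

    sdr_interval: dict[str, tuple[str, int, int]]  # sex -> (scaffold, start, end)
    genes: pd.DataFrame  # gene_id, klass, partner, target_ks, per-sex coords
    repeats: dict[str, pd.DataFrame]  # sex -> scaffold/start/end
    bias: pd.DataFrame | None = None  # gene_id, label, fold
    divergence_target: float = 0.0
    background_bases: int = 0  # SDR background bases eligible for substitution
    background_subs: int = 0  # substitutions actually applied


@dataclass
class SimResult:
    params: SimParams
    male: list[tuple[str, str]]  # (scaffold id, sequence)
    female: list[tuple[str, str]]
    genes: dict[str, pd.DataFrame]  # sex -> gene_id/scaffold/start/end
    repeats: dict[str, pd.DataFrame]
    truth: TruthSet

    def scaffold_lengths(self, sex: str) -> dict[str, int]:
        recs = self.male if sex == "male" else self.female
        return {name: len(seq) for name, seq in recs}

    def write(self, outdir) -> None:
        import os
        import yaml

        os.makedirs(outdir, exist_ok=True)
        j = lambda *p: os.path.join(outdir, *p)
        for sex, recs in (("male", self.male), ("female", self.female)):
            _seq.write_fasta(j(f"{sex}.fa"), recs)
            with open(j(f"{sex}.gff3"), "w") as fh:
                fh.write("##gff-version 3\n")
                for r in self.genes[sex].itertuples():
                    attrs = f"ID={r.gene_id}"
                    fh.write(
                        f"{r.scaffold}\tuvscan_sim\tgene\t{r.start + 1}\t{r.end}\t.\t+\t.\t{attrs}\n"
                    )
                    fh.write(
                        f"{r.scaffold}\tuvscan_sim\tCDS\t{r.start + 1}\t{r.end}\t.\t+\t0\tID={r.gene_id}.cds;Parent={r.gene_id}\n"
                    )
            self.repeats[sex].to_csv(
                j(f"{sex}_repeats.bed"), sep="\t", header=False, index=False
            )
        self.truth.genes.to_csv(j("truth_genes.tsv"), sep="\t", index=False)
        if self.truth.bias is not None:
            self.truth.bias.to_csv(j("truth_bias.tsv"), sep="\t", index=False)
        manifest = {
            "params": dataclasses.asdict(self.params),
            "sdr_interval": {
                sex: list(v) for sex, v in self.truth.sdr_interval.items()
            },
            "divergence": {
                "target": self.truth.divergence_target,
                "background_bases": self.truth.background_bases,
                "background_subs": self.truth.background_subs,
            },
        }
        with open(j("truth.yaml"), "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)


# ------------------------------------------------------------- sequence

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(4, size=n, p=p).astype(np.uint8)
    return _seq.decode(arr)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Per-site i.i.d. substitution, uniform among the 3 alternatives."""
    if rate == 0 or not seq:
        return seq, 0
    enc = _seq.encode(seq).copy()
    mask = (rng.random(len(enc)) < rate) & (enc < 4)
    offs = rng.integers(1, 4, size=len(enc)).astype(np.uint8)
    enc[mask] = (enc[mask] + offs[mask]) % 4
    return _seq.decode(enc), int(mask.sum())


def _make_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random CDS: ATG + (n_codons - 2) sense codons + TAA."""
    body = rng.choice(len(SENSE_CODONS), size=max(n_codons - 2, 0))
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"


_SYN_NEIGHBOURS: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    opts = []
    for _pos in range(3):
        for _b in _BASES:
            if _b == _c[_pos]:
                continue
            _alt = _c[:_pos] + _b + _c[_pos + 1 :]
            if _alt not in _STOPS and _CODON_AA[_alt] == _CODON_AA[_c]:
                opts.append(_alt)
    _SYN_NEIGHBOURS[_c] = opts


def diverge_synonymous(cds: str, target_ks: float, rng: np.random.Generator) -> str:
    """Copy of a CDS carrying only synonymous changes, tuned so the
    Nei-Gojobori + JC estimate of Ks recovers ``target_ks``.

    The number of single-step synonymous substitutions is set to
    pS* x S where pS* = 3/4 (1 - exp(-4 Ks / 3)) inverts the JC
    correction and S is the sequence's synonymous site count; that many
    distinct codons receive one random synonymous neighbour each.
    """
    if target_ks == 0:
        return cds
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    editable = [i for i, c in enumerate(codons) if c not in _STOPS and _SYN_NEIGHBOURS[c]]
    S = sum(_codon_sites(c)[0] for c in codons if c not in _STOPS)
    ps_star = 0.75 * (1 - math.exp(-4 * target_ks / 3))
    n_subs = int(round(ps_star * S))
    if n_subs > len(editable):
        raise ValueError(
            f"target Ks {target_ks} needs {n_subs} synonymous changes but only "
            f"{len(editable)} codons are editable"
        )
    chosen = rng.choice(len(editable), size=n_subs, replace=False)
    for j in chosen:
        i = editable[j]
        opts = _SYN_NEIGHBOURS[codons[i]]
        codons[i] = opts[rng.integers(len(opts))]
    return "".join(codons)


def _diverge_cds(cds: str, codon_rate: float, rng: np.random.Generator) -> str:
    """Paralog-style copy: each internal codon is replaced by a random
    sense codon with probability ``codon_rate`` (changes the protein)."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i in range(1, len(codons)):
        if codons[i] in _STOPS:
            continue
        if rng.random() < codon_rate:
            codons[i] = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
    return "".join(codons)


def _repeat_locus(rng: np.random.Generator, gc: float) -> str:
    """Tandem copies of one random monomer (no TE biology modelled).

    Loci are kept short (2-6 copies of a 50-bp monomer): each extra copy
    multiplies the k-mer multiplicity seen by every depth- and
    k-mer-based detector, exactly like multi-mapping does for real
    repeat arrays, and long arrays would simply blank out their windows.
    """
    monomer = _random_seq(rng, 50, gc)
    return monomer * int(rng.integers(2, 7))


def _plan_layout(
    rng: np.random.Generator, length: int, feature_lens: list[int]
) -> list[int]:
    """Random non-overlapping start offsets preserving feature order."""
    total = sum(feature_lens)
    free = length - total
    if free < 0:
        raise ValueError("features exceed region length")
    gaps = rng.multinomial(free, np.ones(len(feature_lens) + 1) / (len(feature_lens) + 1))
    starts = []
    pos = 0
    for g, flen in zip(gaps[:-1], feature_lens):
        pos += int(g)
        starts.append(pos)
        pos += flen
    return starts


def _build_shared_region(
    rng: np.random.Generator,
    length: int,
    gene_specs: list[tuple[str, str]],
    repeat_fraction: float,
    gc: float,
) -> tuple[str, list[tuple[str, int, int]], list[tuple[int, int]]]:
    """A region identical in both sexes: background + genes + repeats.

    Returns (sequence, [(gene_id, start, end)], [(rep_start, rep_end)]).
    """
    feats: list[tuple[str, str | None, str]] = [
        ("gene", gid, cds) for gid, cds in gene_specs
    ]
    target_rep = int(repeat_fraction * length)
    rep_bp = 0
    while rep_bp < target_rep:
        locus = _repeat_locus(rng, gc)
        feats.append(("rep", None, locus))
        rep_bp += len(locus)
    order = rng.permutation(len(feats))
    feats = [feats[i] for i in order]
    starts = _plan_layout(rng, length, [len(f[2]) for f in feats])
    seq = list(_random_seq(rng, length, gc))
    genes, reps = [], []
    for (kind, gid, fseq), start in zip(feats, starts):
        seq[start : start + len(fseq)] = fseq
        if kind == "gene":
            genes.append((gid, start, start + len(fseq)))
        else:
            reps.append((start, start + len(fseq)))
    return "".join(seq), genes, sorted(reps)


# -------------------------------------------------------------- genomes

def simulate_genome_pair(params: SimParams) -> SimResult:
    """Generate the male/female assembly pair with full truth tracking."""
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(8)]
    rng_auto, rng_par, rng_sdr, rng_div = rngs[0], rngs[1], rngs[2], rngs[3]

    cds_len = params.gene_len_codons
    gene_rows: list[dict] = []  # truth rows
    male_genes: list[dict] = []
    female_genes: list[dict] = []
    male_reps: list[dict] = []
    female_reps: list[dict] = []
    male_records: list[tuple[str, str]] = []
    female_records: list[tuple[str, str]] = []

    # sex-limited genes (and their optional autosomal paralogs) first, so
    # paralog copies can be planted on autosomes
    mlim = [(f"slm{i:02d}_M", _make_cds(rng_sdr, cds_len)) for i in range(params.n_sex_limited_male)]
    flim = [(f"slf{i:02d}_F", _make_cds(rng_sdr, cds_len)) for i in range(params.n_sex_limited_female)]
    paralogs: list[tuple[str, str, str]] = []  # (paralog_id, source_id, cds)
    for gid, cds in mlim + flim:
        if rng_sdr.random() < params.paralog_fraction:
            pid = gid[:-2] + "_P"
            pcds = _diverge_cds(diverge_synonymous(cds, 0.10, rng_sdr), 0.10, rng_sdr)
            paralogs.append((pid, gid, pcds))

    # ------------------------------------------------------- autosomes
    paralog_iter = iter(paralogs)
    for a in range(params.n_autosomes):
        name = f"autosome_{a + 1:02d}"
        specs = [
            (f"auto{a + 1:02d}_g{i:03d}", _make_cds(rng_auto, cds_len))
            for i in range(params.genes_per_autosome)
        ]
        extra = []
        # spread paralog copies across autosomes
        for pid, src, pcds in paralog_iter:
            extra.append((pid, src, pcds))
            if len(extra) >= math.ceil(len(paralogs) / params.n_autosomes):
                break
        specs += [(pid, pcds) for pid, _, pcds in extra]
        seq, genes, reps = _build_shared_region(
            rng_auto, params.autosome_len, specs, params.repeat_fraction_auto, params.gc_content
        )
        male_records.append((name, seq))
        female_records.append((name, seq))
        src_of = {pid: src for pid, src, _ in extra}
        for gid, s, e in genes:
            row = {"gene_id": gid, "scaffold": name, "start": s, "end": e}
            male_genes.append(row)
            female_genes.append(dict(row))
            gene_rows.append(
                {
                    "gene_id": gid,
                    "klass": "autosomal_paralog" if gid in src_of else "autosomal",
                    "partner": src_of.get(gid),
                    "target_ks": np.nan,
                    "scaffold_male": name, "start_male": s, "end_male": e,
                    "scaffold_female": name, "start_female": s, "end_female": e,
                }
            )
        for s, e in reps:
            male_reps.append({"scaffold": name, "start": s, "end": e})
            female_reps.append({"scaffold": name, "start": s, "end": e})

    # ---------------------------------------------------- sex scaffold
    sdr_start, sdr_end = params.sdr_interval
    sex_name = "sex_scaffold"
    par_lens = (sdr_start, params.sex_scaffold_len - sdr_end)
    par_specs: list[list[tuple[str, str]]] = []
    counter = 0
    for plen in par_lens:
        n_genes = int(round(params.genes_per_par_10kb * plen / 10_000))
        par_specs.append(
            [(f"par_g{counter + i:03d}", _make_cds(rng_par, cds_len)) for i in range(n_genes)]
        )
        counter += n_genes

    par_parts = [
        _build_shared_region(rng_par, plen, specs, params.repeat_fraction_par, params.gc_content)
        for plen, specs in zip(par_lens, par_specs)
    ]

    # SDR segment list: background blocks, gametologs, sex-limited genes,
    # repeat loci; each segment knows its male and female realisation.
    gams = [
        (f"gam{i:02d}", _make_cds(rng_sdr, cds_len)) for i in range(params.n_gametologs)
    ]
    ks_of = {
        gid: params.gametolog_ks_levels[i % len(params.gametolog_ks_levels)]
        if params.gametolog_ks_levels
        else 0.0
        for i, (gid, _) in enumerate(gams)
    }
    sdr_len = sdr_end - sdr_start
    feats: list[tuple[str, str | None, str]] = (
        [("gam", gid, cds) for gid, cds in gams]
        + [("mlim", gid, cds) for gid, cds in mlim]
    )
    target_rep = int(params.repeat_fraction_sdr * sdr_len)
    rep_bp = 0
    while rep_bp < target_rep:
        locus = _repeat_locus(rng_sdr, params.gc_content)
        feats.append(("rep", None, locus))
        rep_bp += len(locus)
    order = rng_sdr.permutation(len(feats))
    feats = [feats[i] for i in order]
    starts = _plan_layout(rng_sdr, sdr_len, [len(f[2]) for f in feats])

    segments: list[tuple[str, str | None, str]] = []  # (kind, id, male_seq)
    pos = 0
    for (kind, gid, fseq), start in zip(feats, starts):
        if start > pos:
            segments.append(("bg", None, _random_seq(rng_sdr, start - pos, params.gc_content)))
        segments.append((kind, gid, fseq))
        pos = start + len(fseq)
    if pos < sdr_len:
        segments.append(("bg", None, _random_seq(rng_sdr, sdr_len - pos, params.gc_content)))

    # female-limited insertions at random segment boundaries
    for gid, cds in flim:
        idx = int(rng_sdr.integers(0, len(segments) + 1))
        segments.insert(idx, ("flim", gid, cds))

    d = params.sdr_divergence
    bg_bases = bg_subs = 0
    male_sdr_parts: list[str] = []
    female_sdr_parts: list[str] = []
    m_pos = sdr_start  # running coordinate on the male scaffold
    f_pos = sdr_start
    for kind, gid, mseq in segments:
        if kind == "bg" or kind == "rep":
            fseq_out, nsub = _mutate(mseq, d, rng_div)
            bg_bases += len(mseq)
            bg_subs += nsub
            if kind == "rep":
                male_reps.append({"scaffold": sex_name, "start": m_pos, "end": m_pos + len(mseq)})
                female_reps.append({"scaffold": sex_name, "start": f_pos, "end": f_pos + len(mseq)})
            male_sdr_parts.append(mseq)
            female_sdr_parts.append(fseq_out)
            m_pos += len(mseq)
            f_pos += len(mseq)
        elif kind == "gam":
            fcds = diverge_synonymous(mseq, ks_of[gid], rng_div)
            male_sdr_parts.append(mseq)
            female_sdr_parts.append(fcds)
            mg, fg = f"{gid}_M", f"{gid}_F"
            male_genes.append({"gene_id": mg, "scaffold": sex_name, "start": m_pos, "end": m_pos + len(mseq)})
            female_genes.append({"gene_id": fg, "scaffold": sex_name, "start": f_pos, "end": f_pos + len(fcds)})
            gene_rows.append(
                {
                    "gene_id": mg, "klass": "gametolog", "partner": fg,
                    "target_ks": ks_of[gid],
                    "scaffold_male": sex_name, "start_male": m_pos, "end_male": m_pos + len(mseq),
                    "scaffold_female": None, "start_female": np.nan, "end_female": np.nan,
                }
            )
            gene_rows.append(
                {
                    "gene_id": fg, "klass": "gametolog", "partner": mg,
                    "target_ks": ks_of[gid],
                    "scaffold_male": None, "start_male": np.nan, "end_male": np.nan,
                    "scaffold_female": sex_name, "start_female": f_pos, "end_female": f_pos + len(fcds),
                }
            )
            m_pos += len(mseq)
            f_pos += len(fcds)
        elif kind == "mlim":
            male_sdr_parts.append(mseq)
            male_genes.append({"gene_id": gid, "scaffold": sex_name, "start": m_pos, "end": m_pos + len(mseq)})
            gene_rows.append(
                {
                    "gene_id": gid, "klass": "sex_limited_male", "partner": None,
                    "target_ks": np.nan,
                    "scaffold_male": sex_name, "start_male": m_pos, "end_male": m_pos + len(mseq),
                    "scaffold_female": None, "start_female": np.nan, "end_female": np.nan,
                }
            )
            m_pos += len(mseq)
        elif kind == "flim":
            female_sdr_parts.append(mseq)
            female_genes.append({"gene_id": gid, "scaffold": sex_name, "start": f_pos, "end": f_pos + len(mseq)})
            gene_rows.append(
                {
                    "gene_id": gid, "klass": "sex_limited_female", "partner": None,
                    "target_ks": np.nan,
                    "scaffold_male": None, "start_male": np.nan, "end_male": np.nan,
                    "scaffold_female": sex_name, "start_female": f_pos, "end_female": f_pos + len(mseq),
                }
            )
            f_pos += len(mseq)

    male_sdr = "".join(male_sdr_parts)
    female_sdr = "".join(female_sdr_parts)

    # assemble the sex scaffold; PAR genes/repeats are shared, the second
    # PAR shifts by each sex's SDR length
    male_seq = par_parts[0][0] + male_sdr + par_parts[1][0]
    female_seq = par_parts[0][0] + female_sdr + par_parts[1][0]
    male_records.append((sex_name, male_seq))
    female_records.append((sex_name, female_seq))

    for which, (pseq, pgenes, preps) in enumerate(par_parts):
        m_off = 0 if which == 0 else sdr_start + len(male_sdr)
        f_off = 0 if which == 0 else sdr_start + len(female_sdr)
        for gid, s, e in pgenes:
            male_genes.append({"gene_id": gid, "scaffold": sex_name, "start": s + m_off, "end": e + m_off})
            female_genes.append({"gene_id": gid, "scaffold": sex_name, "start": s + f_off, "end": e + f_off})
            gene_rows.append(
                {
                    "gene_id": gid, "klass": "par", "partner": None, "target_ks": np.nan,
                    "scaffold_male": sex_name, "start_male": s + m_off, "end_male": e + m_off,
                    "scaffold_female": sex_name, "start_female": s + f_off, "end_female": e + f_off,
                }
            )
        for s, e in preps:
            male_reps.append({"scaffold": sex_name, "start": s + m_off, "end": e + m_off})
            female_reps.append({"scaffold": sex_name, "start": s + f_off, "end": e + f_off})

    truth = TruthSet(
        sdr_interval={
            "male": (sex_name, sdr_start, sdr_start + len(male_sdr)),
            "female": (sex_name, sdr_start, sdr_start + len(female_sdr)),
        },
        genes=pd.DataFrame(gene_rows),
        repeats={
            "male": pd.DataFrame(male_reps, columns=["scaffold", "start", "end"]).sort_values(
                ["scaffold", "start"]
            ).reset_index(drop=True),
            "female": pd.DataFrame(female_reps, columns=["scaffold", "start", "end"]).sort_values(
                ["scaffold", "start"]
            ).reset_index(drop=True),
        },
        divergence_target=d,
        background_bases=bg_bases,
        background_subs=bg_subs,
    )
    genes = {
        "male": pd.DataFrame(male_genes).sort_values(["scaffold", "start"]).reset_index(drop=True),
        "female": pd.DataFrame(female_genes).sort_values(["scaffold", "start"]).reset_index(drop=True),
    }
    return SimResult(
        params=params,
        male=male_records,
        female=female_records,
        genes=genes,
        repeats=truth.repeats,
        truth=truth,
    )


# ----------------------------------------------------------------- reads

def simulate_reads(
    genome,
    depth: float,
    read_len: int,
    err_rate: float,
    seed: int,
) -> list[tuple[str, str]]:
    """Uniform error-prone short reads from both strands of a genome.

    ``genome`` is a FASTA path or (id, sequence) iterable. The total read
    count is round(total_bp * depth / read_len), apportioned to
    scaffolds by length (largest remainder). Returns (read id, sequence)
    pairs; write with :func:`write_fastq`.
    """
    import os

    if depth <= 0:
        raise ValueError("depth must be positive")
    records = (
        _seq.read_fasta(genome) if isinstance(genome, (str, os.PathLike)) else list(genome)
    )
    if not records:
        raise ValueError("empty genome")
    shortest = min(len(s) for _, s in records)
    if read_len > shortest:
        raise ValueError(f"read_len {read_len} exceeds shortest scaffold ({shortest} bp)")

    total_bp = sum(len(s) for _, s in records)
    n_total = int(round(total_bp * depth / read_len))
    exact = np.array([len(s) for _, s in records], dtype=float) * n_total / total_bp
    n_per = np.floor(exact).astype(int)
    remainder = n_total - n_per.sum()
    order = np.argsort(-(exact - n_per))
    n_per[order[:remainder]] += 1

    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    ridx = 0
    for (name, seq), n in zip(records, n_per):
        if n == 0:
            continue
        enc = _seq.encode(seq)
        starts = rng.integers(0, len(seq) - read_len + 1, size=n)
        mat = enc[starts[:, None] + np.arange(read_len)[None, :]].copy()
        minus = rng.random(n) < 0.5
        mat[minus] = (3 - mat[minus][:, ::-1]) % 4  # reverse complement
        if err_rate > 0:
            mask = rng.random(mat.shape) < err_rate
            offs = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
            mat[mask] = (mat[mask] + offs[mask]) % 4
        for i in range(n):
            reads.append((f"{name}_r{ridx + i}", _seq.decode(mat[i])))
        ridx += n
    return reads


def write_fastq(reads, path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ------------------------------------------------------------ expression

def simulate_expression(truth: TruthSet, params: SimParams, seed: int | None = None):
    """Replicate TPM matrices with planted sex-biased fold changes.

    Per-gene baselines are log-normal; unbiased genes share one log-scale
    mean across sexes, planted biased genes split a log2 fold change
    symmetrically, gametolog partners share their pair's baseline, and
    sex-limited genes are expressed only in their own sex at half their
    autosomal paralog's mean. Columns are TPM-normalised to 1e6.

    Returns (ExpressionMatrix, truth-bias DataFrame); the bias table is
    also attached to ``truth.bias``.
    """
    from .expression import ExpressionMatrix

    params.validate()
    if params.expr_n_replicates < 2:
        raise ValueError("need >= 2 replicates per sex")
    rng = np.random.default_rng(params.seed + 1_000_003 if seed is None else seed)
    g = truth.genes
    gene_ids = list(g.gene_id)
    klass = dict(zip(g.gene_id, g.klass))
    partner = dict(zip(g.gene_id, g.partner))
    in_male = {r.gene_id: isinstance(r.scaffold_male, str) for r in g.itertuples()}
    in_female = {r.gene_id: isinstance(r.scaffold_female, str) for r in g.itertuples()}

    mu: dict[str, float] = {}
    for gid in gene_ids:
        if gid in mu:
            continue
        base = float(rng.normal(6.0, 1.5))
        mu[gid] = base
        if klass[gid] == "gametolog" and partner.get(gid):
            mu[partner[gid]] = base + float(rng.normal(0.0, 0.3))
    # sex-limited genes sit at half their paralog's expression
    paralog_of = {
        r.partner: r.gene_id for r in g.itertuples() if r.klass == "autosomal_paralog"
    }
    for slg, pid in paralog_of.items():
        mu[slg] = mu[pid] - 1.0

    candidates = [
        gid for gid in gene_ids
        if klass[gid] in ("autosomal", "par") and in_male[gid] and in_female[gid]
    ]
    n_biased = min(params.expr_n_biased, len(candidates))
    biased = list(rng.choice(candidates, size=n_biased, replace=False))
    shift: dict[str, float] = {}
    bias_rows = []
    for i, gid in enumerate(biased):
        fold = params.expr_fold_changes[i % len(params.expr_fold_changes)]
        direction = 1 if i % 2 == 0 else -1
        shift[gid] = direction * math.log2(fold) / 2
        bias_rows.append(
            {"gene_id": gid, "label": "male_biased" if direction > 0 else "female_biased",
             "fold": fold}
        )
    for gid in gene_ids:
        if gid not in shift:
            bias_rows.append({"gene_id": gid, "label": "unbiased", "fold": 1.0})

    r = params.expr_n_replicates
    cols = [f"M{i + 1}" for i in range(r)] + [f"F{i + 1}" for i in range(r)]
    sex_of = {c: ("male" if c.startswith("M") else "female") for c in cols}
    mat = np.zeros((len(gene_ids), 2 * r))
    for i, gid in enumerate(gene_ids):
        for j, c in enumerate(cols):
            sex = sex_of[c]
            present = in_male[gid] if sex == "male" else in_female[gid]
            if not present:
                continue
            s = shift.get(gid, 0.0) * (1 if sex == "male" else -1)
            mat[i, j] = 2 ** (mu[gid] + s + rng.normal(0.0, params.expr_dispersion))
    mat = mat * (1e6 / mat.sum(axis=0, keepdims=True))
    expr = ExpressionMatrix(
        values=pd.DataFrame(mat, index=gene_ids, columns=cols),
        sex=sex_of,
        species="synthetic",
    )
    bias = pd.DataFrame(bias_rows)
    truth.bias = bias
    return expr, bias
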