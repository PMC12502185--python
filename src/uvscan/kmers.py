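"""Canonical k-mer counting and the three windowed k-mer statistics.

Three statistics, computed over fixed windows of an assembly, flag
sequence present in one sex but not the other:

* **AWK** — density (per kb) of sex-specific k-mers: k-mers seen in the
  same-sex read set but entirely absent from the opposite-sex reads.
* **KQ** — the k-mer quotient: the depth-normalised same:opposite
  frequency ratio of the window k-mers shared by both read sets.
* **YGS%** — the percentage of distinct window k-mers with no match in
  the opposite-sex source (assembly by default, reads optionally).

A hemizygous sex-determining region shows high AWK, high YGS% and no
opposite-sex coverage; autosomes and pseudoautosomal regions sit at
AWK ≈ 0, KQ ≈ 1, YGS% ≈ 0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _seq

DEFAULT_K = 15
DEFAULT_WINDOW = 1000

#: default per-window flag cutoffs, calibrated on the bundled simulator
#: (see the package methods note); always overridable.
DEFAULT_CUTOFFS = {"awk": 20.0, "kq": 2.0, "ygs": 30.0}


@dataclass
class KmerTable:
    """Canonical k-mer -> count table, stored as sorted packed codes."""

    k: int
    codes: np.ndarray  # sorted unique int64 canonical codes
    counts: np.ndarray  # int64, parallel to codes
    source: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.codes.shape != self.counts.shape:
            raise ValueError("codes/counts length mismatch")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.codes)

    def get(self, kmer: str) -> int:
        code = _seq.kmer_to_code(_seq.canonical(kmer))
        i = np.searchsorted(self.codes, code)
        if i < len(self.codes) and self.codes[i] == code:
            return int(self.counts[i])
        return 0

    def __getitem__(self, kmer: str) -> int:
        return self.get(kmer)

    def __contains__(self, kmer: str) -> bool:
        return self.get(kmer) > 0

    def to_dict(self) -> dict[str, int]:
        return {
            _seq.code_to_kmer(int(c), self.k): int(n)
            for c, n in zip(self.codes, self.counts)
        }

    def lookup_codes(self, query: np.ndarray) -> np.ndarray:
        """Vectorised counts for an array of canonical codes (0 if absent)."""
        idx = np.searchsorted(self.codes, query)
        idx_c = np.clip(idx, 0, max(len(self.codes) - 1, 0))
        if len(self.codes) == 0:
            return np.zeros(len(query), dtype=np.int64)
        hit = self.codes[idx_c] == query
        return np.where(hit, self.counts[idx_c], 0)

    def member_codes(self, query: np.ndarray) -> np.ndarray:
        return self.lookup_codes(query) > 0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\n")
            for c, n in zip(self.codes, self.counts):
                fh.write(f"{_seq.code_to_kmer(int(c), self.k)}\t{int(n)}\n")

    @classmethod
    def from_tsv(cls, path, source: str = "") -> "KmerTable":
        k = None
        codes, counts = [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    if line.startswith("#k="):
                        k = int(line[3:])
                    continue
                kmer, n = line.split("\t")
                if k is None:
                    k = len(kmer)
                codes.append(_seq.kmer_to_code(_seq.canonical(kmer)))
                counts.append(int(n))
        if k is None:
            raise ValueError(f"no k-mers and no #k= header in {path}")
        codes_a, counts_a = _seq.aggregate_codes(
            np.asarray(codes, dtype=np.int64), np.asarray(counts, dtype=np.int64)
        )
        return cls(k=k, codes=codes_a, counts=counts_a, source=source)


def _iter_sequences(sequences) -> Iterable[str]:
    """Accept a FASTA/FASTQ path, an iterable of strings, or (id, seq) pairs."""
    import os

    if isinstance(sequences, (str, os.PathLike)):
        from Bio import SeqIO

        path = str(sequences)
        fmt = "fastq" if path.endswith((".fq", ".fastq")) else "fasta"
        for rec in SeqIO.parse(path, fmt):
            yield str(rec.seq)
        return
    for item in sequences:
        if isinstance(item, str):
            yield item
        else:  # (id, seq) pair
            yield item[1]


def count_kmers(
    sequences,
    k: int = DEFAULT_K,
    source: str = "",
    chunk_bases: int = 20_000_000,
) -> KmerTable:
    """Count canonical k-mers of FASTA/FASTQ input or in-memory sequences.

    k-mers covering an ambiguous base are skipped. Sequences are
    concatenated with a sentinel and processed in chunks so read sets of
    tens of millions of bases stay within memory.
    """
    parts_codes: list[np.ndarray] = []
    parts_counts: list[np.ndarray] = []
    buf: list[str] = []
    buf_len = 0

    def _flush() -> None:
        nonlocal buf, buf_len
        if not buf:
            return
        blob = "N".join(buf)
        enc = _seq.encode(blob)
        codes, valid = _seq.kmer_codes(enc, k)
        codes = codes[valid]
        if codes.size:
            u, c = _seq.aggregate_codes(codes)
            parts_codes.append(u)
            parts_counts.append(c)
        buf, buf_len = [], 0

    n_seqs = 0
    for seq in _iter_sequences(sequences):
        n_seqs += 1
        buf.append(seq)
        buf_len += len(seq)
        if buf_len >= chunk_bases:
            _flush()
    _flush()

    if n_seqs == 0:
        warnings.warn("empty input: returning an empty k-mer table")
    if not parts_codes:
        return KmerTable(k=k, codes=np.empty(0, np.int64), counts=np.empty(0, np.int64), source=source)
    codes = np.concatenate(parts_codes)
    counts = np.concatenate(parts_counts)
    codes, counts = _seq.aggregate_codes(codes, counts)
    return KmerTable(k=k, codes=codes, counts=counts, source=source)


@dataclass
class KmerSet:
    """A set of canonical k-mers as sorted packed codes."""

    k: int
    codes: np.ndarray

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, kmer: str) -> bool:
        code = _seq.kmer_to_code(_seq.canonical(kmer))
        i = np.searchsorted(self.codes, code)
        return bool(i < len(self.codes) and self.codes[i] == code)

    def to_strings(self) -> set[str]:
        return {_seq.code_to_kmer(int(c), self.k) for c in self.codes}

    def member_codes(self, query: np.ndarray) -> np.ndarray:
        if len(self.codes) == 0:
            return np.zeros(len(query), dtype=bool)
        idx = np.clip(np.searchsorted(self.codes, query), 0, len(self.codes) - 1)
        return self.codes[idx] == query


def sex_specific_kmers(same: KmerTable, opposite: KmerTable, min_count: int = 2) -> KmerSet:
    """k-mers with same-sex count >= min_count and opposite-sex count 0.

    These are the "null ratio" k-mers; the noise floor absorbs
    sequencing-error singletons in the same-sex read set.
    """
    if same.k != opposite.k:
        raise ValueError(f"k mismatch: {same.k} vs {opposite.k}")
    keep = same.counts >= min_count
    cand = same.codes[keep]
    absent = ~opposite.member_codes(cand)
    return KmerSet(k=same.k, codes=cand[absent])


@dataclass
class WindowStat:
    """Per-window k-mer statistics (0-based half-open coordinates)."""

    scaffold: str
    start: int
    end: int
    awk: float | None
    kq: float | None
    ygs_pct: float | None
    n_kmers: int
    flags: dict[str, bool] = field(default_factory=dict)


def _window_kmer_stats(
    uniq: np.ndarray,
    length: int,
    specific: KmerSet,
    same_reads: KmerTable,
    opp_reads: KmerTable,
    opp_asm: KmerTable,
) -> tuple[float | None, float | None, float | None, int]:
    n = len(uniq)
    if n == 0:
        return None, None, None, 0
    awk = float(specific.member_codes(uniq).sum()) / (length / 1000.0)
    same_c = same_reads.lookup_codes(uniq)
    opp_c = opp_reads.lookup_codes(uniq)
    shared = (same_c > 0) & (opp_c > 0)
    if shared.any() and same_reads.total > 0 and opp_reads.total > 0:
        num = same_c[shared].sum() / same_reads.total
        den = opp_c[shared].sum() / opp_reads.total
        kq = float(num / den) if den > 0 else None
    else:
        kq = None
    unmatched = ~opp_asm.member_codes(uniq)
    ygs = 100.0 * float(unmatched.sum()) / n
    return awk, kq, ygs, n


def _apply_flags(ws: WindowStat, cutoffs: dict[str, float]) -> None:
    ws.flags = {
        "awk": ws.awk is not None and ws.awk >= cutoffs["awk"],
        "kq": ws.kq is not None and ws.kq >= cutoffs["kq"],
        "ygs": ws.ygs_pct is not None and ws.ygs_pct >= cutoffs["ygs"],
    }


def window_stats(
    assembly,
    same_reads: KmerTable,
    opp_reads: KmerTable,
    opp_asm: KmerTable,
    width: int = DEFAULT_WINDOW,
    min_count: int = 2,
    cutoffs: dict[str, float] | None = None,
) -> list[WindowStat]:
    """AWK / KQ / YGS% over fixed windows of an assembly.

    ``assembly`` is a FASTA path or iterable of (id, sequence) pairs. All
    k-mer tables must share k; a k-mer is assigned to the window holding
    its start position. Windows without a single valid k-mer report every
    statistic as missing.
    """
    k = same_reads.k
    if not (opp_reads.k == k and opp_asm.k == k):
        raise ValueError("all k-mer tables must share k")
    if width < k:
        raise ValueError(f"window width {width} < k {k}")
    cutoffs = {**DEFAULT_CUTOFFS, **(cutoffs or {})}
    specific = sex_specific_kmers(same_reads, opp_reads, min_count=min_count)

    import os

    if isinstance(assembly, (str, os.PathLike)):
        records = _seq.read_fasta(assembly)
    else:
        records = list(assembly)

    out: list[WindowStat] = []
    for name, seq in records:
        enc = _seq.encode(seq)
        codes, valid = _seq.kmer_codes(enc, k)
        L = len(seq)
        for start in range(0, L, width):
            end = min(start + width, L)
            lo, hi = start, min(end, L - k + 1)
            if hi > lo:
                v = valid[lo:hi]
                uniq = np.unique(codes[lo:hi][v])
            else:
                uniq = np.empty(0, dtype=np.int64)
            awk, kq, ygs, n = _window_kmer_stats(
                uniq, end - start, specific, same_reads, opp_reads, opp_asm
            )
            ws = WindowStat(name, start, end, awk, kq, ygs, n)
            _apply_flags(ws, cutoffs)
            out.append(ws)
    return out


@dataclass
class ContigStat:
    scaffold: str
    mean_awk: float | None
    median_kq: float | None
    ygs_pct: float | None
    n_kmers: int
    flags: dict[str, bool] = field(default_factory=dict)


def contig_stats(
    windows: Sequence[WindowStat],
    assembly=None,
    opp_asm: KmerTable | None = None,
    cutoffs: dict[str, float] | None = None,
) -> list[ContigStat]:
    """Aggregate window statistics to whole contigs.

    Contig YGS% is recomputed over the union of the contig's distinct
    k-mers when the assembly and opposite-sex table are supplied (the
    correct aggregation — not a mean of window percentages); otherwise a
    distinct-k-mer-count weighted mean of window values is used as an
    approximation.
    """
    cutoffs = {**DEFAULT_CUTOFFS, **(cutoffs or {})}
    by_scaf: dict[str, list[WindowStat]] = {}
    for w in windows:
        by_scaf.setdefault(w.scaffold, []).append(w)

    seqs: dict[str, str] = {}
    if assembly is not None:
        import os

        records = _seq.read_fasta(assembly) if isinstance(assembly, (str, os.PathLike)) else assembly
        seqs = dict(records)

    out = []
    for name, ws_list in by_scaf.items():
        awks = [w.awk for w in ws_list if w.awk is not None]
        kqs = [w.kq for w in ws_list if w.kq is not None]
        mean_awk = float(np.mean(awks)) if awks else None
        median_kq = float(np.median(kqs)) if kqs else None
        if name in seqs and opp_asm is not None:
            enc = _seq.encode(seqs[name])
            codes, valid = _seq.kmer_codes(enc, opp_asm.k)
            uniq = np.unique(codes[valid])
            n = len(uniq)
            ygs = 100.0 * float((~opp_asm.member_codes(uniq)).sum()) / n if n else None
        else:
            pairs = [(w.ygs_pct, w.n_kmers) for w in ws_list if w.ygs_pct is not None]
            n = sum(nk for _, nk in pairs)
            ygs = (sum(y * nk for y, nk in pairs) / n) if n else None
        cs = ContigStat(name, mean_awk, median_kq, ygs, n)
        cs.flags = {
            "awk": mean_awk is not None and mean_awk >= cutoffs["awk"],
            "kq": median_kq is not None and median_kq >= cutoffs["kq"],
            "ygs": ygs is not None and ygs >= cutoffs["ygs"],
        }
        out.append(cs)
    return out


def windows_to_tsv(windows: Sequence[WindowStat], path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tstart\tend\tawk\tkq\tygs_pct\tn_kmers\tflag_awk\tflag_kq\tflag_ygs\n")
        for w in windows:
            fmt = lambda v: "NA" if v is None else f"{v:.6g}"
            fh.write(
                f"{w.scaffold}\t{w.start}\t{w.end}\t{fmt(w.awk)}\t{fmt(w.kq)}\t"
                f"{fmt(w.ygs_pct)}\t{w.n_kmers}\t"
                f"{int(w.flags.get('awk', False))}\t{int(w.flags.get('kq', False))}\t"
                f"{int(w.flags.get('ygs', False))}\n"
            )


def windows_from_tsv(path) -> list[WindowStat]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            num = lambda s: None if s == "NA" else float(s)
            ws = WindowStat(f[0], int(f[1]), int(f[2]), num(f[3]), num(f[4]), num(f[5]), int(f[6]))
            ws.flags = {"awk": f[7] == "1", "kq": f[8] == "1", "ygs": f[9] == "1"}
            out.append(ws)
    return out
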