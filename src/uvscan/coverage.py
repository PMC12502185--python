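"""Read-depth based sex-linkage classification.

A contig (or window) of a focal assembly is called sex-linked when the
same-sex read depth lies within a band around the genome-wide median
(default +/-25%) while the opposite-sex depth falls below a fraction of
its genome-wide median (default 80%, strict inequality). Hemizygous
sex-determining regions satisfy both; collapsed repeats and low-quality
sequence fail the same-sex band.

Depth can be loaded from a bedGraph/TSV track produced by any aligner,
or estimated alignment-free from a read k-mer table
(:func:`depth_from_kmer_counts`).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmers import KmerTable, WindowStat, DEFAULT_WINDOW
from . import _seq


@dataclass
class DepthTrack:
    """Per-window mean depth for one read set over one assembly."""

    source_sex: str
    window: int
    scaffolds: dict[str, np.ndarray]  # scaffold -> per-window mean depth

    @property
    def genome_wide_median(self) -> float:
        allv = np.concatenate([v for v in self.scaffolds.values()])
        return float(np.median(allv))

    def windows(self):
        for name, depths in self.scaffolds.items():
            for i, d in enumerate(depths):
                yield name, i * self.window, float(d)


@dataclass
class CoverageCall:
    unit: str  # contig name or "scaffold:start-end"
    same_ok: bool
    opp_ok: bool

    @property
    def flagged(self) -> bool:
        return self.same_ok and self.opp_ok


def load_depth(path, window: int = DEFAULT_WINDOW, source_sex: str = "") -> DepthTrack:
    """Load a bedGraph (``scaffold start end depth``, 0-based half-open)
    or 4-column TSV into per-window base-weighted mean depths.

    Intervals must be sorted and non-overlapping within a scaffold.
    """
    per_scaf: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split()
            scaf, start, end, depth = f[0], int(f[1]), int(f[2]), float(f[3])
            ivs = per_scaf.setdefault(scaf, [])
            if ivs and start < ivs[-1][1]:
                raise ValueError(
                    f"overlapping/unsorted intervals on {scaf} at {start}"
                )
            ivs.append((start, end, depth))
    if not per_scaf:
        raise ValueError(f"empty depth track: {path}")

    scaffolds: dict[str, np.ndarray] = {}
    for scaf, ivs in per_scaf.items():
        length = ivs[-1][1]
        n_win = (length + window - 1) // window
        acc = np.zeros(n_win)
        cov = np.zeros(n_win)
        for start, end, depth in ivs:
            pos = start
            while pos < end:
                w = pos // window
                stop = min(end, (w + 1) * window)
                acc[w] += depth * (stop - pos)
                cov[w] += stop - pos
                pos = stop
        with np.errstate(invalid="ignore"):
            scaffolds[scaf] = np.where(cov > 0, acc / np.maximum(cov, 1), 0.0)
    return DepthTrack(source_sex=source_sex, window=window, scaffolds=scaffolds)


def depth_from_kmer_counts(
    assembly,
    reads: KmerTable,
    read_len: int,
    window: int = DEFAULT_WINDOW,
    source_sex: str = "",
) -> DepthTrack:
    """Alignment-free depth estimate from a read k-mer table.

    The expected read-set multiplicity of a genomic k-mer at depth D is
    D * (read_len - k + 1) / read_len, so the per-window mean k-mer count
    rescaled by read_len / (read_len - k + 1) estimates the mean depth.
    Repeat-induced multi-mapping inflates repeated windows exactly as it
    would an aligner's raw depth.
    """
    import os

    k = reads.k
    records = (
        _seq.read_fasta(assembly)
        if isinstance(assembly, (str, os.PathLike))
        else list(assembly)
    )
    scale = read_len / max(read_len - k + 1, 1)
    scaffolds: dict[str, np.ndarray] = {}
    for name, seq in records:
        enc = _seq.encode(seq)
        codes, valid = _seq.kmer_codes(enc, k)
        counts = reads.lookup_codes(codes).astype(np.float64)
        counts[~valid] = np.nan
        L = len(seq)
        n_win = (L + window - 1) // window
        means = np.full(n_win, 0.0)
        for w in range(n_win):
            lo = w * window
            hi = min((w + 1) * window, L - k + 1)
            if hi > lo:
                sl = counts[lo:hi]
                ok = ~np.isnan(sl)
                means[w] = float(sl[ok].mean()) * scale if ok.any() else 0.0
        scaffolds[name] = means
    return DepthTrack(source_sex=source_sex, window=window, scaffolds=scaffolds)


def classify_coverage(
    same: DepthTrack,
    opp: DepthTrack,
    band: float = 0.25,
    opp_frac: float = 0.80,
    opp_median: str = "own",
) -> tuple[dict[str, CoverageCall], list[tuple[str, int, int, CoverageCall]]]:
    """Apply the median-based coverage rule per contig and per window.

    same_ok: contig median same-sex depth within ``band`` of the same
    track's genome-wide median (inclusive band). opp_ok: contig median
    opposite-sex depth strictly below ``opp_frac`` times the reference
    median, which is the opposite track's own genome-wide median by
    default (``opp_median='own'``) or the same-sex one
    (``opp_median='same'``).

    Returns (per-contig calls, per-window calls).
    """
    if set(same.scaffolds) != set(opp.scaffolds):
        raise ValueError("tracks cover different scaffolds")
    if same.window != opp.window:
        raise ValueError("tracks use different window sizes")
    m_same = same.genome_wide_median
    if m_same <= 0:
        raise ValueError("degenerate same-sex library: zero median depth")
    m_ref = opp.genome_wide_median if opp_median == "own" else m_same
    lo, hi = (1 - band) * m_same, (1 + band) * m_same
    opp_cut = opp_frac * m_ref

    contig_calls: dict[str, CoverageCall] = {}
    window_calls: list[tuple[str, int, int, CoverageCall]] = []
    for scaf in same.scaffolds:
        sd = same.scaffolds[scaf]
        od = opp.scaffolds[scaf]
        if len(sd) != len(od):
            raise ValueError(f"window count mismatch on {scaf}")
        cs = float(np.median(sd))
        co = float(np.median(od))
        contig_calls[scaf] = CoverageCall(scaf, lo <= cs <= hi, co < opp_cut)
        w = same.window
        for i in range(len(sd)):
            call = CoverageCall(
                f"{scaf}:{i * w}-{(i + 1) * w}",
                lo <= float(sd[i]) <= hi,
                float(od[i]) < opp_cut,
            )
            window_calls.append((scaf, i * w, (i + 1) * w, call))
    return contig_calls, window_calls


def calls_to_tsv(contig_calls: dict[str, CoverageCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("unit\tsame_ok\topp_ok\tflagged\n")
        for name, c in contig_calls.items():
            fh.write(f"{name}\t{int(c.same_ok)}\t{int(c.opp_ok)}\t{int(c.flagged)}\n")
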