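"""Consensus SDR calling and in-silico PCR marker validation.

Four independent detectors vote on every unit (window or contig):
read-coverage rule, AWK, KQ and YGS. Units supported by at least three
of the four are retained; consecutive retained windows are merged into
sex-determining-region (SDR) intervals, the remainder of a sex scaffold
is labelled pseudoautosomal (PAR) and scaffolds without any retained run
are autosomal.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .kmers import WindowStat
from .coverage import CoverageCall
from ._seq import revcomp

METHODS = ("coverage", "awk", "kq", "ygs")


@dataclass
class MethodVotes:
    unit: str
    votes: dict[str, bool]

    def __post_init__(self) -> None:
        # a method undefined on a unit counts as a false vote, recorded
        self.votes = {m: bool(self.votes.get(m, False)) for m in METHODS}

    @property
    def n_votes(self) -> int:
        return sum(self.votes.values())


def consensus(votes: MethodVotes, min_methods: int = 3) -> bool:
    """Retain a unit as sex-linked when >= min_methods detectors agree."""
    if not 1 <= min_methods <= 4:
        raise ValueError(f"min_methods must be in [1, 4], got {min_methods}")
    return votes.n_votes >= min_methods


def combine_window_votes(
    windows: list[WindowStat],
    window_calls: list[tuple[str, int, int, CoverageCall]],
) -> list[tuple[str, int, int, MethodVotes]]:
    """Join k-mer window flags with coverage window calls on coordinates."""
    cov = {(s, a): c for s, a, b, c in window_calls}
    out = []
    for w in windows:
        call = cov.get((w.scaffold, w.start))
        votes = dict(w.flags)
        votes["coverage"] = call.flagged if call is not None else False
        out.append(
            (w.scaffold, w.start, w.end, MethodVotes(f"{w.scaffold}:{w.start}-{w.end}", votes))
        )
    return out


@dataclass
class Interval:
    start: int
    end: int
    label: str  # V-SDR | U-SDR | PAR | autosome
    n_windows: int = 0


@dataclass
class SdrPartition:
    """Ordered labelled intervals tiling each scaffold."""

    assembly_sex: str  # "male" or "female"
    scaffolds: dict[str, list[Interval]] = field(default_factory=dict)

    @property
    def sdr_label(self) -> str:
        return "V-SDR" if self.assembly_sex == "male" else "U-SDR"

    def sdr_intervals(self, scaffold: str | None = None) -> list[tuple[str, int, int]]:
        out = []
        for name, ivs in self.scaffolds.items():
            if scaffold is not None and name != scaffold:
                continue
            out += [(name, iv.start, iv.end) for iv in ivs if iv.label.endswith("SDR")]
        return out

    def region_of(self, scaffold: str, pos: int) -> str:
        for iv in self.scaffolds.get(scaffold, []):
            if iv.start <= pos < iv.end:
                return iv.label
        raise KeyError(f"{scaffold}:{pos} outside partition")

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for name, ivs in self.scaffolds.items():
                for iv in ivs:
                    fh.write(f"{name}\t{iv.start}\t{iv.end}\t{iv.label}\n")

    @classmethod
    def from_bed(cls, path, assembly_sex: str = "male") -> "SdrPartition":
        part = cls(assembly_sex=assembly_sex)
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.split()
                part.scaffolds.setdefault(f[0], []).append(
                    Interval(int(f[1]), int(f[2]), f[3])
                )
        for ivs in part.scaffolds.values():
            ivs.sort(key=lambda iv: iv.start)
        return part


def call_sdr_intervals(
    voted_windows: list[tuple[str, int, int, MethodVotes]],
    scaffold_lengths: dict[str, int],
    min_methods: int = 3,
    gap_tol: int = 5,
    min_run: int = 3,
    assembly_sex: str = "male",
) -> SdrPartition:
    """Merge consensus-retained windows into SDR intervals.

    Runs of retained windows separated by gaps of <= gap_tol windows are
    bridged; merged runs spanning < min_run windows are dropped. On
    scaffolds with a surviving SDR interval the flanks are labelled PAR;
    scaffolds without one are autosome end to end.
    """
    part = SdrPartition(assembly_sex=assembly_sex)
    sdr_label = part.sdr_label

    by_scaf: dict[str, list[tuple[int, int, MethodVotes]]] = {}
    for scaf, start, end, votes in voted_windows:
        by_scaf.setdefault(scaf, []).append((start, end, votes))
    for scaf, rows in by_scaf.items():
        if rows != sorted(rows, key=lambda r: r[0]):
            raise ValueError(f"windows on {scaf} are not sorted by start")

    for scaf, length in scaffold_lengths.items():
        rows = by_scaf.get(scaf, [])
        retained = [
            (start, end) for start, end, v in rows if consensus(v, min_methods)
        ]
        # merge retained windows, bridging gaps of <= gap_tol windows
        width = rows[0][1] - rows[0][0] if rows else 1
        merged: list[list[int]] = []  # [start, end, n_windows]
        for start, end in retained:
            if merged and (start - merged[-1][1]) <= gap_tol * width:
                merged[-1][1] = end
                merged[-1][2] += 1
            else:
                merged.append([start, end, 1])
        kept = [m for m in merged if m[2] >= min_run]

        ivs: list[Interval] = []
        if not kept:
            ivs.append(Interval(0, length, "autosome"))
        else:
            pos = 0
            for start, end, n in kept:
                if start > pos:
                    ivs.append(Interval(pos, start, "PAR"))
                ivs.append(Interval(start, min(end, length), sdr_label, n_windows=n))
                pos = min(end, length)
            if pos < length:
                ivs.append(Interval(pos, length, "PAR"))
        part.scaffolds[scaf] = ivs
    return part


@dataclass
class PrimerPair:
    forward: str
    reverse: str
    size_min: int
    size_max: int
    target_sex: str = ""

    def __post_init__(self) -> None:
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()
        if min(len(self.forward), len(self.reverse)) < 15:
            raise ValueError("primers must be >= 15 bp")
        if self.size_min > self.size_max:
            raise ValueError("product size range inverted")
        for p in (self.forward, self.reverse):
            if set(p) - set("ACGT"):
                raise ValueError(f"primer {p} contains non-ACGT bases")


def _find_amplicons(primers: PrimerPair, seq: str) -> list[int]:
    """Exact-match amplicon sizes on both orientations of one sequence."""
    sizes = []
    for template in (seq, revcomp(seq)):
        fwd, rev_rc = primers.forward, revcomp(primers.reverse)
        i = template.find(fwd)
        while i != -1:
            j = template.find(rev_rc, i + len(fwd))
            while j != -1:
                size = j + len(rev_rc) - i
                if size > primers.size_max:
                    break
                if size >= primers.size_min:
                    sizes.append(size)
                j = template.find(rev_rc, j + 1)
            i = template.find(fwd, i + 1)
    return sizes


def insilico_pcr(primers: PrimerPair, male, female) -> dict:
    """Classify a primer pair by exact-match amplification in each genome.

    ``male``/``female`` are FASTA paths or (id, sequence) iterables.
    Returns {"call": male_specific|female_specific|both|none,
    "ambiguous": bool, "male_products": [...], "female_products": [...]}.
    """
    import os
    from . import _seq

    def _amps(genome):
        records = (
            _seq.read_fasta(genome)
            if isinstance(genome, (str, os.PathLike))
            else genome
        )
        sizes = []
        for _, seq in records:
            sizes += _find_amplicons(primers, seq.upper())
        return sizes

    m, f = _amps(male), _amps(female)
    if m and f:
        call = "both"
    elif m:
        call = "male_specific"
    elif f:
        call = "female_specific"
    else:
        call = "none"
    return {
        "call": call,
        "ambiguous": len(m) > 1 or len(f) > 1,
        "male_products": m,
        "female_products": f,
    }
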