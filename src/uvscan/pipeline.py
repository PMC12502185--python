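"""End-to-end convenience: simulation -> detectors -> consensus partition.

Wires the simulator output through k-mer counting, the window
statistics, the coverage rule and the consensus caller, returning
everything a downstream analysis needs. This is what the CLI commands
compose step by step and what the test-bench runs in one call.
"""
from __future__ import annotations

from dataclasses import dataclass

from .coverage import classify_coverage, depth_from_kmer_counts
from .kmers import KmerTable, WindowStat, count_kmers, window_stats
from .sdrcall import SdrPartition, call_sdr_intervals, combine_window_votes
from .simulate import SimParams, SimResult, simulate_genome_pair, simulate_reads


@dataclass
class DetectionResult:
    sim: SimResult
    windows: list[WindowStat]
    partition: SdrPartition
    same_reads_table: KmerTable
    opp_reads_table: KmerTable
    opp_asm_table: KmerTable


def run_detection(
    params: SimParams | None = None,
    sim: SimResult | None = None,
    focal_sex: str = "male",
    k: int = 15,
    window: int = 1000,
    min_methods: int = 3,
    gap_tol: int = 5,
    min_run: int = 3,
) -> DetectionResult:
    """Simulate (unless given) and run the full SDR detection pipeline
    on the focal sex's assembly."""
    if sim is None:
        sim = simulate_genome_pair(params or SimParams())
    p = sim.params
    focal = sim.male if focal_sex == "male" else sim.female
    other = sim.female if focal_sex == "male" else sim.male
    same_reads = simulate_reads(focal, p.read_depth, p.read_len, p.err_rate, p.seed + 11)
    opp_reads = simulate_reads(other, p.read_depth, p.read_len, p.err_rate, p.seed + 12)

    same_tab = count_kmers(same_reads, k, source=f"{focal_sex}_reads")
    opp_tab = count_kmers(opp_reads, k, source="opp_reads")
    opp_asm_tab = count_kmers(other, k, source="opp_asm")

    ws = window_stats(focal, same_tab, opp_tab, opp_asm_tab, width=window)
    same_depth = depth_from_kmer_counts(focal, same_tab, p.read_len, window=window,
                                        source_sex=focal_sex)
    opp_depth = depth_from_kmer_counts(focal, opp_tab, p.read_len, window=window)
    _, win_calls = classify_coverage(same_depth, opp_depth)
    voted = combine_window_votes(ws, win_calls)
    part = call_sdr_intervals(
        voted,
        sim.scaffold_lengths(focal_sex),
        min_methods=min_methods,
        gap_tol=gap_tol,
        min_run=min_run,
        assembly_sex=focal_sex,
    )
    return DetectionResult(sim, ws, part, same_tab, opp_tab, opp_asm_tab)


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard overlap of two half-open intervals."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 1.0
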