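"""Alignment, reciprocal best hits, NG86 counting and the strata scan."""
from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uvscan.gametologs import (
    GametologPair,
    SENSE_CODONS,
    _CODON_AA,
    _STOPS,
    classify_sdr_genes,
    codon_align,
    jukes_cantor,
    local_align,
    make_aligner,
    ng86,
    rbh_pairs,
    strata_scan,
    translate,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


# ------------------------------------------------- independent DP oracle

def sw_gotoh_oracle(a, b, score, gap_open, gap_extend):
    """Plain-Python Smith-Waterman-Gotoh best local score."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (left)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (up)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            diag = H[i - 1][j - 1] + score(a[i - 1], b[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestLocalAlign:
    def test_self_alignment_sums_diagonal(self):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        s = "MKVLANQWERTY"
        score, _ = local_align(s, s)
        assert score == sum(blosum[c, c] for c in s)

    def test_simple_match_mismatch_scores(self):
        aligner = make_aligner(matrix=None, match=2, mismatch=-1, gap_open=-2, gap_extend=-2)
        score, _ = local_align("ACGT", "ACGT", aligner)
        assert score == 8

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "MKV")

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_matches_dp_oracle_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list(AA), size=30))
        b = "".join(rng.choice(list(AA), size=30))
        aligner = make_aligner(gap_open=-5, gap_extend=-1)
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        expected = sw_gotoh_oracle(a, b, lambda x, y: blosum[x, y], -5.0, -1.0)
        assert aligner.score(a, b) == pytest.approx(expected)


class TestRbh:
    def _mutate(self, s, rng, n):
        s = list(s)
        for i in rng.choice(len(s), size=n, replace=False):
            s[i] = rng.choice(list(AA))
        return "".join(s)

    def test_identical_proteomes_pair_up(self, rng):
        prots = {
            f"P{i}": "".join(rng.choice(list(AA), size=80)) for i in range(3)
        }
        male = prots
        female = {f"{k}f": v for k, v in prots.items()}
        pairs, ties = rbh_pairs(male, female)
        assert sorted(pairs) == [("P0", "P0f"), ("P1", "P1f"), ("P2", "P2f")]
        assert not ties

    def test_reciprocity_required(self, rng):
        base = "".join(rng.choice(list(AA), size=80))
        # A's best is B1, but B1 prefers A2 (closer to it)
        b1 = self._mutate(base, rng, 8)
        a = self._mutate(b1, rng, 6)
        a2 = self._mutate(b1, rng, 2)
        pairs, _ = rbh_pairs({"A": a, "A2": a2}, {"B1": b1})
        assert pairs == [("A2", "B1")]

    def test_equal_best_scores_break_to_no_pair(self, rng):
        p = "".join(rng.choice(list(AA), size=60))
        q = "".join(rng.choice(list(AA), size=60))
        pairs, ties = rbh_pairs({"A": p}, {"B1": p, "B2": p})
        assert pairs == [] and "A" in ties
        # the unambiguous other protein still pairs in a mixed set
        pairs2, _ = rbh_pairs({"A": p, "C": q}, {"B1": p, "B2": p, "Cf": q})
        assert pairs2 == [("C", "Cf")]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            rbh_pairs([("A", "MKVMKV"), ("A", "MKVMKV")], {"B": "MKVMKV"})

    def test_symmetry_under_swap(self, rng):
        male = {f"M{i}": "".join(rng.choice(list(AA), size=60)) for i in range(4)}
        female = {f"F{i}": self._mutate(male[f"M{i}"], rng, 5) for i in range(4)}
        ab, _ = rbh_pairs(male, female)
        ba, _ = rbh_pairs(female, male)
        assert {(m, f) for m, f in ab} == {(m, f) for f, m in ba}


class TestCodonAlign:
    def test_gap_free_pair_keeps_all_codons(self):
        cds = "ATGGCTAAACGT"
        _, aln = local_align(translate(cds), translate(cds))
        a, b = codon_align(cds, cds, aln)
        assert a == b == cds

    def test_gap_columns_removed(self):
        # M A A A A K R W D E vs the same protein missing two alanines;
        # mild gap costs keep the flanks aligned around the 2-column gap
        cds_a = "ATGGCTGCAGCTGCAAAACGTTGGGATGAA"
        cds_b = "ATGGCTGCAAAACGTTGGGATGAA"
        aligner = make_aligner(matrix=None, match=5, mismatch=-4, gap_open=-2, gap_extend=-1)
        _, aln = local_align(translate(cds_a), translate(cds_b), aligner)
        a, b = codon_align(cds_a, cds_b, aln)
        assert len(a) == len(b) == len(cds_b)
        assert translate(a) == translate(b) == "MAAKRWDE"

    def test_retranslation_matches_gapless_alignment(self, rng):
        codons = [c for c in SENSE_CODONS if c != "ATG"]
        cds_a = "ATG" + "".join(rng.choice(codons, size=40))
        cds_b = list(cds_a)
        for i in rng.choice(range(3, len(cds_a)), size=10, replace=False):
            cds_b[i] = rng.choice(list("ACGT"))
        cds_b = "".join(cds_b)
        try:
            prot_b = translate(cds_b)
        except ValueError:
            return  # random edit introduced a stop; nothing to test
        _, aln = local_align(translate(cds_a), prot_b)
        a, b = codon_align(cds_a, cds_b, aln)
        assert len(a) == len(b) and len(a) % 3 == 0
        assert translate(a) in translate(cds_a)

    def test_internal_stop_rejected(self):
        cds = "ATGTAAGCT"
        with pytest.raises(ValueError):
            _, aln = local_align("MA", "MA")
            codon_align(cds, "ATGGCTGCT", aln)


# --------------------------------------------- NG86 brute-force oracle

def oracle_sites(codon):
    """Site counts by explicit enumeration of the 9 point mutations."""
    syn = 0
    for pos, base in itertools.product(range(3), "ACGT"):
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1 :]
        if alt not in _STOPS and _CODON_AA[alt] == _CODON_AA[codon]:
            syn += 1
    return syn / 3, 3 - syn / 3


def oracle_paths(c1, c2):
    """Pathway counts by explicit recursion over mutation orders."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    results = []

    def walk(cur, remaining, sd, nd):
        if not remaining:
            results.append((sd, nd))
            return
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                continue
            step_syn = _CODON_AA[cur] == _CODON_AA[nxt]
            walk(nxt, [p for p in remaining if p != pos], sd + step_syn, nd + (not step_syn))

    walk(c1, diffs, 0, 0)
    if not results:
        return len(diffs) / 2, len(diffs) / 2
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


class TestNg86:
    def test_identical_sequences(self):
        r = ng86("ATGGCTAAACGTTGGGCTAAACGTTGGGCT", "ATGGCTAAACGTTGGGCTAAACGTTGGGCT")
        assert r.Ks == 0 and r.Kn == 0 and not r.saturated

    def test_worked_two_codon_example(self):
        with pytest.warns(UserWarning):
            r = ng86("GCTGCA", "GCCGCA")
        assert r.S == pytest.approx(2.0)
        assert r.N == pytest.approx(4.0)
        assert r.Sd == pytest.approx(1.0)
        assert r.Nd == pytest.approx(0.0)
        assert r.pS == pytest.approx(0.5)
        assert r.Ks == pytest.approx(-0.75 * math.log(1 / 3), abs=1e-4)
        assert r.Kn == 0

    def test_saturation_flagged(self):
        # alanine codons differing at every third position: pS = 1
        a = "GCT" * 20
        b = "GCC" * 20
        r = ng86(a, b)
        assert r.pS == pytest.approx(1.0)
        assert r.saturated and r.Ks is None and r.omega is None

    def test_site_conservation_all_sense_codons(self):
        from uvscan.gametologs import _codon_sites

        for c in SENSE_CODONS:
            s, n = _codon_sites(c)
            assert s + n == pytest.approx(3.0)
            os, on = oracle_sites(c)
            assert s == pytest.approx(os)

    def test_pathway_counts_match_oracle_over_all_pairs(self):
        """Exhaustive check of every 61 x 61 sense-codon pair."""
        from uvscan.gametologs import _codon_path_counts

        for c1 in SENSE_CODONS:
            for c2 in SENSE_CODONS:
                sd, nd = _codon_path_counts(c1, c2)
                osd, ond = oracle_paths(c1, c2)
                assert sd == pytest.approx(osd), (c1, c2)
                assert nd == pytest.approx(ond), (c1, c2)
                ndiff = sum(x != y for x, y in zip(c1, c2))
                assert sd + nd == pytest.approx(ndiff)

    def test_agrees_with_biopython_on_clean_pairs(self, rng):
        """Independent cross-check against Bio.codonalign's NG86."""
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        for _ in range(5):
            codons = [c for c in SENSE_CODONS]
            a = "".join(rng.choice(codons, size=60))
            b_l = [
                rng.choice(codons) if rng.random() < 0.1 else c
                for c in (a[i : i + 3] for i in range(0, len(a), 3))
            ]
            b = "".join(b_l)
            r = ng86(a, b)
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            # conventions differ slightly (treatment of mutations to stop
            # codons in site counting), so agreement is approximate
            if r.Kn is not None:
                assert r.Kn == pytest.approx(dn, abs=0.015)
            if r.Ks is not None and ds >= 0:
                assert r.Ks == pytest.approx(ds, abs=0.015)

    def test_jukes_cantor_saturation_boundary(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.75) is None
        with pytest.raises(ValueError):
            jukes_cantor(-0.1)


class TestKsRecovery:
    @pytest.mark.parametrize("target", [0.05, 0.2, 0.5])
    def test_simulated_gametologs_recover_target(self, target, rng):
        """Planted synonymous divergence is re-estimated within 15%."""
        from uvscan.simulate import _make_cds, diverge_synonymous

        estimates = []
        for i in range(11):
            cds = _make_cds(np.random.default_rng(1000 + i), 320)
            partner = diverge_synonymous(cds, target, np.random.default_rng(2000 + i))
            body = slice(3, len(cds) - 3)  # trim start/stop codons
            r = ng86(cds[body], partner[body])
            assert r.Ks is not None
            estimates.append(r.Ks)
        med = float(np.median(estimates))
        assert med == pytest.approx(target, rel=0.15)


class TestClassification:
    def test_three_way_classification(self):
        out = classify_sdr_genes(
            sdr_m=["m1", "m2", "m3"],
            sdr_f=["f1"],
            rbh=[("m1", "f1"), ("m2", "fX")],
            self_hits={"m2": "auto7", "m3": None, "f1": None},
        )
        classes = {r.gene_id: r.gene_class for r in out}
        assert classes["m1"] == "gametolog"
        assert classes["m2"] == "sex_limited_with_autosomal_paralog"
        assert classes["m3"] == "sex_limited_orphan"
        assert classes["f1"] == "gametolog"

    def test_missing_proteome_entry_rejected(self):
        with pytest.raises(ValueError):
            classify_sdr_genes(["m1"], [], [], {}, proteome_ids={"other"})

    def test_simulated_truth_classes_recovered(self, small_sim):
        """RBH over the simulated proteomes recovers the planted
        gametolog pairs and paralog relations."""
        from uvscan.gametologs import make_aligner

        truth = small_sim.truth.genes
        prot = {}
        for sex in ("male", "female"):
            seqs = dict(small_sim.male if sex == "male" else small_sim.female)
            for r in small_sim.genes[sex].itertuples():
                cds = seqs[r.scaffold][r.start : r.end]
                prot.setdefault(sex, {})[r.gene_id] = translate(cds)
        # restrict to SDR genes for speed: truth gametologs + sex-limited
        sdr_m = list(truth[truth.klass.isin(["gametolog", "sex_limited_male"])]
                     .dropna(subset=["scaffold_male"]).gene_id)
        sdr_f = list(truth[truth.klass.isin(["gametolog", "sex_limited_female"])]
                     .dropna(subset=["scaffold_female"]).gene_id)
        male_prot = {g: prot["male"][g] for g in sdr_m}
        female_prot = {g: prot["female"][g] for g in sdr_f}
        pairs, _ = rbh_pairs(male_prot, female_prot)
        expected = {
            (r.gene_id, r.partner)
            for r in truth[truth.klass == "gametolog"].itertuples()
            if r.gene_id.endswith("_M")
        }
        assert set(pairs) == expected


class TestStrataScan:
    def _pairs(self, ks_list):
        return [
            GametologPair(f"m{i}", f"f{i}", ks, 0.0, None, ks is None, v_position=i * 1000)
            for i, ks in enumerate(ks_list)
        ]

    def test_uniform_ks_single_segment(self):
        res = strata_scan(self._pairs([0.3] * 8))
        assert len(res["segments"]) == 1

    def test_planted_change_point_found(self, rng):
        ks = list(2.0 + rng.normal(0, 0.05, 5)) + list(0.3 + rng.normal(0, 0.05, 5))
        res = strata_scan(self._pairs(ks))
        assert len(res["segments"]) == 2
        (s1, e1, m1), (s2, e2, m2) = res["segments"]
        assert e1 == 5 and s2 == 5
        assert m1 > m2

    def test_saturated_pairs_rank_oldest(self):
        pairs = self._pairs([None, None, None, 0.2, 0.2, 0.2])
        res = strata_scan(pairs)
        assert res["segments"][0][2] > res["segments"][-1][2]

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            strata_scan(self._pairs([0.5]))
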