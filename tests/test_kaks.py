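import itertools
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from ltpscan.kaks import (
    CodonAlignment, GENETIC_CODE, PairwiseAlignment, SiteCounts, analyze_pair,
    align_proteins_global, backtranslate_alignment, jukes_cantor,
    kaks_estimate, ng86_counts, synonymous_site_fraction,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")
SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def brute_force_alignment_score(a, b, gap_open=10.0, gap_extend=0.5):
    """Oracle: exhaustively enumerate all global alignments (as move strings)
    and return the best affine-gap score.  Gap of length L costs
    open + (L−1)·extend; end gaps are penalized."""
    best = -math.inf

    def recurse(i, j, score, prev):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, score + BLOSUM62[a[i], b[j]], "D")
        if i < len(a):
            cost = gap_extend if prev == "U" else gap_open
            recurse(i + 1, j, score - cost, "U")
        if j < len(b):
            cost = gap_extend if prev == "L" else gap_open
            recurse(i, j + 1, score - cost, "L")

    recurse(0, 0, 0.0, "")
    return best


def oracle_pair_diff(c1, c2):
    """Oracle: explicit enumeration of substitution paths between two codons,
    averaging syn/nonsyn step counts over stop-free orderings (all orderings
    if every path crosses a stop)."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    all_paths, clean_paths = [], []
    for order in itertools.permutations(positions):
        states = [c1]
        for pos in order:
            states.append(states[-1][:pos] + c2[pos] + states[-1][pos + 1:])
        steps = [(GENETIC_CODE[x] == GENETIC_CODE[y])
                 for x, y in zip(states, states[1:])]
        record = (sum(steps), len(steps) - sum(steps))
        all_paths.append(record)
        if all(GENETIC_CODE[s] != "*" for s in states[1:]):
            clean_paths.append(record)
    use = clean_paths or all_paths
    return (sum(p[0] for p in use) / len(use),
            sum(p[1] for p in use) / len(use))


class TestAlignProteinsGlobal:
    def test_identity(self):
        aln = align_proteins_global("MKC", "MKC")
        assert aln.aligned_a == aln.aligned_b == "MKC"

    def test_forced_single_gap(self):
        aln = align_proteins_global("MKC", "MC")
        assert aln.aligned_a == "MKC"
        assert aln.aligned_b.count("-") == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_proteins_global("", "MK")

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_optimal_score_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aas, size=int(rng.integers(1, 7))))
        b = "".join(rng.choice(aas, size=int(rng.integers(1, 7))))
        assert align_proteins_global(a, b).score == pytest.approx(
            brute_force_alignment_score(a, b))

    def test_no_dual_gap_columns(self):
        aln = align_proteins_global("MKCW", "MW")
        assert all(not (x == "-" and y == "-")
                   for x, y in zip(aln.aligned_a, aln.aligned_b))


class TestBacktranslate:
    def test_gapless(self):
        aln = PairwiseAlignment("MK", "MK", 0)
        out = backtranslate_alignment(aln, "ATGAAA", "ATGAAG")
        assert out.codons_a == "ATGAAA"
        assert out.codons_b == "ATGAAG"

    def test_gap_becomes_codon_gap(self):
        aln = PairwiseAlignment("MKC", "M-C", 0)
        out = backtranslate_alignment(aln, "ATGAAATGT", "ATGTGC")
        assert out.codons_b == "ATG---TGC"

    def test_round_trip_degap(self):
        aln = align_proteins_global("MKCW", "MCW")
        cds_a, cds_b = "ATGAAATGTTGG", "ATGTGCTGG"
        out = backtranslate_alignment(aln, cds_a, cds_b)
        assert out.codons_a.replace("-", "") == cds_a
        assert out.codons_b.replace("-", "") == cds_b

    def test_translation_mismatch_names_codon(self):
        aln = PairwiseAlignment("MK", "MK", 0)
        with pytest.raises(ValueError, match="codon 1"):
            backtranslate_alignment(aln, "ATGTGT", "ATGAAA")


class TestNg86Counts:
    def test_identical_codons(self):
        counts = ng86_counts(CodonAlignment("TTT", "TTT"))
        assert counts.Sd == counts.Nd == 0

    def test_phe_to_leu_single_nonsynonymous(self):
        counts = ng86_counts(CodonAlignment("TTT", "TTA"))
        assert counts.Nd == 1
        assert counts.Sd == 0

    def test_synonymous_third_position(self):
        counts = ng86_counts(CodonAlignment("GGT", "GGC"))
        assert counts.Sd == 1
        assert counts.Nd == 0

    def test_site_conservation(self):
        rng = np.random.default_rng(0)
        codons_a = "".join(rng.choice(SENSE_CODONS, size=20))
        codons_b = "".join(rng.choice(SENSE_CODONS, size=20))
        counts = ng86_counts(CodonAlignment(codons_a, codons_b))
        assert counts.S + counts.N == pytest.approx(3 * 20)

    def test_gap_and_stop_columns_skipped(self):
        counts = ng86_counts(CodonAlignment("TTT---TAATTT", "TTTAAATAATTA"))
        assert counts.skipped_codons == 2
        assert counts.S + counts.N == pytest.approx(6)

    @settings(max_examples=80, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_random_codon_pairs_match_path_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ca = SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))]
        cb = SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))]
        counts = ng86_counts(CodonAlignment(ca, cb))
        sd, nd = oracle_pair_diff(ca, cb)
        assert counts.Sd == pytest.approx(sd)
        assert counts.Nd == pytest.approx(nd)

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        a = "".join(rng.choice(SENSE_CODONS, size=15))
        b = "".join(rng.choice(SENSE_CODONS, size=15))
        fwd = ng86_counts(CodonAlignment(a, b))
        rev = ng86_counts(CodonAlignment(b, a))
        assert fwd.S == pytest.approx(rev.S)
        assert fwd.Sd == pytest.approx(rev.Sd)
        assert fwd.Nd == pytest.approx(rev.Nd)

    def test_fourfold_sites_give_zero_ka(self):
        # mutate only 4-fold-degenerate third positions
        a = "GGTCCTACTGCT" * 5
        b = "GGCCCAACTGCT" * 5    # 2 of 4 third positions changed per repeat
        counts = ng86_counts(CodonAlignment(a, b))
        est = kaks_estimate(counts)
        assert est.ka == 0.0
        assert est.ks > 0


class TestKaksEstimate:
    def test_zero_differences(self):
        est = kaks_estimate(SiteCounts(S=100, N=200, Sd=0, Nd=0))
        assert est.ka == est.ks == 0.0

    def test_jc_closed_form(self):
        est = kaks_estimate(SiteCounts(S=100, N=200, Sd=30, Nd=0))
        assert est.ks == pytest.approx(-0.75 * math.log(0.6), abs=1e-10)
        assert est.ks == pytest.approx(0.38312, abs=5e-6)

    def test_saturation_flag(self):
        est = kaks_estimate(SiteCounts(S=100, N=200, Sd=80, Nd=0))
        assert est.saturated
        assert est.ks is None

    def test_ratio(self):
        est = kaks_estimate(SiteCounts(S=100, N=100, Sd=10, Nd=10))
        assert est.ratio == pytest.approx(1.0)

    @given(st.floats(0, 0.7), st.floats(0.001, 0.7))
    def test_monotone_below_saturation(self, p_small, delta):
        p_big = min(p_small + delta, 0.749)
        assert jukes_cantor(p_big) >= jukes_cantor(p_small)


class TestSimulationRecovery:
    def test_zero_targets_identical(self):
        from ltpscan.synthetic_data import simulate_codon_pair
        a, b, _ = simulate_codon_pair(50, 0.0, 0.0, seed=4)
        assert a == b
        counts, est = analyze_pair(str(Seq(a).translate()), str(Seq(b).translate()), a, b)
        assert est.ka == est.ks == 0.0

    def test_recovery_within_three_se(self):
        # scaled-down version of the acceptance run (30 replicates here)
        from ltpscan.synthetic_data import simulate_codon_pair
        d_ks, d_ka = [], []
        for rep in range(30):
            a, b, truth = simulate_codon_pair(300, 0.5, 0.05, seed=900 + rep)
            row = truth.rows[0]
            counts, est = analyze_pair(str(Seq(a).translate()),
                                       str(Seq(b).translate()), a, b)
            d_ks.append(est.ks - row["realized_ks"])
            d_ka.append(est.ka - row["realized_ka"])
        d_ks, d_ka = np.asarray(d_ks), np.asarray(d_ka)
        # SE of a single NG86 estimate = replicate SD
        assert abs(d_ks.mean()) <= 3 * d_ks.std(ddof=1)
        assert abs(d_ka.mean()) <= 3 * d_ka.std(ddof=1)
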