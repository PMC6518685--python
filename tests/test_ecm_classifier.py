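import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ltpscan.ecm_classifier import (
    ClassificationResult, EcmMatch, ScanConfig, TypeTemplate,
    classify_by_similarity, classify_by_spacing, classify_proteome,
    consensus_logo_counts, find_ecm_matches, format_allowed, load_templates,
)
from ltpscan.io_formats import ProteinRecord

from conftest import build_ecm


def brute_force_ecm(seq, config=ScanConfig()):
    """Independent oracle: enumerate all 8-subsets of cysteine positions and
    keep those satisfying the structural constraints and spacer bounds."""
    cys = [i for i, ch in enumerate(seq) if ch == "C"]
    cys_set = set(cys)
    lo, hi = config.min_spacer, config.max_spacer
    found = []
    for combo in itertools.combinations(cys, 8):
        c = combo
        spacers = (c[1] - c[0] - 1, c[2] - c[1] - 1, c[4] - c[3] - 1,
                   c[6] - c[5] - 1, c[7] - c[6] - 1)
        if c[3] != c[2] + 1:
            continue
        if c[5] != c[4] + 2 or seq[c[4] + 1] == "C":
            continue
        if any(not (lo <= s <= hi) for s in spacers):
            continue
        if not config.allow_cys_in_spacers:
            spacer_ranges = [(c[0], c[1]), (c[1], c[2]), (c[3], c[4]),
                             (c[5], c[6]), (c[6], c[7])]
            if any(p in cys_set
                   for a, b in spacer_ranges for p in range(a + 1, b)):
                continue
        found.append(spacers)
    return found


class TestFindEcmMatches:
    def test_type_i_construction(self):
        seq = "M" + build_ecm((9, 12, 19, 20, 3))
        matches = find_ecm_matches(seq)
        assert len(matches) == 1
        assert matches[0].spacers == (9, 12, 19, 20, 3)
        assert matches[0].cys_positions[0] == 1
        assert matches[0].ecm_seq == seq[1:]

    def test_no_cysteines(self):
        assert find_ecm_matches("MKLLVA") == []

    def test_seven_cysteines(self):
        seq = build_ecm((9, 12, 19, 20, 3)).replace("CC", "CA", 1)
        assert find_ecm_matches(seq) == []

    def test_nine_cys_multiple_assignments_vs_oracle(self):
        # extra cysteines inside the s4/s5 region create alternative c7/c8
        # choices once cysteine-containing spacers are allowed
        seq = ("C" + "A" * 9 + "C" + "A" * 12 + "CC" + "A" * 19 + "CAC"
               + "A" * 9 + "C" + "A" * 9 + "C" + "A" * 9 + "C")
        config = ScanConfig(allow_cys_in_spacers=True)
        matches = find_ecm_matches(seq, config)
        oracle = brute_force_ecm(seq, config)
        assert len(matches) == len(oracle) >= 2
        assert sorted(m.spacers for m in matches) == sorted(oracle)

    def test_matches_ordered_by_c1_then_c8(self):
        seq = ("C" + "A" * 9 + "C" + "A" * 12 + "CC" + "A" * 19 + "CAC"
               + "A" * 9 + "C" + "A" * 9 + "C" + "A" * 9 + "C")
        matches = find_ecm_matches(seq, ScanConfig(allow_cys_in_spacers=True))
        keys = [(m.cys_positions[0], m.cys_positions[7]) for m in matches]
        assert keys == sorted(keys)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 10 ** 6), st.booleans())
    def test_random_sequences_match_oracle(self, seed, allow_cys):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(20, 201))
        n_cys = int(rng.integers(0, 13))
        seq = list(rng.choice(list("ADEFGHIKLMNPQRSTVWY"), size=length))
        for pos in rng.choice(length, size=min(n_cys, length), replace=False):
            seq[pos] = "C"
        seq = "".join(seq)
        config = ScanConfig(allow_cys_in_spacers=allow_cys)
        assert sorted(m.spacers for m in find_ecm_matches(seq, config)) == \
            sorted(brute_force_ecm(seq, config))

    def test_spacer_bounds_configurable(self):
        seq = build_ecm((2, 12, 19, 20, 3))
        assert find_ecm_matches(seq) == []
        assert len(find_ecm_matches(seq, ScanConfig(min_spacer=2))) == 1


class TestClassifyBySpacing:
    @pytest.mark.parametrize("spacers,expected", [
        ((9, 12, 19, 20, 3), ["I"]),
        ((7, 13, 8, 23, 6), ["II"]),
        ((5, 5, 5, 5, 5), []),
    ])
    def test_examples(self, templates, spacers, expected):
        match = EcmMatch((0,) * 8, spacers, "")
        assert classify_by_spacing(match, templates) == expected

    def test_overlap_set_matches_exhaustive_oracle(self, templates):
        # oracle: direct set-membership over the Cartesian product of every
        # template's allowed sets
        oracle_multi = set()
        for t in templates:
            for tup in itertools.product(*[sorted(a) for a in t.allowed]):
                n = sum(1 for u in templates if all(
                    s in a for s, a in zip(tup, u.allowed)))
                if n >= 2:
                    oracle_multi.add(tup)
        impl_multi = set()
        for t in templates:
            for tup in itertools.product(*[sorted(a) for a in t.allowed]):
                if len(classify_by_spacing(EcmMatch((0,) * 8, tup, ""), templates)) >= 2:
                    impl_multi.add(tup)
        assert impl_multi == oracle_multi
        assert oracle_multi          # XII/XIII genuinely overlap

    def test_registry_order_preserved(self, templates):
        # a tuple in the XII/XIII intersection lists XII first
        match = EcmMatch((0,) * 8, (9, 13, 21, 21, 9), "")
        assert classify_by_spacing(match, templates) == ["XII", "XIII"]


class TestClassifyBySimilarity:
    def test_identical_reference(self):
        ecm = build_ecm((9, 12, 19, 20, 3))
        assert classify_by_similarity(ecm, [("I", ecm)]) == ("I", 100.0)

    def test_hamming_one_of_fifty(self):
        ref = ("MKLV" * 12 + "RS")  # length 50
        query = "A" + ref[1:]
        far = "W" * 50
        type_name, pct = classify_by_similarity(query, [("I", far), ("II", ref)])
        assert type_name == "II"
        assert pct == pytest.approx(98.0)

    def test_tie_goes_to_first_registered(self):
        ref = "MKLVRSMKLVRSMKLVRSM...".replace(".", "A")
        query = "A" + ref[1:]
        result = classify_by_similarity(query, [("V", ref), ("VII", ref)])
        assert result[0] == "V"

    def test_empty_references_rejected(self):
        with pytest.raises(ValueError):
            classify_by_similarity("CAC", [])


class TestClassifyProteome:
    def test_empty_proteome(self, templates):
        results, summary = classify_proteome([], templates)
        assert results == []
        assert summary["count"].sum() == 0

    def test_unmatched_without_fallback(self, templates):
        rec = ProteinRecord("p", build_ecm((5, 5, 5, 5, 5)))
        results, _ = classify_proteome([rec], templates)
        assert results[0].assigned_type == "unclassified"
        assert results[0].best_match is not None

    def test_no_ecm(self, templates):
        results, _ = classify_proteome([ProteinRecord("p", "MKLV")], templates)
        assert results[0].assigned_type == "no_ecm"
        assert results[0].method == "none"

    def test_similarity_fallback(self, templates):
        ecm = build_ecm((5, 5, 5, 5, 5), filler="L")
        rec = ProteinRecord("p", "MK" + ecm)
        refs = [("XII", ecm)]
        results, _ = classify_proteome([rec], templates, references=refs)
        assert results[0].assigned_type == "XII"
        assert results[0].method == "similarity"
        assert results[0].similarity_identity == pytest.approx(100.0)

    def test_fallback_below_threshold_unclassified(self, templates):
        ecm = build_ecm((5, 5, 5, 5, 5), filler="L")
        rec = ProteinRecord("p", ecm)
        refs = [("XII", "W" * len(ecm))]
        results, _ = classify_proteome([rec], templates, references=refs)
        assert results[0].assigned_type == "unclassified"

    def test_planted_counts_and_shares(self, templates):
        from ltpscan.synthetic_data import generate_proteome
        composition = {"I": 36, "II": 6, "IV": 10, "V": 2, "VII": 1,
                       "VIII": 12, "XII": 7, "XIII": 9}
        proteins, _, truth = generate_proteome(composition, 200, seed=1)
        results, summary = classify_proteome(proteins, templates)
        counts = dict(zip(summary["type"], summary["count"]))
        assert counts == composition
        share = summary.loc[summary["type"] == "I", "percent"].item()
        assert share == pytest.approx(36 / 83 * 100, abs=0.005)
        # every planted protein's true type is among its matched types
        truth_by_id = {r["record_id"]: r for r in truth.rows}
        for r in results:
            t = truth_by_id[r.protein_id]
            if t["category"] == "family":
                assert t["true_type"] in r.matched_types
            else:
                assert r.assigned_type in ("no_ecm", "unclassified")

    def test_summary_counts_consistent(self, templates):
        from ltpscan.synthetic_data import generate_proteome
        proteins, _, _ = generate_proteome({"I": 5, "II": 3}, 9, seed=7)
        results, summary = classify_proteome(proteins, templates)
        n_classified = sum(1 for r in results
                           if r.assigned_type not in ("no_ecm", "unclassified"))
        assert summary["count"].sum() == n_classified

    def test_determinism(self, templates):
        from ltpscan.synthetic_data import generate_proteome
        proteins, _, _ = generate_proteome({"I": 4, "XIII": 4}, 12, seed=3)
        r1, s1 = classify_proteome(proteins, templates)
        r2, s2 = classify_proteome(proteins, templates)
        assert r1 == r2
        assert s1.equals(s2)


class TestBestMatchRule:
    def test_prefers_fewest_matched_types_then_leftmost(self, templates):
        # Two valid ECMs in one protein: an ambiguous XII/XIII motif first,
        # then a unique type-II motif; the rule picks the type-II one.
        ambiguous = build_ecm((9, 13, 21, 21, 9))
        unique = build_ecm((7, 13, 8, 23, 6))
        rec = ProteinRecord("p", ambiguous + "AAAA" + unique)
        results, _ = classify_proteome([rec], templates)
        assert results[0].assigned_type == "II"
        assert results[0].matched_types == ("II",)


class TestConsensusLogoCounts:
    def test_identical_sequences(self):
        counts = consensus_logo_counts(["CAC", "CAC", "CAC"])
        assert counts.loc["C", 0] == 3
        assert counts.loc["A", 1] == 3

    def test_single_divergent_column(self):
        counts = consensus_logo_counts(["CAC", "CGC"])
        assert counts.loc["A", 1] == 1
        assert counts.loc["G", 1] == 1

    def test_column_sums_equal_n(self):
        seqs = ["CA-C", "CGAC", "C-AC"]
        counts = consensus_logo_counts(seqs)
        assert (counts.sum(axis=0) == len(seqs)).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consensus_logo_counts(["CAC", "CA"])


class TestFormatAllowed:
    @pytest.mark.parametrize("values,expected", [
        ({9, 10}, "9–10"),
        ({3, 13, 14}, "3,13–14"),
        ({19, 21, 22, 23, 26, 30}, "19,21–23,26,30"),
        ({24}, "24"),
    ])
    def test_compact_ranges(self, values, expected):
        assert format_allowed(values) == expected
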