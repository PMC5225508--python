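"""Structural annotation: boundaries, TIRs, TSDs, subterminal repeats,
terminal palindrome, coding span."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement
from hypothesis import given, settings
from hypothesis import strategies as st

from mulescan._transposase import dde_domain_query
from mulescan.annotator import (BoundaryError, annotate_element, call_tsd,
                                detect_boundaries, find_subterminal_repeats,
                                find_tir, locate_orf_dde,
                                score_terminal_palindrome)
from mulescan.synthetic import ElementTemplate, build_element

DNA = st.text(alphabet="ACGT", min_size=12, max_size=40)


def _rand(rng, n, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


class TestDetectBoundaries:
    def test_identical_element_distinct_flanks_exact(self, muta_core):
        # flanks drawn from disjoint alphabets cannot match at the edge,
        # so the boundary is unambiguous and must be recovered exactly
        rng = np.random.default_rng(0)
        el = muta_core.seq
        a = _rand(rng, 300, "AC") + el + _rand(rng, 300, "AC")
        b = _rand(rng, 280, "GT") + el + _rand(rng, 320, "GT")
        ba, bb = detect_boundaries(a, b)
        assert ba == (300, 300 + len(el))
        assert bb == (280, 280 + len(el))
        # symmetric in argument order
        bb2, ba2 = detect_boundaries(b, a)
        assert (ba2, bb2) == (ba, bb)

    def test_diverged_copies_within_5bp(self, muta_core):
        rng = np.random.default_rng(1)
        el = muta_core.seq
        el2 = list(el)
        for i in rng.choice(len(el), 32, replace=False):   # ~1% divergence
            el2[i] = "ACGT"[rng.integers(0, 4)]
        el2 = "".join(el2)
        a = _rand(rng, 300) + el + _rand(rng, 300)
        b = _rand(rng, 250) + el2 + _rand(rng, 350)
        ba, bb = detect_boundaries(a, b)
        assert abs(ba[0] - 300) <= 5 and abs(ba[1] - (300 + len(el))) <= 5
        assert abs(bb[0] - 250) <= 5 and abs(bb[1] - (250 + len(el2))) <= 5

    def test_same_locus_duplicate_errors(self, muta_core):
        rng = np.random.default_rng(2)
        a = _rand(rng, 200) + muta_core.seq + _rand(rng, 200)
        with pytest.raises(BoundaryError, match="cannot resolve"):
            detect_boundaries(a, a)


class TestFindTir:
    def test_planted_145bp_perfect(self, muta_core):
        tir = find_tir(muta_core.seq)
        assert (tir.length, tir.identity) == (145, 1.0)

    def test_planted_151bp(self):
        t = ElementTemplate(total_len=3496, tir_len=151,
                            subrepeat_unit_len=15, subrepeat_copies=9,
                            spacer_len_range=(0, 1), n_exons=1)
        core = build_element(t, np.random.default_rng(3))
        assert find_tir(core.seq).length == 151

    def test_random_sequence_mostly_none(self):
        none_count = 0
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            none_count += find_tir(_rand(rng, 2000)) is None
        assert none_count >= 19

    def test_strand_symmetric(self, muta_core):
        fwd = find_tir(muta_core.seq)
        rev = find_tir(reverse_complement(muta_core.seq))
        assert (fwd.length, fwd.identity) == (rev.length, rev.identity)

    def test_too_short_returns_none(self):
        assert find_tir("ACGT" * 10) is None


class TestCallTsd:
    def test_nested_nine_over_eight(self):
        left = "GGCCGGCC" + "ATTCAATAG"
        right = "ATTCAATAG" + "GGTTGGTT"
        tsd = call_tsd(left, right)
        assert (tsd.length, tsd.left) == (9, "ATTCAATAG")

    def test_eight_bp(self):
        tsd = call_tsd("TTTT" + "CGATTCAA", "CGATTCAA" + "GGGG")
        assert (tsd.length, tsd.left) == (8, "CGATTCAA")

    def test_unrelated_flanks_none(self):
        assert call_tsd("AAAACCCCGGGG", "TTTTGGGGAAAA") is None

    def test_n_never_matches(self):
        assert call_tsd("TTTTCGANTCAA", "CGANTCAAGGGG") is None

    def test_imperfect_flagged_not_counted(self):
        left, right = "TTTTCGATTCAA", "CGATACAAGGGG"
        assert call_tsd(left, right) is None
        imp = call_tsd(left, right, report_imperfect=True)
        assert imp is not None and not imp.perfect

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(DNA, st.text(alphabet="ACGT", min_size=8, max_size=9), DNA)
    def test_strand_symmetry(self, lf, dup, rf):
        left, right = lf + dup, dup + rf
        fwd = call_tsd(left, right)
        rev = call_tsd(reverse_complement(right), reverse_complement(left))
        assert (fwd is None) == (rev is None)
        if fwd is not None:
            assert fwd.length == rev.length
            assert rev.left == reverse_complement(fwd.right)


class TestSubterminalRepeats:
    def test_planted_12mer_nine_copies(self, muta_core):
        sub = find_subterminal_repeats(muta_core.seq[:145])
        assert (sub.unit_len, sub.copies) == (12, 9)
        assert set(sub.spacers) <= {3, 4}
        assert len(sub.spacers) == 8

    def test_planted_15mer(self):
        t = ElementTemplate(total_len=3496, tir_len=151,
                            subrepeat_unit_len=15, subrepeat_copies=9,
                            spacer_len_range=(0, 1), n_exons=1)
        core = build_element(t, np.random.default_rng(5))
        sub = find_subterminal_repeats(core.seq[:151])
        assert (sub.unit_len, sub.copies) == (15, 9)

    def test_random_arm_mostly_none(self):
        none_count = 0
        for seed in range(20):
            rng = np.random.default_rng(4000 + seed)
            none_count += find_subterminal_repeats(_rand(rng, 145)) is None
        assert none_count >= 19

    def test_one_mismatch_per_copy_tolerated(self):
        unit = "GACACTGAGATT"
        spacers = ["CTA", "GAC", "TTG", "AGT", "CCA"]   # varied boundaries
        copies = []
        for k in range(5):
            c = list(unit)
            c[k] = {"G": "C", "A": "T", "C": "G", "T": "A"}[c[k]]
            copies.append("".join(c))
        arm = unit + "".join(sp + c for sp, c in zip(spacers, copies))
        sub = find_subterminal_repeats(arm)
        assert sub is not None and sub.copies == 6 and sub.unit_len == 12


class TestTerminalPalindrome:
    @pytest.mark.parametrize("motif,unpaired", [
        ("GGGAAATCCC", (5, 6)),          # 5th/6th unpaired, rest paired
        ("GAATTAATTC", ()),              # perfect palindrome
        ("AAAAAAAAAA", tuple(range(1, 11))),
    ])
    def test_pairing_profile(self, motif, unpaired):
        assert score_terminal_palindrome(motif) == unpaired

    def test_n_reported_unpaired(self):
        assert 1 in score_terminal_palindrome("NAATTAATTC")
        assert 10 in score_terminal_palindrome("NAATTAATTC")

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            score_terminal_palindrome("ACGTACGT")

    def test_generated_motifs_match_template(self):
        for seed in range(5):
            core = build_element(ElementTemplate(), np.random.default_rng(seed))
            assert score_terminal_palindrome(core.seq[:10]) == (5, 6)


class TestLocateOrfDde:
    def test_planted_single_exon_triad_recovered(self):
        t = ElementTemplate(n_exons=1)
        core = build_element(t, np.random.default_rng(6))
        q, triad = dde_domain_query()
        coding = locate_orf_dde(core.seq, q, triad)
        assert coding is not None
        assert coding.strand == "+"
        assert coding.dde_offsets == core.dde_offsets
        assert not coding.interrupted
        s, e = coding.orf_span
        assert s <= core.dde_offsets[0] and e >= core.dde_offsets[2] + 3

    def test_two_exon_domain_found_in_coding_exon(self, muta_core):
        q, triad = dde_domain_query()
        coding = locate_orf_dde(muta_core.seq, q, triad)
        assert coding is not None
        assert coding.dde_offsets == muta_core.dde_offsets

    def test_internal_stop_flagged_interrupted(self):
        t = ElementTemplate(n_exons=1)
        core = build_element(t, np.random.default_rng(7))
        seq = list(core.seq)
        mid = core.dde_offsets[1] + 30      # between D2 and E, in frame
        off = core.orf_spans[0][0]
        mid -= (mid - off) % 3
        seq[mid:mid + 3] = "TAA"
        coding = locate_orf_dde("".join(seq), *dde_domain_query())
        assert coding is not None and coding.interrupted

    def test_noncoding_derivative_none(self):
        rng = np.random.default_rng(8)
        q, _ = dde_domain_query()
        assert locate_orf_dde(_rand(rng, 1500), q) is None


def test_annotate_element_closed_loop(small_genome):
    genome, _genes, truth = small_genome
    q, triad = dde_domain_query()
    p = [x for x in truth.planted if x.kind == "full"][0]
    el = annotate_element(genome, p.scaffold, p.span, dde_query=q,
                          triad_offsets=triad)
    assert el.tir.length == 145
    assert el.tsd.length == len(p.tsd_seq)
    assert (el.subrepeats.unit_len, el.subrepeats.copies) == (12, 9)
    assert el.palindrome.unpaired == (5, 6)
    assert el.coding is not None
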