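"""Derivative discovery: terminal seed search, convergent end pairing,
TSD verification against the planted truth, Pack-MULE content."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from mulescan.derivatives import (EndHit, census, classify_pack_content,
                                  pair_ends, terminal_seed_search,
                                  verify_and_annotate)
from mulescan.formats_io import GenomeSet
from mulescan.synthetic import random_genome


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestTerminalSeedSearch:
    def test_planted_exact_termini_all_found(self):
        rng = np.random.default_rng(0)
        term = _rand(rng, 50)
        pieces, pos = [], []
        cur = 0
        for _ in range(4):
            gap = _rand(rng, 2000)
            pieces += [gap, term]
            cur += len(gap)
            pos.append(cur)
            cur += 50
        genome = GenomeSet({"s": "".join(pieces) + _rand(rng, 1000)})
        hits = terminal_seed_search(genome, term)
        fwd = [h for h in hits if h.orientation == "fwd"]
        assert sorted(h.start for h in fwd) == pos
        assert all(h.mismatches == 0 for h in fwd)

    def test_reverse_occurrence_flagged(self):
        rng = np.random.default_rng(1)
        term = _rand(rng, 50)
        genome = GenomeSet(
            {"s": _rand(rng, 500) + reverse_complement(term) + _rand(rng, 500)})
        hits = terminal_seed_search(genome, term)
        assert [h.orientation for h in hits] == ["rev"]
        assert hits[0].start == 500

    def test_mismatch_bounded(self):
        rng = np.random.default_rng(2)
        term = _rand(rng, 50)
        noisy = list(term)
        for i in (5, 20, 35):
            noisy[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[noisy[i]]
        genome = GenomeSet({"s": _rand(rng, 300) + "".join(noisy)
                            + _rand(rng, 300)})
        assert terminal_seed_search(genome, term, max_mismatches=5)
        assert not terminal_seed_search(genome, term, max_mismatches=2)

    def test_random_genome_no_exact_hits(self):
        rng = np.random.default_rng(3)
        term = _rand(rng, 50)
        clean = 0
        for seed in range(20):
            g = random_genome(1, 100_000, seed=5000 + seed)
            clean += not terminal_seed_search(g, term, max_mismatches=0)
        assert clean >= 19

    def test_wrong_terminus_length_rejected(self):
        with pytest.raises(ValueError, match="50"):
            terminal_seed_search(GenomeSet({"s": "ACGT" * 100}), "ACGT")


class TestPairEnds:
    def _hits(self, layout):
        # layout: list of (start, orientation)
        return [EndHit("s", st, st + 50, o, 0) for st, o in layout]

    def test_single_convergent_pair(self):
        cands = pair_ends(self._hits([(100, "fwd"), (1550, "rev")]))
        assert len(cands) == 1
        assert cands[0].span == (100, 1600)
        assert not cands[0].nested

    def test_divergent_orientation_no_candidate(self):
        assert pair_ends(self._hits([(100, "rev"), (1550, "fwd")])) == []

    def test_span_limits_respected(self):
        near = pair_ends(self._hits([(100, "fwd"), (120, "rev")]))
        assert near == []        # below min_span
        far = pair_ends(self._hits([(100, "fwd"), (30_000, "rev")]))
        assert far == []         # beyond max_span

    def test_nested_pairs_both_emitted_and_flagged(self):
        hits = self._hits([(100, "fwd"), (1000, "fwd"),
                           (2000, "rev"), (4000, "rev")])
        cands = pair_ends(hits)
        spans = {c.span for c in cands}
        assert spans == {(100, 4050), (1000, 2050)}
        flags = {c.span: c.nested for c in cands}
        assert flags[(1000, 2050)] is True
        assert flags[(100, 4050)] is False

    def test_each_hit_used_once_matches_valid_pairings(self):
        # brute force: the emitted pairing must be among all pairings
        # that are convergent, within span limits, and hit-disjoint
        import itertools

        hits = self._hits([(0, "fwd"), (500, "fwd"), (1200, "rev"),
                           (5000, "fwd"), (6000, "rev")])
        fwd = [h for h in hits if h.orientation == "fwd"]
        rev = [h for h in hits if h.orientation == "rev"]
        valid = []
        for rperm in itertools.permutations(rev):
            for fsub in itertools.permutations(fwd, len(rev)):
                pairing = set()
                ok = True
                for lh, rh in zip(fsub, rperm):
                    span = rh.end - lh.start
                    if rh.start <= lh.start or not 100 <= span <= 20000:
                        ok = False
                        break
                    pairing.add((lh.start, rh.end))
                if ok and pairing:
                    valid.append(pairing)
        got = {c.span for c in pair_ends(hits)}
        assert any(got == v for v in valid)


class TestVerifyAndAnnotate:
    def test_verified_count_matches_planted_perfect_subset(
            self, derivative_genome):
        genome, _genes, truth = derivative_genome
        full = [p for p in truth.planted if p.kind == "full"][0]
        term = genome.fetch(full.scaffold, full.span[0], full.span[0] + 50)
        cands = pair_ends(terminal_seed_search(genome, term))
        dervs = verify_and_annotate(cands, genome)
        want = {(p.scaffold, p.span) for p in truth.planted if p.tsd_perfect}
        got = {(d.scaffold, d.span) for d in dervs if d.tsd_verified}
        assert got == want

    def test_count_invariant_under_scaffold_order(self, derivative_genome):
        genome, _genes, truth = derivative_genome
        full = [p for p in truth.planted if p.kind == "full"][0]
        term = genome.fetch(full.scaffold, full.span[0], full.span[0] + 50)
        shuffled = GenomeSet(dict(reversed(list(genome.scaffolds.items()))))
        a = verify_and_annotate(
            pair_ends(terminal_seed_search(genome, term)), genome)
        b = verify_and_annotate(
            pair_ends(terminal_seed_search(shuffled, term)), shuffled)
        assert census(a) == census(b)

    def test_scrambled_flank_unverified(self):
        rng = np.random.default_rng(4)
        term = _rand(rng, 50)
        internal = _rand(rng, 400)
        elem = term + internal + reverse_complement(term)
        tsd = _rand(rng, 9)
        left_bg, right_bg = _rand(rng, 200), _rand(rng, 200)
        good = left_bg + tsd + elem + tsd + right_bg
        bad = left_bg + tsd + elem + _rand(rng, 9) + right_bg
        genome = GenomeSet({"good": good, "bad": bad})
        dervs = verify_and_annotate(
            pair_ends(terminal_seed_search(genome, term)), genome)
        status = {d.scaffold: d.tsd_verified for d in dervs}
        assert status == {"good": True, "bad": False}


class TestPackContent:
    def _derivative(self, internal):
        from mulescan.derivatives import DerivativeElement

        return DerivativeElement(
            scaffold="s", span=(0, len(internal) + 100),
            left_match=EndHit("s", 0, 50, "fwd", 0),
            right_match=EndHit("s", len(internal) + 50,
                               len(internal) + 100, "rev", 0),
            tsd=None, internal_span=(50, 50 + len(internal)),
            internal_seq=internal)

    def test_planted_fragment_recovered(self):
        rng = np.random.default_rng(5)
        host = _rand(rng, 600)
        frag = list(host[100:376])                 # 276 bp
        for i in rng.choice(276, 7, replace=False):
            frag[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[i]]
        internal = _rand(rng, 60) + "".join(frag) + _rand(rng, 60)
        hits = classify_pack_content(self._derivative(internal),
                                     {"kinase": host})
        assert len(hits) == 1
        assert hits[0].source_gene == "kinase"
        assert hits[0].length >= 270
        assert hits[0].identity >= 0.97

    def test_random_internal_no_hits(self):
        rng = np.random.default_rng(6)
        host = _rand(rng, 600)
        for seed in range(20):
            r2 = np.random.default_rng(7000 + seed)
            internal = _rand(r2, 500)
            assert classify_pack_content(self._derivative(internal),
                                         {"g": host}) == []

    def test_two_fragments_non_overlapping(self):
        rng = np.random.default_rng(7)
        host = _rand(rng, 800)
        internal = (_rand(rng, 40) + host[0:150] + _rand(rng, 40)
                    + host[400:560] + _rand(rng, 40))
        hits = classify_pack_content(self._derivative(internal), {"g": host})
        assert len(hits) == 2
        spans = sorted(h.fragment_span for h in hits)
        assert spans[0][1] <= spans[1][0]

    def test_thresholds_respected(self):
        rng = np.random.default_rng(8)
        host = _rand(rng, 600)
        internal = _rand(rng, 30) + host[:80] + _rand(rng, 30)   # too short
        assert classify_pack_content(self._derivative(internal),
                                     {"g": host}, min_len=100) == []
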