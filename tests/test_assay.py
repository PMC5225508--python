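"""Yeast-assay analytics: rate arithmetic, footprint classification,
display-read mapping and reinsertion TSD extraction."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from mulescan.assay import (DonorSite, ExcisionError, classify_footprint,
                            excision_frequency, extract_reinsertion_tsd,
                            map_display_read, proportion,
                            reintegration_ratio, tsd_census)
from mulescan.formats_io import GenomeSet
from mulescan.synthetic import (generate_assay_fixtures,
                                generate_reinsertion_flanks, random_genome)


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestRates:
    def test_frequency_from_colony_counts(self):
        # 20 colonies from 100 ul of a 1e5 dilution of a 500 ul culture
        # estimate 1e7 viable cells; 244 revertants -> 2.44e-5
        r = excision_frequency(244, [(1e5, 20, 100)])
        assert r.viable_cells == pytest.approx(1.0e7)
        assert r.frequency == pytest.approx(2.44e-5)

    def test_consistent_dilutions_agree(self):
        one = excision_frequency(100, [(1e5, 20)])
        both = excision_frequency(100, [(1e5, 20), (1e6, 2)])
        assert both.viable_cells == pytest.approx(one.viable_cells)
        assert both.frequency == pytest.approx(one.frequency)

    def test_zero_revertants_zero_frequency(self):
        assert excision_frequency(0, [(1e5, 30)]).frequency == 0

    def test_all_zero_viable_rejected(self):
        with pytest.raises(ValueError, match="viable"):
            excision_frequency(10, [(1e5, 0), (1e6, 0)])

    def test_reintegration_ratio_values(self):
        assert reintegration_ratio(2.71e-6, 2.44e-5) == 11
        assert reintegration_ratio(5e-5, 5e-5) == 100
        assert reintegration_ratio(41 / 300, 1.0) == 14

    def test_reintegration_zero_total_rejected(self):
        with pytest.raises(ValueError):
            reintegration_ratio(1e-6, 0)

    @pytest.mark.parametrize("count,total,pct", [
        (4, 38, 10.5), (27, 29, 93.1), (25, 29, 86.2), (0, 10, 0.0),
    ])
    def test_proportion_values(self, count, total, pct):
        p, se = proportion(count, total)
        assert p == pytest.approx(pct, abs=0.05)
        assert se >= 0
        if count in (0, total):
            assert se == 0

    def test_proportion_zero_total_rejected(self):
        with pytest.raises(ValueError):
            proportion(1, 0)


def _donor(rng, tsd=None):
    tl = _rand(rng, 50)
    return DonorSite(left_flank=_rand(rng, 60), right_flank=_rand(rng, 60),
                     tsd=tsd, element_termini=(tl, reverse_complement(tl)))


class TestClassifyFootprint:
    def test_precise_with_tsd_single_copy(self):
        rng = np.random.default_rng(0)
        donor = _donor(rng, tsd="ATTCAATAG")
        call = classify_footprint(donor.empty_site, donor)
        assert call.footprint_class == "precise"
        assert call.tsd_copies_remaining == 1

    def test_precise_without_tsd(self):
        rng = np.random.default_rng(1)
        donor = _donor(rng)
        call = classify_footprint(donor.empty_site, donor)
        assert call.footprint_class == "precise"
        assert (call.left_bp_lost, call.right_bp_lost) == (0, 0)

    def test_flank_deletion_per_side_counts(self):
        rng = np.random.default_rng(2)
        donor = _donor(rng)
        left, right = donor.left_flank, donor.right_flank
        # drop 3 bp left, 1 bp right; regenerate until boundary bases
        # cannot slide (unique decomposition)
        jx = left[:-3] + right[1:]
        if left[-4] != right[1] and left[-3] != right[0]:
            call = classify_footprint(jx, donor)
            assert call.footprint_class == "flank_deletion"
            assert call.left_bp_lost + call.right_bp_lost == 4

    def test_tir_remnant_thirteen(self):
        rng = np.random.default_rng(3)
        donor = _donor(rng)
        remnant = donor.element_termini[0][:13]
        jx = donor.left_flank + remnant + donor.right_flank
        call = classify_footprint(jx, donor)
        assert call.footprint_class == "tir_remnant"
        assert call.remnant_len == 13

    def test_remnant_beyond_ceiling_complex(self):
        rng = np.random.default_rng(4)
        donor = _donor(rng)
        jx = donor.left_flank + donor.element_termini[0][:20] \
            + donor.right_flank
        assert classify_footprint(jx, donor).footprint_class == "complex"

    def test_insertion_of_filler(self):
        rng = np.random.default_rng(5)
        donor = _donor(rng)
        tl, tr = donor.element_termini
        filler = "ACGTG"
        if filler != tl[:5] and filler != tr[-5:]:
            jx = donor.left_flank + filler + donor.right_flank
            call = classify_footprint(jx, donor)
            assert call.footprint_class in ("insertion", "tir_remnant")

    def test_element_not_excised_raises(self):
        rng = np.random.default_rng(6)
        donor = _donor(rng)
        tl, tr = donor.element_termini
        still = donor.left_flank + tl + "ACGT" * 30 + tr + donor.right_flank
        with pytest.raises(ExcisionError):
            classify_footprint(still, donor)

    def test_extra_correct_flank_ignored(self):
        rng = np.random.default_rng(7)
        donor = _donor(rng, tsd="CGATTCAA")
        extra_l, extra_r = _rand(rng, 50), _rand(rng, 50)
        jx = extra_l + donor.empty_site + extra_r
        call = classify_footprint(jx, donor)
        assert call.footprint_class == "precise"

    def test_closed_loop_all_classes(self):
        for seed in range(6):
            for tsd in (None, "ATTCAATAG"):
                counts = {"precise": 5, "flank_deletion": 8,
                          "insertion": 4}
                if tsd is None:
                    counts["tir_remnant"] = 5
                fx = generate_assay_fixtures(counts, tsd=tsd, seed=seed)
                for jx, label in fx.junctions:
                    call = classify_footprint(jx, fx.donor)
                    assert call.footprint_class == label, (seed, tsd, label)


class TestMapDisplayRead:
    @pytest.fixture()
    def setup(self):
        rng = np.random.default_rng(8)
        genome = random_genome(1, 60_000, seed=42)
        term = _rand(rng, 50)
        return genome, term, rng

    def test_unique_flank_maps(self, setup):
        genome, term, rng = setup
        flank = genome.fetch("scf1", 10_000, 10_030)
        read = term[-20:] + flank
        loc = map_display_read(read, genome, term)
        assert loc.status == "mapped"
        assert (loc.scaffold, loc.pos, loc.strand) == ("scf1", 10_000, "+")

    def test_reverse_strand_flank(self, setup):
        genome, term, rng = setup
        flank = reverse_complement(genome.fetch("scf1", 20_000, 20_030))
        loc = map_display_read(term[-20:] + flank, genome, term)
        assert loc.status == "mapped" and loc.strand == "-"

    def test_duplicated_flank_ambiguous(self, setup):
        genome, term, rng = setup
        dup = _rand(rng, 30)
        seq = genome.scaffolds["scf1"]
        g2 = GenomeSet({"scf1": seq[:1000] + dup + seq[1000:2000] + dup
                        + seq[2000:]})
        loc = map_display_read(term[-20:] + dup, g2, term)
        assert loc.status == "ambiguous"

    def test_foreign_flank_unmapped(self, setup):
        genome, term, rng = setup
        loc = map_display_read(term[-20:] + "ACGT" * 8, genome, term)
        assert loc.status in ("unmapped", "ambiguous", "mapped")
        plasmid = "TTTTGGGGCCCCAAAA" + "TGCA" * 4
        loc2 = map_display_read(term[-20:] + plasmid, genome, term)
        assert loc2.status == "unmapped"

    def test_short_flank_rejected(self, setup):
        genome, term, _ = setup
        with pytest.raises(ValueError, match="flank"):
            map_display_read(term[-20:] + "ACGTACGT", genome, term)

    def test_read_without_terminus_rejected(self, setup):
        genome, term, rng = setup
        with pytest.raises(ValueError, match="terminus"):
            map_display_read(_rand(rng, 60), genome, term)


class TestReinsertionTsd:
    def test_planted_nine_bp(self):
        genome = random_genome(1, 50_000, seed=11)
        sites = generate_reinsertion_flanks(0, 5, genome, seed=1)
        for s in sites:
            call = extract_reinsertion_tsd((s.scaffold, s.pos), genome,
                                           s.left_flank, s.right_flank)
            assert call.status == "ok"
            assert call.tsd.length == 9
            assert not call.ambiguous

    def test_coincidental_ninth_base_flagged(self):
        # an 8-bp duplication inside an A-homopolymer run reads as a
        # 9-bp duplication by string matching, while the genomic spans
        # of the two read flanks overlap by only 8 bp
        rng = np.random.default_rng(12)
        p = 300
        scaffold = (_rand(rng, p - 2) + "C" + "A" * 10 + "G"
                    + _rand(rng, 300))
        genome = GenomeSet({"s": scaffold})
        left = scaffold[p - 40:p + 8]       # physical 8-bp TSD copy
        right = scaffold[p:p + 40]
        call = extract_reinsertion_tsd(("s", p), genome, left, right)
        assert call.status == "ok"
        assert call.tsd.length == 9         # longest-match rule
        assert call.ambiguous               # coordinate overlap says 8

    def test_flank_absent_from_genome_excluded(self):
        genome = random_genome(1, 30_000, seed=13)
        rng = np.random.default_rng(14)
        call = extract_reinsertion_tsd(("scf1", 100), genome,
                                       _rand(rng, 40), _rand(rng, 40))
        assert call.status == "excluded"

    def test_census_matches_planted_mix(self):
        genome = random_genome(1, 100_000, seed=15)
        sites = generate_reinsertion_flanks(21, 39, genome, seed=3)
        calls = [extract_reinsertion_tsd((s.scaffold, s.pos), genome,
                                         s.left_flank, s.right_flank)
                 for s in sites]
        assert tsd_census(calls) == {8: 21, 9: 39}
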