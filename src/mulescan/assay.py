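"""Analytics for the yeast transposition assay.

Covers excision/reintegration rate arithmetic from colony counts,
binomial proportions, classification of revertant excision footprints
(precise / flank deletion / insertion / TIR remnant / complex),
transposon-display read mapping, and TSD extraction at reinsertion
sites.

A *precise* excision restores the empty donor site exactly: flank + one
TSD copy + flank when the donor carried a TSD, or the original sequence
when it did not.  TIR remnants longer than 13 bp are classed complex,
mirroring the observed ceiling on remnant length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Seq import reverse_complement

from .annotator import TsdAnnotation, call_tsd
from .formats_io import GenomeSet

MAX_REMNANT = 13


class ExcisionError(ValueError):
    """Raised when a revertant still contains the element."""


# ---------------------------------------------------------------------------
# rates and proportions

@dataclass
class AssayRates:
    revertant_colonies: int
    viable_dilutions: list[tuple[float, int, float]]  # (dilution, colonies, ul)
    viable_cells: float
    frequency: float
    sd: float | None = None


def excision_frequency(revertants: int,
                       viable_dilutions: list[tuple],
                       resuspension_ul: float = 500.0,
                       sd: float | None = None) -> AssayRates:
    """Excision frequency (events per viable cell) from colony counts.

    Each viable-count plating (dilution factor, colonies, plated ul;
    the volume defaults to 100 ul) estimates the culture's viable cells
    as ``colonies * dilution * resuspension / plated``; the mean over
    dilutions divides the revertant count."""
    if revertants < 0:
        raise ValueError("revertant count must be >= 0")
    if not viable_dilutions:
        raise ValueError("need at least one viable-count dilution")
    norm = []
    for tup in viable_dilutions:
        if len(tup) == 2:
            dilution, colonies = tup
            volume = 100.0
        else:
            dilution, colonies, volume = tup
        if colonies < 0 or dilution <= 0 or volume <= 0:
            raise ValueError("bad viable-count entry")
        norm.append((float(dilution), int(colonies), float(volume)))
    estimates = [c * d * (resuspension_ul / v) for d, c, v in norm]
    viable = sum(estimates) / len(estimates)
    if viable <= 0:
        raise ValueError("zero viable colonies at all dilutions")
    return AssayRates(revertant_colonies=revertants, viable_dilutions=norm,
                      viable_cells=viable, frequency=revertants / viable,
                      sd=sd)


def reintegration_ratio(freq_selected: float, freq_total: float) -> int:
    """Percent of excised elements that reintegrated, to the nearest
    integer (e.g. marker-retaining revertants / all revertants)."""
    if freq_total <= 0:
        raise ValueError("total frequency must be > 0")
    if freq_selected < 0:
        raise ValueError("selected frequency must be >= 0")
    return round(100.0 * freq_selected / freq_total)


def proportion(count: int, total: int) -> tuple[float, float]:
    """Percentage with its binomial standard error."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= count <= total:
        raise ValueError("count must be within [0, total]")
    p = count / total
    return 100.0 * p, 100.0 * math.sqrt(p * (1 - p) / total)


# ---------------------------------------------------------------------------
# footprint classification

@dataclass(frozen=True)
class DonorSite:
    """Reference description of the donor locus: the flanks around the
    inserted element, the donor TSD (None when absent), and the
    element's two 50-bp termini."""
    left_flank: str
    right_flank: str
    tsd: str | None
    element_termini: tuple[str, str]

    @property
    def empty_site(self) -> str:
        return self.left_flank + (self.tsd or "") + self.right_flank


@dataclass(frozen=True)
class FootprintCall:
    footprint_class: str          # precise | flank_deletion | insertion |
                                  # tir_remnant | complex
    left_bp_lost: int
    right_bp_lost: int
    remnant_len: int
    tsd_copies_remaining: int
    inserted_len: int = 0


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def _indel_placements(rev: str, ref: str) -> list[tuple[int, str]]:
    """All (offset, block) with rev == ref[:o] + block + ref[o:]."""
    d = len(rev) - len(ref)
    if d <= 0:
        return []
    out = []
    for o in range(len(ref) + 1):
        if rev[:o] == ref[:o] and rev[o + d:] == ref[o:]:
            out.append((o, rev[o:o + d]))
    return out


def classify_footprint(revertant_seq: str, donor: DonorSite,
                       element_termini: tuple[str, str] | None = None
                       ) -> FootprintCall:
    """Classify one revertant junction against the reconstructed empty
    donor site.

    The revertant is anchored to the reference by its outermost 12-mers
    (extra sequence beyond the stored flanks is ignored), then the
    discrepancy between the two is decomposed: bases missing from the
    reference are a flank deletion with per-side counts; extra bases
    matching a terminus prefix/suffix (<= 13 bp) are a TIR remnant;
    other extra bases are an insertion; mixtures are complex."""
    termini = element_termini or donor.element_termini
    rev = revertant_seq.upper()
    tl, tr = termini[0].upper(), termini[1].upper()
    if tl in rev and tr in rev:
        raise ExcisionError("element not excised: both termini present")
    ref = donor.empty_site.upper()
    tsd = (donor.tsd or "").upper()
    j0 = len(donor.left_flank)
    j1 = j0 + len(tsd)

    # anchor: clip revertant sequence extending beyond the reference
    a = rev.find(ref[:12])
    if a > 0:
        rev = rev[a:]
    b = rev.rfind(ref[-12:])
    if b != -1 and b + 12 < len(rev):
        rev = rev[:b + 12]
    # anchor the reference window onto the revertant (short reads)
    o = 0 if ref.startswith(rev[:12]) else max(0, ref.find(rev[:12]))
    e = len(ref)
    tail = ref.rfind(rev[-12:])
    if tail != -1:
        e = tail + 12
    window = ref[o:e]

    if len(rev) < 24:
        raise ValueError("revertant must cover at least 12 bp per side")

    p = _lcp(rev, window)
    s = _lcs(rev, window)
    cap = min(len(rev), len(window))
    if p + s > cap:
        s = cap - p
    gap_rev = rev[p:len(rev) - s]
    gap_ref = window[p:len(window) - s]

    def copies_remaining() -> int:
        if not tsd:
            return 0
        joint = rev[max(0, p - len(tsd) - 4):min(len(rev), p + len(tsd) + 4
                                                 + len(gap_rev))]
        return min(2, joint.count(tsd)) if joint else 0

    if not gap_rev and not gap_ref:
        return FootprintCall("precise", 0, 0, 0, 1 if tsd else 0)

    if not gap_rev:                       # bases deleted from the reference
        del_lo, del_hi = o + p, o + len(window) - s
        left_lost = max(0, min(del_hi, j0) - del_lo)
        right_lost = max(0, del_hi - max(del_lo, j1))
        tsd_hit = max(0, min(del_hi, j1) - max(del_lo, j0))
        if tsd_hit:
            mid = (j0 + j1) / 2
            left_lost += sum(1 for x in range(max(del_lo, j0),
                                              min(del_hi, j1)) if x < mid)
            right_lost += sum(1 for x in range(max(del_lo, j0),
                                               min(del_hi, j1)) if x >= mid)
        return FootprintCall("flank_deletion", left_lost, right_lost, 0,
                             1 if tsd and not tsd_hit else 0)

    if not gap_ref:                       # bases added to the reference
        placements = _indel_placements(rev, window)
        for _o, block in placements:
            n = len(block)
            if block == tl[:n] or block == tr[-n:]:
                if n <= MAX_REMNANT:
                    return FootprintCall("tir_remnant", 0, 0, n,
                                         copies_remaining(), inserted_len=n)
                return FootprintCall("complex", 0, 0, n, copies_remaining(),
                                     inserted_len=n)
        return FootprintCall("insertion", 0, 0, 0, copies_remaining(),
                             inserted_len=len(gap_rev))

    return FootprintCall("complex", 0, 0, 0, copies_remaining(),
                         inserted_len=len(gap_rev))


# ---------------------------------------------------------------------------
# transposon-display mapping

@dataclass(frozen=True)
class MappedLocus:
    status: str                   # mapped | ambiguous | unmapped
    scaffold: str | None = None
    pos: int | None = None
    strand: str | None = None


def map_display_read(read: str, genome: GenomeSet, terminus: str,
                     min_flank: int = 20, min_terminus: int = 12
                     ) -> MappedLocus:
    """Map a transposon-display read (terminus tail + genomic flank).

    The longest terminus suffix opening the read is trimmed; the
    remaining flank is searched exactly against both strands.  A unique
    hit maps; several hits are ambiguous; none is unmapped."""
    read = read.upper()
    terminus = terminus.upper()
    k = 0
    for n in range(min(len(terminus), len(read)), min_terminus - 1, -1):
        if read.startswith(terminus[-n:]):
            k = n
            break
    if k == 0:
        raise ValueError("read does not begin with the element terminus")
    flank = read[k:]
    if len(flank) < min_flank:
        raise ValueError(f"flank after trimming is {len(flank)} bp "
                         f"(< {min_flank})")
    locs: list[tuple[str, int, str]] = []
    rc = reverse_complement(flank)
    for scaffold, seq in genome.scaffolds.items():
        for query, strand in ((flank, "+"), (rc, "-")):
            i = seq.find(query)
            while i != -1:
                locs.append((scaffold, i, strand))
                i = seq.find(query, i + 1)
    if not locs:
        return MappedLocus("unmapped")
    if len(locs) > 1:
        return MappedLocus("ambiguous")
    scaffold, pos, strand = locs[0]
    return MappedLocus("mapped", scaffold, pos, strand)


# ---------------------------------------------------------------------------
# reinsertion TSDs

@dataclass(frozen=True)
class ReinsertionTsd:
    status: str                   # ok | excluded
    tsd: TsdAnnotation | None = None
    ambiguous: bool = False


def extract_reinsertion_tsd(locus, genome: GenomeSet, left_read_flank: str,
                            right_read_flank: str,
                            len_range: tuple[int, int] = (8, 10)
                            ) -> ReinsertionTsd:
    """TSD at a mapped reinsertion junction.

    The length is the longest perfect duplication between the two read
    flanks.  Both flanks must match the genome exactly; the overlap of
    their genomic spans independently implies a duplication length, and
    a disagreement with the string-based call (a coincidental extra
    matching base) sets the ambiguity flag."""
    left = left_read_flank.upper()
    right = right_read_flank.upper()
    scaffold = getattr(locus, "scaffold", None) or (
        locus[0] if isinstance(locus, tuple) else None)
    if scaffold is None or scaffold not in genome.scaffolds:
        return ReinsertionTsd("excluded")
    seq = genome.scaffolds[scaffold]
    li = seq.find(left)
    ri = seq.find(right)
    if li == -1 or ri == -1:
        return ReinsertionTsd("excluded")     # flanks disagree with genome
    if seq.find(left, li + 1) != -1 or seq.find(right, ri + 1) != -1:
        return ReinsertionTsd("excluded")
    t_coord = (li + len(left)) - ri
    tsd = call_tsd(left, right, len_range)
    if tsd is None:
        return ReinsertionTsd("ok", None, ambiguous=t_coord in
                              range(len_range[0], len_range[1] + 1))
    return ReinsertionTsd("ok", tsd, ambiguous=(tsd.length != t_coord))


def tsd_census(calls: list[ReinsertionTsd]) -> dict[int, int]:
    """Histogram of TSD lengths over usable reinsertion calls."""
    out: dict[int, int] = {}
    for c in calls:
        if c.status == "ok" and c.tsd is not None:
            out[c.tsd.length] = out.get(c.tsd.length, 0) + 1
    return out
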