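"""Genome-wide discovery of nonautonomous derivative elements.

Derivatives share the autonomous element's termini but carry variable
internal sequence.  Discovery is mismatch-bounded seed-and-extend on
the 50-bp termini (12-mer exact seeds), convergent end pairing, TSD
verification on 100-bp flanks, and Pack-MULE content classification by
local nucleotide alignment of the internal region against host coding
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import reverse_complement

from ._align import local_align_dna
from .annotator import TsdAnnotation, call_tsd
from .formats_io import GenomeSet

SEED_LEN = 12


@dataclass(frozen=True)
class EndHit:
    scaffold: str
    start: int
    end: int
    orientation: str       # 'fwd' = element 5' start, 'rev' = element 3' end
    mismatches: int


def _mismatches(a: str, b: str) -> int:
    return sum(x != y or x == "N" or y == "N" for x, y in zip(a, b))


def _scan_one(seq: str, pattern: str, max_mismatches: int) -> list[tuple[int, int]]:
    """All start positions where pattern matches seq with <= max
    mismatches, found via exact 12-mer seeds."""
    found: dict[int, int] = {}
    plen = len(pattern)
    for off in range(plen - SEED_LEN + 1):
        seed = pattern[off:off + SEED_LEN]
        if "N" in seed:
            continue
        i = seq.find(seed)
        while i != -1:
            start = i - off
            if start >= 0 and start + plen <= len(seq) and start not in found:
                mm = _mismatches(seq[start:start + plen], pattern)
                if mm <= max_mismatches:
                    found[start] = mm
            i = seq.find(seed, i + 1)
    return sorted(found.items())


def terminal_seed_search(genome: GenomeSet, terminus_50bp: str,
                         max_mismatches: int = 5) -> list[EndHit]:
    """Find all oriented occurrences of the element's 50-bp terminus.

    Forward occurrences are element 5' starts; occurrences of the
    reverse complement are element 3' ends."""
    if len(terminus_50bp) != 50:
        raise ValueError("terminus must be exactly 50 bp")
    term = terminus_50bp.upper()
    rc = reverse_complement(term)
    hits: list[EndHit] = []
    for scaffold, seq in genome.scaffolds.items():
        for start, mm in _scan_one(seq, term, max_mismatches):
            hits.append(EndHit(scaffold, start, start + 50, "fwd", mm))
        for start, mm in _scan_one(seq, rc, max_mismatches):
            hits.append(EndHit(scaffold, start, start + 50, "rev", mm))
    hits.sort(key=lambda h: (h.scaffold, h.start, h.orientation))
    return hits


@dataclass(frozen=True)
class CandidateInterval:
    scaffold: str
    span: tuple[int, int]
    left_hit: EndHit
    right_hit: EndHit
    nested: bool = False


def pair_ends(end_hits: list[EndHit], min_span: int = 100,
              max_span: int = 20000) -> list[CandidateInterval]:
    """Pair 5' starts with their closest convergent 3' ends.

    5' hits are processed innermost-first so nested elements resolve to
    inner-with-inner / outer-with-outer; each hit is used at most once.
    Candidates contained in another candidate are flagged nested (both
    are emitted, never merged)."""
    out: list[CandidateInterval] = []
    by_scf: dict[str, list[EndHit]] = {}
    for h in end_hits:
        by_scf.setdefault(h.scaffold, []).append(h)
    for scaffold, hits in by_scf.items():
        fwd = sorted([h for h in hits if h.orientation == "fwd"],
                     key=lambda h: -h.start)
        rev = sorted([h for h in hits if h.orientation == "rev"],
                     key=lambda h: h.start)
        used: set[int] = set()
        for lh in fwd:
            best = None
            for k, rh in enumerate(rev):
                if k in used or rh.start <= lh.start:
                    continue
                span = rh.end - lh.start
                if min_span <= span <= max_span:
                    best = k
                    break
            if best is not None:
                used.add(best)
                rh = rev[best]
                out.append(CandidateInterval(scaffold, (lh.start, rh.end),
                                             lh, rh))
    flagged = []
    for c in out:
        nested = any(o is not c and o.scaffold == c.scaffold
                     and o.span[0] <= c.span[0] and c.span[1] <= o.span[1]
                     for o in out)
        flagged.append(CandidateInterval(c.scaffold, c.span, c.left_hit,
                                         c.right_hit, nested))
    flagged.sort(key=lambda c: (c.scaffold, c.span))
    return flagged


@dataclass(frozen=True)
class PackHit:
    source_gene: str
    fragment_span: tuple[int, int]    # within the internal region
    identity: float
    length: int


@dataclass
class DerivativeElement:
    scaffold: str
    span: tuple[int, int]
    left_match: EndHit
    right_match: EndHit
    tsd: TsdAnnotation | None
    internal_span: tuple[int, int]
    internal_seq: str
    nested: bool = False
    pack_hits: list[PackHit] = field(default_factory=list)

    @property
    def tsd_verified(self) -> bool:
        return self.tsd is not None and self.tsd.perfect


def verify_and_annotate(candidates: list[CandidateInterval],
                        genome: GenomeSet, flank: int = 100,
                        tsd_len_range: tuple[int, int] = (8, 10)
                        ) -> list[DerivativeElement]:
    """Call TSDs on the candidates' flanks and build derivative records.

    A derivative is TSD-verified only when the duplication is perfect;
    everything else is reported unverified."""
    out: list[DerivativeElement] = []
    for c in candidates:
        start, end = c.span
        left = genome.fetch(c.scaffold, start - flank, start)
        right = genome.fetch(c.scaffold, end, end + flank)
        tsd = call_tsd(left, right, tsd_len_range)
        internal = (c.left_hit.end, c.right_hit.start)
        out.append(DerivativeElement(
            scaffold=c.scaffold, span=c.span, left_match=c.left_hit,
            right_match=c.right_hit, tsd=tsd, internal_span=internal,
            internal_seq=genome.fetch(c.scaffold, *internal),
            nested=c.nested))
    return out


def classify_pack_content(derivative: DerivativeElement,
                          host_cds_set: dict[str, str],
                          min_identity: float = 0.70,
                          min_len: int = 100) -> list[PackHit]:
    """Align the internal region against each host CDS; report hits with
    identity >= ``min_identity`` over >= ``min_len`` aligned bp.
    Multiple non-overlapping fragments per CDS are found by masking."""
    internal = derivative.internal_seq
    hits: list[PackHit] = []
    if len(internal) < 50:
        return hits
    for gid, cds in host_cds_set.items():
        subject = list(internal)
        for _ in range(10):
            aln = local_align_dna(cds, "".join(subject))
            if aln.score <= 0 or aln.length < min_len:
                break
            if aln.identity >= min_identity:
                s0, s1 = aln.subject_span
                hits.append(PackHit(source_gene=gid,
                                    fragment_span=(s0, s1),
                                    identity=round(aln.identity, 4),
                                    length=aln.length))
                for i in range(s0, s1):
                    subject[i] = "N"
            else:
                break
    derivative.pack_hits = sorted(hits, key=lambda h: (-h.length, h.source_gene))
    return derivative.pack_hits


def census(derivatives: list[DerivativeElement]) -> dict[str, int]:
    """Census counts: all candidates vs perfect-TSD verified, split by
    TSD length, plus how many carry pack content."""
    verified = [d for d in derivatives if d.tsd_verified]
    return {
        "candidates": len(derivatives),
        "tsd_verified": len(verified),
        "tsd8": sum(d.tsd.length == 8 for d in verified),
        "tsd9": sum(d.tsd.length == 9 for d in verified),
        "pack": sum(bool(d.pack_hits) for d in derivatives),
    }
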