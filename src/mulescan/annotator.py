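"""Structural annotation of candidate elements.

Turns a genomic interval (typically around a translated DDE hit) into a
fully annotated element: boundaries from a paired copy, terminal
inverted repeats, target-site duplication, subterminal tandem repeats,
the terminal palindrome profile, and the coding span containing the
catalytic domain.

Coordinates are 0-based half-open throughout.  TSD calls are exact-match
only: the longest perfect duplication in the allowed length range wins
(a 9-bp duplication containing an 8-bp one is one 9-bp TSD).  Imperfect
duplications can be reported but carry ``perfect=False`` and are never
counted as TSDs downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import reverse_complement

from ._align import global_align_dna, extend_align_dna, local_align_protein

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class BoundaryError(ValueError):
    """Raised when two copies cannot resolve an element boundary."""


@dataclass(frozen=True)
class TirAnnotation:
    length: int
    identity: float


@dataclass(frozen=True)
class TsdAnnotation:
    length: int
    left: str
    right: str
    perfect: bool = True


@dataclass(frozen=True)
class SubrepeatAnnotation:
    unit_len: int
    unit: str                # consensus unit
    copies: int
    spacers: tuple[int, ...]


@dataclass(frozen=True)
class PalindromeAnnotation:
    motif: str
    unpaired: tuple[int, ...]     # 1-based positions within the 10-mer


@dataclass(frozen=True)
class CodingAnnotation:
    orf_span: tuple[int, int]         # element-relative
    domain_span: tuple[int, int]
    strand: str
    dde_offsets: tuple[int, int, int] | None
    interrupted: bool
    single_orf_approximation: bool = True


@dataclass
class AnnotatedElement:
    scaffold: str
    span: tuple[int, int]
    tir: TirAnnotation | None = None
    tsd: TsdAnnotation | None = None
    subrepeats: SubrepeatAnnotation | None = None
    palindrome: PalindromeAnnotation | None = None
    coding: CodingAnnotation | None = None
    id: str = "element"


# ---------------------------------------------------------------------------
# boundary detection

def detect_boundaries(copy_a: str, copy_b: str, window: int = 20,
                      min_identity: float = 0.8, min_run: int = 6
                      ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Locate the shared-element boundaries of two copies of the same
    family embedded in unrelated flanking sequence.

    The two sequences are globally aligned; the element appears as the
    maximal block of alignment columns whose ``window``-column identity
    stays at or above ``min_identity``, refined to the first/last run of
    ``min_run`` consecutive matching columns.  Returns the (start, end)
    offsets of the element in each copy.  Raises :class:`BoundaryError`
    if the sequences are similar end to end (same-locus duplicates).
    """
    if not copy_a or not copy_b:
        raise ValueError("empty sequence")
    # harsh mismatch/gap costs keep the shared element on a strict
    # diagonal; cheap gaps would let flanking noise steal edge bases
    _, aa, ab = global_align_dna(copy_a, copy_b, match=1, mismatch=-2, gap=4)
    ncol = len(aa)
    match = np.array([a == b and a != "-" and a != "N"
                      for a, b in zip(aa, ab)], dtype=float)
    if ncol < window:
        raise BoundaryError("sequences too short to profile")
    csum = np.concatenate([[0.0], np.cumsum(match)])
    wid = (csum[window:] - csum[:-window]) / window    # per window start
    good = np.where(wid >= min_identity)[0]
    if good.size == 0:
        raise BoundaryError("no similar block found")
    if good.size >= 0.95 * wid.size:
        raise BoundaryError("cannot resolve boundary: copies are similar "
                            "over their whole length (same locus?)")
    c0, c1 = int(good[0]), int(good[-1]) + window      # candidate columns

    def _first_run(lo: int, hi: int, step: int) -> int:
        run = 0
        rng = range(lo, hi, step)
        for c in rng:
            run = run + 1 if match[c] else 0
            if run >= min_run:
                return c - (min_run - 1) * (1 if step > 0 else -1)
        raise BoundaryError("no unambiguous boundary run found")

    left = _first_run(c0, c1, 1)
    right = _first_run(c1 - 1, c0 - 1, -1) + 1          # half-open column end

    # map alignment columns to sequence offsets
    pos_a = np.cumsum([c != "-" for c in aa])           # chars consumed after col
    pos_b = np.cumsum([c != "-" for c in ab])
    sa, ea = int(pos_a[left] - (aa[left] != "-")), int(pos_a[right - 1])
    sb, eb = int(pos_b[left] - (ab[left] != "-")), int(pos_b[right - 1])
    # extend outward over directly equal bases: equally-scoring global
    # alignments can desynchronize the last few shared columns, and the
    # boundary is the outermost position where similarity collapses
    while ea < len(copy_a) and eb < len(copy_b) \
            and copy_a[ea] == copy_b[eb] and copy_a[ea] != "N":
        ea += 1
        eb += 1
    while sa > 0 and sb > 0 and copy_a[sa - 1] == copy_b[sb - 1] \
            and copy_a[sa - 1] != "N":
        sa -= 1
        sb -= 1
    return (sa, ea), (sb, eb)


# ---------------------------------------------------------------------------
# terminal inverted repeats

def find_tir(element: str, min_len: int = 50, min_identity: float = 0.8,
             anchor_slack: int = 5, min_run: int = 6) -> TirAnnotation | None:
    """Find the terminal inverted repeat of an element.

    The 5' prefix is aligned against the reverse complement of the 3'
    suffix (search window ``min(len/2, 1000)`` bp) by anchored extension
    from every start offset within ``anchor_slack`` of the termini.  The
    aligned arm is trimmed back to the end of its last ``min_run``
    consecutive matches (so stray matches in the flanking sequence do
    not inflate the repeat), and the longest arm with identity >=
    ``min_identity`` is reported."""
    if len(element) < 2 * min_len:
        return None
    w = min(len(element) // 2, 1000)
    prefix = element[:w]
    suffix_rc = reverse_complement(element[-w:])
    best: tuple[int, float] | None = None
    for a in range(anchor_slack + 1):
        for b in range(anchor_slack + 1):
            # stiff mismatch/gap costs keep the arm aligned strictly
            # diagonally; stray similarity past the repeat cannot pay
            # for a realignment that steals terminal arm bases
            aln = extend_align_dna(prefix[a:], suffix_rc[b:],
                                   match=1, mismatch=-2, gap=4)
            if aln.length == 0:
                continue
            cols = [(x != "-" and x == y and x != "N", x != "-")
                    for x, y in zip(aln.aligned_query, aln.aligned_subject)]
            # trim to the end of the last run of min_run consecutive matches
            run = 0
            end = 0
            for c, (is_match, _) in enumerate(cols, start=1):
                run = run + 1 if is_match else 0
                if run >= min_run:
                    end = c
            if end == 0:
                continue
            matches = sum(m for m, _ in cols[:end])
            consumed_q = sum(q for _, q in cols[:end])
            ident = matches / end
            length = consumed_q + a
            if ident < min_identity or length < min_len:
                continue
            if (best is None or length > best[0]
                    or (length == best[0] and ident > best[1])):
                best = (length, ident)
    if best is None:
        return None
    return TirAnnotation(length=best[0], identity=round(best[1], 4))


# ---------------------------------------------------------------------------
# target-site duplication

def call_tsd(left_flank: str, right_flank: str,
             len_range: tuple[int, int] = (8, 10),
             report_imperfect: bool = False) -> TsdAnnotation | None:
    """Call the TSD as the longest k in ``len_range`` whose k-suffix of
    the left flank equals the k-prefix of the right flank exactly
    (nested shorter duplications are suppressed).  With
    ``report_imperfect`` a one-mismatch candidate may be returned with
    ``perfect=False``; it is never a TSD proper."""
    lo, hi = len_range
    for k in range(hi, lo - 1, -1):
        if len(left_flank) < k or len(right_flank) < k:
            continue
        ls, rs = left_flank[-k:], right_flank[:k]
        if "N" not in ls and ls == rs:
            return TsdAnnotation(k, ls, rs, perfect=True)
    if report_imperfect:
        for k in range(hi, lo - 1, -1):
            if len(left_flank) < k or len(right_flank) < k:
                continue
            ls, rs = left_flank[-k:], right_flank[:k]
            mism = sum(a != b or a == "N" or b == "N" for a, b in zip(ls, rs))
            if mism == 1:
                return TsdAnnotation(k, ls, rs, perfect=False)
    return None


# ---------------------------------------------------------------------------
# subterminal tandem repeats

def _unit_mismatches(a: str, b: str) -> int:
    return sum(x != y or x == "N" or y == "N" for x, y in zip(a, b))


def find_subterminal_repeats(tir_arm: str,
                             unit_range: tuple[int, int] = (9, 15),
                             min_copies: int = 3, max_spacer: int = 6,
                             max_mismatch_per_copy: int = 1
                             ) -> SubrepeatAnnotation | None:
    """Detect tandem subterminal repeats inside a TIR arm.

    Every unit length in ``unit_range`` and every start phase seeds a
    greedy chain: successive copies may be separated by 0..``max_spacer``
    bp and each may differ from the seed unit by at most
    ``max_mismatch_per_copy``.  The chain maximizing
    copies x unit_len - 2 x mismatches wins (ties: shorter unit, then
    earlier start); the mismatch penalty keeps a unit from absorbing
    spacer bases, which would chain with one mismatch per copy."""
    best = None   # ((score, -u, -s), copy_seqs, spacers, s, u)
    n = len(tir_arm)
    for u in range(unit_range[0], unit_range[1] + 1):
        if u * min_copies > n:
            continue
        for s in range(0, n - u * min_copies + 1):
            unit = tir_arm[s:s + u]
            copies = [unit]
            spacers: list[int] = []
            pos = s + u
            n_mismatch = 0
            while True:
                nxt = None
                for sp in range(0, max_spacer + 1):
                    cand = tir_arm[pos + sp:pos + sp + u]
                    if len(cand) < u:
                        break
                    mm = _unit_mismatches(cand, unit)
                    if mm <= max_mismatch_per_copy:
                        nxt = (sp, cand, mm)
                        break
                if nxt is None:
                    break
                spacers.append(nxt[0])
                copies.append(nxt[1])
                n_mismatch += nxt[2]
                pos += nxt[0] + u
            if len(copies) < min_copies:
                continue
            key = (len(copies) * u - 2 * n_mismatch, -u, -s)
            if best is None or key > best[0]:
                best = (key, copies, tuple(spacers), s, u)
    if best is None:
        return None
    _, copies, spacers, _s, u = best
    cons = "".join(
        max("ACGT", key=lambda b: sum(c[i] == b for c in copies))
        for i in range(u))
    return SubrepeatAnnotation(unit_len=u, unit=cons, copies=len(copies),
                               spacers=spacers)


# ---------------------------------------------------------------------------
# terminal palindrome

def score_terminal_palindrome(terminal: str) -> tuple[int, ...]:
    """Return the 1-based unpaired positions of a 10-bp terminal motif.

    Position i (1..5) pairs with 11-i iff the bases are Watson-Crick
    complements; both members of a failed pair are reported.  Non-ACGT
    bases are always unpaired."""
    if len(terminal) != 10:
        raise ValueError("terminal motif must be exactly 10 bases")
    unpaired: set[int] = set()
    t = terminal.upper()
    for i in range(1, 6):
        j = 11 - i
        a, b = t[i - 1], t[j - 1]
        if a not in _COMP or b not in _COMP or _COMP[a] != b:
            unpaired.update((i, j))
    return tuple(sorted(unpaired))


# ---------------------------------------------------------------------------
# coding span

def locate_orf_dde(element: str, dde_query: str,
                   triad_offsets: tuple[int, int, int] | None = None,
                   min_score: int = 60) -> CodingAnnotation | None:
    """Locate the catalytic domain by translated local alignment and
    report the longest stop-free reading segment overlapping it.

    Multi-exon structure is not inferred (single-ORF approximation);
    a stop codon inside the aligned domain sets ``interrupted``.
    """
    from .homology import six_frame_translate

    if len(element) < 300:
        return None
    frames = six_frame_translate(element)
    best = None
    for fr in frames:
        if not fr.peptide:
            continue
        aln = local_align_protein(dde_query, fr.peptide)
        if best is None or aln.score > best[1].score:
            best = (fr, aln)
    if best is None or best[1].score < min_score:
        return None
    fr, aln = best
    s0, s1 = aln.subject_span
    domain_span = fr.to_genomic(s0, s1)
    # longest stop-free segment of this frame overlapping the domain
    pep = fr.peptide
    seg_start = 0
    segments = []
    for i, c in enumerate(pep + "*"):
        if c == "*":
            if i > seg_start:
                segments.append((seg_start, i))
            seg_start = i + 1
    overlapping = [seg for seg in segments if seg[0] < s1 and seg[1] > s0]
    if overlapping:
        orf_pep = max(overlapping, key=lambda t: t[1] - t[0])
    else:
        orf_pep = (s0, s1)
    orf_span = fr.to_genomic(orf_pep[0], orf_pep[1])
    interrupted = "*" in pep[s0:s1] or not (
        orf_pep[0] <= s0 and orf_pep[1] >= s1)

    dde = None
    if triad_offsets is not None:
        positions = []
        qi, si = aln.query_span[0], s0
        want = {off: None for off in triad_offsets}
        for x, y in zip(aln.aligned_query, aln.aligned_subject):
            if qi in want and x != "-" and y != "-":
                want[qi] = fr.to_genomic(si, si + 1)[0] if fr.strand == "+" \
                    else fr.to_genomic(si, si + 1)[1] - 3
            if x != "-":
                qi += 1
            if y != "-":
                si += 1
        if all(v is not None for v in want.values()):
            positions = [want[off] for off in triad_offsets]
            dde = tuple(positions)
    return CodingAnnotation(orf_span=orf_span, domain_span=domain_span,
                            strand=fr.strand, dde_offsets=dde,
                            interrupted=bool(interrupted))


# ---------------------------------------------------------------------------
# one-stop annotation

def annotate_element(genome, scaffold: str, span: tuple[int, int],
                     dde_query: str | None = None,
                     triad_offsets: tuple[int, int, int] | None = None,
                     flank: int = 20, element_id: str = "element",
                     tir_kwargs: dict | None = None) -> AnnotatedElement:
    """Annotate an element interval: TIR, TSD, subterminal repeats,
    terminal palindrome, and (if a query is given) the coding span."""
    start, end = span
    seq = genome.fetch(scaffold, start, end)
    left = genome.fetch(scaffold, start - flank, start)
    right = genome.fetch(scaffold, end, end + flank)
    tir = find_tir(seq, **(tir_kwargs or {}))
    tsd = call_tsd(left, right)
    sub = pal = None
    if tir is not None:
        sub = find_subterminal_repeats(seq[:tir.length])
        pal = PalindromeAnnotation(seq[:10],
                                   score_terminal_palindrome(seq[:10]))
    coding = None
    if dde_query is not None:
        coding = locate_orf_dde(seq, dde_query, triad_offsets)
    return AnnotatedElement(scaffold=scaffold, span=span, tir=tir, tsd=tsd,
                            subrepeats=sub, palindrome=pal, coding=coding,
                            id=element_id)
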