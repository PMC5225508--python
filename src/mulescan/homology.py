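"""Translated homology search for the transposase catalytic (DDE) domain.

All six reading frames of every scaffold are scanned with local
affine-gap Smith–Waterman against a peptide query.  Significance uses a
Karlin–Altschul surrogate ``E = K * m * n * exp(-lambda * S)`` with the
standard gapped BLOSUM62/11,1 constants (lambda = 0.267, K = 0.041) and
``n`` the total genome length in bp; any monotone surrogate preserves
the filtering semantics of an E-value cutoff, and fixed constants keep
results deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Seq import Seq, reverse_complement

from ._align import local_align_protein
from .formats_io import GenomeSet

KA_LAMBDA = 0.267
KA_K = 0.041

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class FrameTranslation:
    strand: str                  # '+' or '-'
    frame: int                   # 0, 1, 2
    peptide: str
    seq_len: int                 # length of the source DNA

    def to_genomic(self, pep_start: int, pep_end: int) -> tuple[int, int]:
        """Map a peptide slice back to forward-strand DNA coordinates
        (0-based half-open; always a multiple of 3 long)."""
        s, e = self.frame + 3 * pep_start, self.frame + 3 * pep_end
        if self.strand == "+":
            return s, e
        return self.seq_len - e, self.seq_len - s


def six_frame_translate(seq: str) -> list[FrameTranslation]:
    """Translate all six frames; stops are '*', ambiguous codons 'X'."""
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-ACGTN symbols in sequence: {sorted(bad)}")
    out: list[FrameTranslation] = []
    rc = reverse_complement(seq)
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            sub = s[frame:]
            sub = sub[:len(sub) - len(sub) % 3]
            pep = str(Seq(sub).translate()) if sub else ""
            out.append(FrameTranslation(strand, frame, pep, len(seq)))
    return out


@dataclass(frozen=True)
class TranslatedHit:
    scaffold: str
    span: tuple[int, int]        # forward-strand, 0-based half-open
    strand: str
    frame: int
    score: int
    evalue: float
    subject_peptide: str


def surrogate_evalue(score: int, query_len: int, db_len: int) -> float:
    return KA_K * query_len * db_len * math.exp(-KA_LAMBDA * score)


def search_dde(genome: GenomeSet, query: str, evalue_cutoff: float = 1e-3,
               gap_open: int = 11, gap_extend: int = 1,
               max_hits_per_frame: int = 100) -> list[TranslatedHit]:
    """Scan every frame of every scaffold for the query domain.

    Hits are collected iteratively: the best local alignment is
    recorded, its subject segment masked, and the frame re-searched
    until the surrogate E-value exceeds the cutoff.  The result is
    sorted by score (descending)."""
    if len(query) < 30:
        raise ValueError("query must be at least 30 residues")
    n_db = genome.total_length
    hits: list[TranslatedHit] = []
    if n_db == 0:
        return hits
    for scaffold, seq in genome.scaffolds.items():
        if len(seq) < 3:
            continue
        for fr in six_frame_translate(seq):
            subject = list(fr.peptide)
            for _ in range(max_hits_per_frame):
                aln = local_align_protein(query, "".join(subject),
                                          gap_open=gap_open,
                                          gap_extend=gap_extend)
                if aln.score <= 0:
                    break
                e = surrogate_evalue(aln.score, len(query), n_db)
                if e > evalue_cutoff:
                    break
                s0, s1 = aln.subject_span
                span = fr.to_genomic(s0, s1)
                hits.append(TranslatedHit(
                    scaffold=scaffold, span=span, strand=fr.strand,
                    frame=fr.frame, score=aln.score, evalue=e,
                    subject_peptide=fr.peptide[s0:s1]))
                for i in range(s0, s1):
                    subject[i] = "X"
    hits.sort(key=lambda h: (-h.score, h.scaffold, h.span))
    return hits


def dedup_hits(hits: list[TranslatedHit],
               reciprocal_overlap: float = 0.5) -> list[TranslatedHit]:
    """Greedy duplicate removal: keep the best-scoring hit, drop any
    later hit overlapping a kept hit on the same scaffold and strand by
    at least ``reciprocal_overlap`` of both spans."""
    ordered = sorted(hits, key=lambda h: (-h.score, h.scaffold, h.span))
    kept: list[TranslatedHit] = []
    for h in ordered:
        redundant = False
        for k in kept:
            if h.scaffold != k.scaffold or h.strand != k.strand:
                continue
            ov = (min(h.span[1], k.span[1]) - max(h.span[0], k.span[0]))
            if ov <= 0:
                continue
            la, lb = h.span[1] - h.span[0], k.span[1] - k.span[0]
            if ov >= reciprocal_overlap * la and ov >= reciprocal_overlap * lb:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def hits_table(hits: list[TranslatedHit]) -> "object":
    """Hit list as a pandas DataFrame (for TSV export)."""
    import pandas as pd

    return pd.DataFrame(
        [{"scaffold": h.scaffold, "start": h.span[0], "end": h.span[1],
          "strand": h.strand, "frame": h.frame, "score": h.score,
          "evalue": h.evalue} for h in hits])
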