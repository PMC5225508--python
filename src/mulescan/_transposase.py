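"""A fixed synthetic MULE-like transposase used by the genome generator.

The peptide is 504 residues with the catalytic DDE triad at residues
214, 283 and 419 (1-based) — the positions reported for the active
mosquito element this package models.  The sequence itself is synthetic:
it is drawn once from a fixed random stream, so it is a deterministic
package constant, not any real gene.  A fixed one-codon-per-residue
back-translation gives the matching CDS.
"""

from __future__ import annotations

import numpy as np

TRANSPOSASE_LEN = 504
# 1-based residue positions of the catalytic triad
DDE_RESIDUES = (214, 283, 419)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "TTA", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


def _build_peptide() -> str:
    rng = np.random.default_rng(8404)
    aas = [_AA20[i] for i in rng.integers(0, 20, size=TRANSPOSASE_LEN)]
    aas[0] = "M"
    r1, r2, r3 = DDE_RESIDUES
    aas[r1 - 1] = "D"
    aas[r2 - 1] = "D"
    aas[r3 - 1] = "E"
    return "".join(aas)


TRANSPOSASE_PEPTIDE: str = _build_peptide()
TRANSPOSASE_CDS: str = "".join(_CODON[a] for a in TRANSPOSASE_PEPTIDE) + "TAA"

# DDE catalytic-domain query: residues 180..440 (1-based, inclusive),
# comfortably spanning the triad.
DOMAIN_START, DOMAIN_END = 180, 440


def dde_domain_query() -> tuple[str, tuple[int, int, int]]:
    """Return (domain peptide, 0-based offsets of the D/D/E within it)."""
    pep = TRANSPOSASE_PEPTIDE[DOMAIN_START - 1:DOMAIN_END]
    offs = tuple(r - DOMAIN_START for r in DDE_RESIDUES)
    return pep, offs  # type: ignore[return-value]
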