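"""Synthetic genomes, annotations and assay fixtures.

The generator plants MULE-like elements with the exact structure the
annotation stack assumes — long TIRs opening with a 10-bp imperfect
terminal palindrome, tandem subterminal repeats with short spacers, a
transposase ORF carrying a D..D..E triad, and an 8/9-bp target-site
duplication created by copying the bases at the insertion point — into
i.i.d. uniform-ACGT background, and emits a machine-readable truth
table for recall/precision testing.

Everything is driven by one integer seed; submodule streams are derived
from it by fixed offsets, so identical seeds give byte-identical output.

Fixture-disambiguation note: planted TSDs and footprint junctions are
locally adjusted (a background base resampled, an inserted block
redrawn) so that the exact-match rules downstream have a unique reading.
Real loci can be ambiguous; the truth table is meant to be exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import reverse_complement

from ._transposase import (DDE_RESIDUES, TRANSPOSASE_CDS, dde_domain_query)
from .assay import DonorSite
from .formats_io import Gene, GeneSet, GenomeSet

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _substream(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(offset)])


def random_genome(n_scaffolds: int = 1, scaffold_len: int = 100_000,
                  seed: int = 0) -> GenomeSet:
    """Pure uniform-ACGT background genome with no planted structure."""
    rng = _substream(seed, 99)
    return GenomeSet({f"scf{i + 1}": _rand_dna(rng, scaffold_len)
                      for i in range(n_scaffolds)})


# ---------------------------------------------------------------------------
# element template and construction

@dataclass(frozen=True)
class ElementTemplate:
    """Structural parameters of a plantable autonomous element.

    Defaults mirror the active mosquito element the package models:
    3198 bp, 145-bp TIRs opening with a 10-bp terminal palindrome whose
    5th/6th bases are unpaired, nine copies of a 12-bp subterminal
    repeat with 3-4 bp spacers, a two-exon transposase ORF, 9-bp TSD.
    """

    total_len: int = 3198
    tir_len: int = 145
    tsd_len: int = 9
    palindrome_unpaired: frozenset = frozenset({5, 6})
    subrepeat_unit_len: int = 12
    subrepeat_copies: int = 9
    spacer_len_range: tuple[int, int] = (3, 4)
    n_exons: int = 2
    family_divergence: int = 0

    def __post_init__(self) -> None:
        if self.tsd_len not in (8, 9):
            raise ValueError("tsd_len must be 8 or 9")
        for i in self.palindrome_unpaired:
            if not 1 <= i <= 10:
                raise ValueError("palindrome positions are 1..10")
            if 11 - i not in self.palindrome_unpaired:
                raise ValueError("unpaired positions must come in (i, 11-i) pairs")
        need = 10 + (self.subrepeat_copies * self.subrepeat_unit_len
                     + max(0, self.subrepeat_copies - 1) * self.spacer_len_range[0])
        if need > self.tir_len:
            raise ValueError(
                f"subterminal repeat structure needs {need} bp but TIR is "
                f"{self.tir_len} bp")


@dataclass
class ElementCore:
    """A concrete element sequence plus its ground-truth substructure."""

    seq: str
    template: ElementTemplate
    palindrome_motif: str
    subrepeat_unit: str
    spacers: list[int]
    orf_spans: list[tuple[int, int]]      # element-relative, half-open
    dde_offsets: tuple[int, int, int]     # element-relative codon starts

    @property
    def terminus(self) -> str:
        return self.seq[:50]


def _build_palindrome(rng: np.random.Generator,
                      unpaired: frozenset) -> str:
    b = [""] * 10
    for i in range(1, 6):
        j = 11 - i
        b[i - 1] = _BASES[rng.integers(0, 4)]
        comp = _COMP[b[i - 1]]
        if i in unpaired:
            choices = [x for x in _BASES if x != comp]
            b[j - 1] = choices[rng.integers(0, 3)]
        else:
            b[j - 1] = comp
    return "".join(b)


def _build_tir_arm(template: ElementTemplate, rng: np.random.Generator
                   ) -> tuple[str, str, str, list[int]]:
    motif = _build_palindrome(rng, template.palindrome_unpaired)
    unit = _rand_dna(rng, template.subrepeat_unit_len)
    lo, hi = template.spacer_len_range
    spacers = [int(rng.integers(lo, hi + 1))
               for _ in range(max(0, template.subrepeat_copies - 1))]
    used = 10 + template.subrepeat_copies * len(unit) + sum(spacers)
    i = 0
    while used > template.tir_len:
        if spacers[i % len(spacers)] > lo:
            spacers[i % len(spacers)] -= 1
            used -= 1
        i += 1
        if i > 10 * max(1, len(spacers)) and used > template.tir_len:
            raise ValueError("cannot fit subterminal repeats inside TIR")
    # Spacer boundary bases are drawn under a balance constraint: among
    # the bases immediately preceding (and following) the repeat copies
    # no single base may occur more than 3 times.  Without this, a run
    # of same-base spacer ends makes a unit+1 phase reading (one
    # mismatch per copy) genuinely outscore the planted unit, and the
    # truth table would misstate the repeat length.
    for _try in range(500):
        sp_seqs = [_rand_dna(rng, s) for s in spacers]
        pad = _rand_dna(rng, template.tir_len - 10
                        - template.subrepeat_copies * len(unit) - sum(spacers))
        pre_chars = [motif[-1]] + [s[-1] for s in sp_seqs if s]
        post_chars = [s[0] for s in sp_seqs if s] + ([pad[0]] if pad else [])
        if (max(pre_chars.count(b) for b in _BASES) <= 3
                and max(post_chars.count(b) for b in _BASES) <= 3):
            break
    parts = [motif]
    for c in range(template.subrepeat_copies):
        parts.append(unit)
        if c < template.subrepeat_copies - 1:
            parts.append(sp_seqs[c])
    arm = "".join(parts) + pad
    assert len(arm) == template.tir_len
    return arm, motif, unit, spacers


def build_element(template: ElementTemplate, rng: np.random.Generator
                  ) -> ElementCore:
    """Assemble one autonomous element sequence from a template."""
    arm, motif, unit, spacers = _build_tir_arm(template, rng)
    cds = TRANSPOSASE_CDS
    if template.n_exons >= 2:
        exon1, intron_len = 120, 80
        intron = "GT" + _rand_dna(rng, intron_len - 4) + "AG"
        coding = cds[:exon1] + intron + cds[exon1:]
    else:
        exon1, intron_len = len(cds), 0
        coding = cds
    internal_len = template.total_len - 2 * template.tir_len
    if internal_len < len(coding) + 20:
        raise ValueError("element too short for transposase ORF")
    pad_total = internal_len - len(coding)
    pre = int(rng.integers(10, pad_total - 9))
    post = pad_total - pre
    seq = list(arm + _rand_dna(rng, pre) + coding + _rand_dna(rng, post)
               + reverse_complement(arm))
    # the TIR must not extend by a coincidentally complementary base,
    # or the element would truly carry a longer repeat than declared
    t = template.tir_len
    if seq[t] == _COMP[seq[-t - 1]]:
        seq[t] = [b for b in _BASES
                  if b != _COMP[seq[-t - 1]]][int(rng.integers(0, 3))]
    seq = "".join(seq)
    cstart = template.tir_len + pre

    def genomic(cds_pos: int) -> int:
        off = intron_len if (template.n_exons >= 2 and cds_pos >= exon1) else 0
        return cstart + cds_pos + off

    dde = tuple(genomic((r - 1) * 3) for r in DDE_RESIDUES)
    if template.n_exons >= 2:
        orf_spans = [(cstart, cstart + exon1),
                     (cstart + exon1 + intron_len, cstart + len(coding))]
    else:
        orf_spans = [(cstart, cstart + len(cds))]
    assert len(seq) == template.total_len
    return ElementCore(seq, template, motif, unit, spacers, orf_spans, dde)  # type: ignore[arg-type]


def _diverge(core: ElementCore, n_subs: int, rng: np.random.Generator) -> str:
    """Apply up to n_subs substitutions in noncoding internal DNA."""
    if n_subs <= 0:
        return core.seq
    t = core.template
    protected = [(0, t.tir_len), (len(core.seq) - t.tir_len, len(core.seq))]
    protected += core.orf_spans
    allowed = [i for i in range(len(core.seq))
               if not any(s <= i < e for s, e in protected)]
    seq = list(core.seq)
    for i in rng.choice(len(allowed), size=min(n_subs, len(allowed)),
                        replace=False):
        pos = allowed[int(i)]
        seq[pos] = [b for b in _BASES if b != seq[pos]][int(rng.integers(0, 3))]
    return "".join(seq)


# ---------------------------------------------------------------------------
# truth table

@dataclass(frozen=True)
class PlantedElement:
    id: str
    scaffold: str
    span: tuple[int, int]            # final (post-insertion) coordinates
    kind: str                        # full | derivative | pack
    tsd_seq: str | None
    tsd_perfect: bool
    tir_len: int                     # left-arm length (truncated for derivatives)
    tir_len_right: int
    genic: bool
    host_fragment_source: str | None = None
    dde_offsets: tuple[int, int, int] | None = None


@dataclass
class TruthTable:
    planted: list[PlantedElement] = field(default_factory=list)

    def of_kind(self, *kinds: str) -> list[PlantedElement]:
        return [p for p in self.planted if p.kind in kinds]

    @property
    def genic_fraction(self) -> float:
        return sum(p.genic for p in self.planted) / len(self.planted)


# ---------------------------------------------------------------------------
# TSD helpers

def _longest_dup(left: str, right: str, lo: int = 8, hi: int = 10) -> int:
    """Longest k in [lo, hi] with k-suffix(left) == k-prefix(right); 0 if none."""
    best = 0
    for k in range(lo, hi + 1):
        if len(left) >= k and len(right) >= k and left[-k:] == right[:k]:
            best = k
    return best


def _fix_tsd_context(bg: list[str], p: int, k: int) -> None:
    """Resample bases after p until the duplication of bg[p-k:p] reads as
    exactly k bp (no coincidental longer match)."""
    dup = "".join(bg[p - k:p])
    for _ in range(40):
        left = "".join(bg[max(0, p - 12):p])
        right = dup + "".join(bg[p:p + 12])
        if _longest_dup(left, right) == k:
            return
        j = _longest_dup(left, right)
        x = p + (j - k - 1)             # right-continuation base to break
        bg[x] = _COMP[bg[x]]
    raise RuntimeError("could not disambiguate TSD context")


# ---------------------------------------------------------------------------
# genome generation

def generate_genome(template: ElementTemplate | None = None,
                    n_scaffolds: int = 4, scaffold_len: int = 120_000,
                    n_full_copies: int = 7, n_derivatives: int = 8,
                    n_genes: int | None = None,
                    genic_insert_frac: float = 0.643, seed: int = 0, *,
                    window: int = 5000, derivative_tsd_frac: float = 1.0,
                    pack_frac: float = 0.2,
                    derivative_internal_range: tuple[int, int] = (100, 1500),
                    derivative_tir_frac_range: tuple[float, float] = (0.5, 1.0),
                    pack_identity: float = 0.975, pack_fragment_len: int = 276,
                    ) -> tuple[GenomeSet, GeneSet, TruthTable]:
    """Plant full-length elements and derivatives into a synthetic genome.

    A fraction ``genic_insert_frac`` of planted sites is placed in gene
    bodies or within ``window`` bp of a gene; the remainder is kept more
    than ``window`` bp from every gene.  TSDs are created by duplicating
    the 8 or 9 bp at the insertion point.  Returns the genome, its gene
    annotation, and the truth table of planted elements.
    """
    template = template or ElementTemplate()
    if not 0.0 <= genic_insert_frac <= 1.0:
        raise ValueError("genic_insert_frac must be in [0, 1]")
    if min(n_scaffolds, scaffold_len, n_full_copies, n_derivatives) < 0:
        raise ValueError("counts must be >= 0")

    rng_bg = _substream(seed, 1)
    rng_el = _substream(seed, 2)
    rng_place = _substream(seed, 3)
    rng_gene = _substream(seed, 4)

    n_sites = n_full_copies + n_derivatives
    margin = window + 2500
    slot = template.total_len + 2 * margin + 1000
    slots = [(f"scf{s + 1}", k * slot)
             for s in range(n_scaffolds)
             for k in range(scaffold_len // slot)]
    n_genic = int(round(genic_insert_frac * n_sites))
    if n_genes is None:
        n_genes = min(len(slots) - n_sites, n_genic + 5) if slots else 0
        n_genes = max(n_genes, n_genic)
    if n_genes < n_genic:
        raise ValueError("n_genes smaller than the number of genic sites")
    n_extra_genes = n_genes - n_genic
    if n_sites + n_extra_genes > len(slots):
        raise ValueError("elements cannot fit without overlap: "
                         f"{n_sites} sites + {n_extra_genes} spare genes "
                         f"> {len(slots)} slots")

    order = rng_place.permutation(len(slots))
    site_slots = [slots[i] for i in order[:n_sites]]
    gene_slots = [slots[i] for i in order[n_sites:n_sites + n_extra_genes]]
    genic_flags = np.zeros(n_sites, dtype=bool)
    genic_flags[rng_place.permutation(n_sites)[:n_genic]] = True

    backgrounds = {f"scf{s + 1}": list(_rand_dna(rng_bg, scaffold_len))
                   for s in range(n_scaffolds)}

    core = build_element(template, rng_el)
    # full copies (family members, each up to family_divergence substitutions)
    full_seqs = [core.seq] + [
        _diverge(core, template.family_divergence, rng_el)
        for _ in range(max(0, n_full_copies - 1))]

    # plan genes on background coordinates
    genes_bg: list[tuple[str, str, int, int]] = []   # (id, scaffold, start, end)
    plans = []                                        # per site
    for idx in range(n_sites):
        scf, s0 = site_slots[idx]
        p = s0 + margin + int(rng_place.integers(0, 1000))
        plans.append({"scaffold": scf, "p": p, "genic": bool(genic_flags[idx])})
    gi = 0
    for plan in plans:
        if not plan["genic"]:
            continue
        gi += 1
        gid = f"gene{gi}"
        p = plan["p"]
        L = int(rng_gene.integers(500, 1501))
        if rng_gene.random() < 0.5:                      # gene body
            a = int(rng_gene.integers(300, 1201))
            b = int(rng_gene.integers(300, 1201))
            genes_bg.append((gid, plan["scaffold"], p - a, p + b))
            plan["category"] = "gene_body"
        else:
            # within window, upstream side: the site of an insertion is
            # its left junction, and a downstream gene would sit a full
            # element length away from it after insertion
            d = int(rng_gene.integers(1, window + 1))
            e = p - d + 1
            genes_bg.append((gid, plan["scaffold"], e - L, e))
            plan["category"] = "within_window"
    extra_gene_ids = []
    for scf, s0 in gene_slots:
        gi += 1
        gid = f"gene{gi}"
        c = s0 + slot // 2
        L = int(rng_gene.integers(500, 1501))
        genes_bg.append((gid, scf, c - L // 2, c - L // 2 + L))
        extra_gene_ids.append(gid)

    gene_seq = {gid: "".join(backgrounds[scf][max(0, s):e])
                for gid, scf, s, e in genes_bg}

    # derivative sequences
    deriv_info = []
    frac_lo, frac_hi = derivative_tir_frac_range
    pack_sources = extra_gene_ids or [g[0] for g in genes_bg]
    for d in range(n_derivatives):
        tl = int(round(template.tir_len * rng_el.uniform(frac_lo, frac_hi)))
        tr = int(round(template.tir_len * rng_el.uniform(frac_lo, frac_hi)))
        ilen = int(rng_el.integers(derivative_internal_range[0],
                                   derivative_internal_range[1] + 1))
        is_pack = bool(pack_sources) and rng_el.random() < pack_frac
        src = None
        if is_pack:
            src = pack_sources[int(rng_el.integers(0, len(pack_sources)))]
            host = gene_seq[src]
            flen = min(pack_fragment_len, len(host), max(ilen - 20, 0))
            if flen < 100:
                is_pack, src = False, None
        if is_pack:
            frag, _prov = mutate_fragment(gene_seq[src][:0 + flen],
                                          pack_identity, rng_el)
            pad = ilen - flen
            internal = (_rand_dna(rng_el, pad // 2) + frag
                        + _rand_dna(rng_el, pad - pad // 2))
        else:
            internal = _rand_dna(rng_el, ilen)
        seq = (core.seq[:tl] + internal
               + reverse_complement(core.seq[:tr]))
        perfect = rng_el.random() < derivative_tsd_frac
        deriv_info.append({"seq": seq, "tl": tl, "tr": tr, "src": src,
                           "perfect": perfect,
                           "kind": "pack" if src else "derivative"})

    # assemble scaffolds
    inserts_by_scf: dict[str, list[dict]] = {scf: [] for scf in backgrounds}
    for idx, plan in enumerate(plans):
        if idx < n_full_copies:
            entry = {"seq": full_seqs[idx], "kind": "full", "perfect": True,
                     "tl": template.tir_len, "tr": template.tir_len,
                     "src": None, "id": f"full{idx + 1}",
                     "dde": core.dde_offsets}
        else:
            d = deriv_info[idx - n_full_copies]
            entry = {**d, "id": f"na{idx - n_full_copies + 1}", "dde": None}
        entry.update(p=plan["p"], genic=plan["genic"],
                     k=int(8 + rng_place.integers(0, 2)))
        inserts_by_scf[plan["scaffold"]].append(entry)

    truth = TruthTable()
    scaffolds_out: dict[str, str] = {}
    gene_final: dict[str, tuple[str, int, int]] = {
        gid: (scf, s, e) for gid, scf, s, e in genes_bg}
    for scf, bg in backgrounds.items():
        ins = sorted(inserts_by_scf[scf], key=lambda d: d["p"])
        for entry in ins:
            _fix_tsd_context(bg, entry["p"], entry["k"])
        pieces = []
        prev = 0
        offset = 0
        shifts = []                      # (bg position, added length)
        for entry in ins:
            p, k = entry["p"], entry["k"]
            dup = "".join(bg[p - k:p])
            pieces.append("".join(bg[prev:p]))
            elem = entry["seq"]
            right_dup = dup
            if not entry["perfect"]:
                right_dup = _COMP[dup[0]] + dup[1:]
            pieces.append(elem + right_dup)
            start = p + offset
            end = start + len(elem)
            offset += len(elem) + k
            shifts.append((p, len(elem) + k))
            prev = p
            truth.planted.append(PlantedElement(
                id=entry["id"], scaffold=scf, span=(start, end),
                kind=entry["kind"], tsd_seq=dup,
                tsd_perfect=entry["perfect"], tir_len=entry["tl"],
                tir_len_right=entry["tr"], genic=entry["genic"],
                host_fragment_source=entry["src"],
                dde_offsets=entry["dde"]))
        pieces.append("".join(bg[prev:]))
        scaffolds_out[scf] = "".join(pieces)
        # shift/stretch gene coordinates on this scaffold
        for gid, (gscf, gs, ge) in list(gene_final.items()):
            if gscf != scf:
                continue
            ns, ne = gs, ge
            for p, added in shifts:
                if p <= gs:
                    ns += added
                    ne += added
                elif gs < p < ge:
                    ne += added
            gene_final[gid] = (gscf, ns, ne)

    genome = GenomeSet(scaffolds_out)
    genes = GeneSet([Gene(gid, scf, max(0, s), min(e, len(scaffolds_out[scf])))
                     for gid, (scf, s, e) in gene_final.items()])
    return genome, genes, truth


def generate_point_sites(genome: GenomeSet, n_sites: int, n_genic: int,
                         window: int, seed: int = 0
                         ) -> tuple[GeneSet, list[tuple[str, int]], list[bool]]:
    """Plant point insertion sites (no element sequence) with exactly
    ``n_genic`` of them in gene bodies or within ``window`` bp of a
    gene, the rest farther than ``window`` from every gene.  Returns
    the gene annotation, the sites, and their genic flags."""
    if not 0 <= n_genic <= n_sites:
        raise ValueError("need 0 <= n_genic <= n_sites")
    rng = _substream(seed, 17)
    margin = window + 1000       # gene reach is window + max gene length
    slot = 2 * margin + 500
    slots = [(scf, k * slot) for scf, L in genome.lengths.items()
             for k in range(L // slot)]
    if n_sites > len(slots):
        raise ValueError("sites cannot fit without interference")
    order = rng.permutation(len(slots))
    genes: list[Gene] = []
    sites: list[tuple[str, int]] = []
    flags = [True] * n_genic + [False] * (n_sites - n_genic)
    for i, genic in enumerate(flags):
        scf, s0 = slots[int(order[i])]
        p = s0 + margin + int(rng.integers(0, 400))
        sites.append((scf, p))
        if not genic:
            continue
        L = int(rng.integers(300, 1000))
        if rng.random() < 0.5:                          # gene body
            a = int(rng.integers(50, L - 50))
            genes.append(Gene(f"ygene{i + 1}", scf, p - a, p - a + L))
        else:                                           # within window
            d = int(rng.integers(1, window + 1))
            if rng.random() < 0.5:
                genes.append(Gene(f"ygene{i + 1}", scf, p + d, p + d + L))
            else:
                e = p - d + 1
                genes.append(Gene(f"ygene{i + 1}", scf, e - L, e))
    return GeneSet(genes), sites, flags


# ---------------------------------------------------------------------------
# pack derivatives

def mutate_fragment(fragment: str, identity: float,
                    rng: np.random.Generator) -> tuple[str, int]:
    """Introduce round(len * (1 - identity)) substitutions; returns
    (mutated fragment, number of mismatches)."""
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must be in (0, 1]")
    n_mut = int(round(len(fragment) * (1.0 - identity)))
    seq = list(fragment)
    if n_mut:
        for i in rng.choice(len(seq), size=n_mut, replace=False):
            i = int(i)
            seq[i] = [b for b in _BASES if b != seq[i]][int(rng.integers(0, 3))]
    return "".join(seq), n_mut


def generate_pack_derivative(template: ElementTemplate, host_gene_seq: str,
                             fragment_len: int, identity: float, seed: int = 0
                             ) -> tuple[str, dict]:
    """Build a TIR-flanked nonautonomous element whose internal region
    carries a mutated host-gene fragment at the requested identity."""
    if fragment_len > len(host_gene_seq):
        raise ValueError("fragment_len exceeds host gene length")
    rng = _substream(seed, 7)
    arm, _, _, _ = _build_tir_arm(template, rng)
    if fragment_len > 0:
        frag, n_mut = mutate_fragment(host_gene_seq[:fragment_len],
                                      identity, rng)
    else:
        if not 0.0 < identity <= 1.0:
            raise ValueError("identity must be in (0, 1]")
        frag, n_mut = "", 0
    pad_l, pad_r = _rand_dna(rng, 30), _rand_dna(rng, 30)
    seq = arm + pad_l + frag + pad_r + reverse_complement(arm)
    prov = {
        "pack": fragment_len > 0,
        "fragment_span": (len(arm) + len(pad_l),
                          len(arm) + len(pad_l) + fragment_len),
        "source_span": (0, fragment_len),
        "n_mismatches": n_mut,
    }
    return seq, prov


# ---------------------------------------------------------------------------
# yeast-assay fixtures

@dataclass
class FootprintFixtureSet:
    donor: DonorSite
    junctions: list[tuple[str, str]]     # (revertant junction seq, true class)


_CLASS_ALIASES = {"deletion": "flank_deletion"}
_KNOWN_CLASSES = {"precise", "flank_deletion", "insertion", "tir_remnant"}


def _indel_placements(rev: str, ref: str) -> list[str]:
    """All strings X such that rev == ref[:o] + X + ref[o:] for some o
    (insertion-placement ambiguity).  Empty list if rev is not ref plus
    one contiguous block."""
    d = len(rev) - len(ref)
    if d <= 0:
        return []
    out = []
    for o in range(len(ref) + 1):
        if rev[:o] == ref[:o] and rev[o + d:] == ref[o:]:
            out.append(rev[o:o + d])
    return out


def generate_assay_fixtures(class_counts: dict[str, int],
                            tsd: str | None, seed: int = 0, *,
                            flank_len: int = 60,
                            remnant_range: tuple[int, int] = (1, 13),
                            ) -> FootprintFixtureSet:
    """Generate revertant donor-junction sequences of known footprint class.

    ``precise`` restores the empty site exactly (one TSD copy retained
    when ``tsd`` is given); ``flank_deletion`` removes 1-4 bp of flank
    per side; ``insertion`` adds filler bases at the joint;
    ``tir_remnant`` leaves 1-13 terminal bp of a TIR.
    """
    if remnant_range[1] > 13:
        raise ValueError("TIR remnants longer than 13 bp are outside the "
                         "modeled footprint classes")
    counts: dict[str, int] = {}
    for key, n in class_counts.items():
        cls = _CLASS_ALIASES.get(key, key)
        if cls not in _KNOWN_CLASSES:
            raise ValueError(f"unknown footprint class {key!r}")
        if n < 0:
            raise ValueError("counts must be >= 0")
        counts[cls] = counts.get(cls, 0) + int(n)

    rng = _substream(seed, 11)
    tl = _rand_dna(rng, 50)
    termini = (tl, reverse_complement(tl))
    left = _rand_dna(rng, flank_len)
    right = _rand_dna(rng, flank_len)
    donor = DonorSite(left_flank=left, right_flank=right, tsd=tsd,
                      element_termini=termini)
    ref = left + (tsd or "") + right

    junctions: list[tuple[str, str]] = []
    for cls in ("precise", "flank_deletion", "insertion", "tir_remnant"):
        for _ in range(counts.get(cls, 0)):
            if cls == "precise":
                junctions.append((ref, cls))
            elif cls == "flank_deletion":
                if tsd is None:
                    dl = int(rng.integers(0, 5))
                    dr = int(rng.integers(0 if dl else 1, 5))
                else:
                    # keep the deletion one contiguous block next to the TSD
                    if rng.random() < 0.5:
                        dl, dr = int(rng.integers(1, 5)), 0
                    else:
                        dl, dr = 0, int(rng.integers(1, 5))
                jx = (left[:len(left) - dl] + (tsd or "") + right[dr:])
                junctions.append((jx, cls))
            elif cls == "insertion":
                for _try in range(100):
                    ins = _rand_dna(rng, int(rng.integers(1, 11)))
                    jx = left + (tsd or "") + ins + right
                    reads = _indel_placements(jx, ref)
                    if not any(x == termini[0][:len(x)]
                               or x == termini[1][-len(x):] for x in reads):
                        break
                junctions.append((jx, cls))
            else:  # tir_remnant
                r = int(rng.integers(remnant_range[0], remnant_range[1] + 1))
                side = int(rng.integers(0, 2))
                block = termini[0][:r] if side == 0 else termini[1][-r:]
                jx = left + (tsd or "") + block + right
                junctions.append((jx, cls))
    order = rng.permutation(len(junctions))
    junctions = [junctions[int(i)] for i in order]
    return FootprintFixtureSet(donor=donor, junctions=junctions)


# ---------------------------------------------------------------------------
# reinsertion flanks

@dataclass(frozen=True)
class ReinsertionSite:
    scaffold: str
    pos: int                 # insertion point (start of the duplicated bases)
    tsd_len: int
    tsd_seq: str
    left_flank: str          # ends with the left TSD copy
    right_flank: str         # begins with the right TSD copy


def generate_reinsertion_flanks(n8: int, n9: int, genome: GenomeSet,
                                seed: int = 0, flank_len: int = 40
                                ) -> list[ReinsertionSite]:
    """Simulate transposon-display junction flanks for reinsertion events
    carrying 8-bp (n8 events) and 9-bp (n9 events) TSDs.  Sites are drawn
    so the duplication length reads unambiguously and the left flank maps
    uniquely in the genome."""
    if n8 < 0 or n9 < 0:
        raise ValueError("counts must be >= 0")
    rng = _substream(seed, 13)
    names = list(genome.scaffolds)
    lens = np.array([len(genome.scaffolds[s]) for s in names], dtype=float)
    probs = lens / lens.sum()
    sites: list[ReinsertionSite] = []
    for k in [8] * n8 + [9] * n9:
        for _try in range(500):
            scf = names[int(rng.choice(len(names), p=probs))]
            seq = genome.scaffolds[scf]
            if len(seq) < 2 * flank_len + 24:
                continue
            p = int(rng.integers(flank_len + 2, len(seq) - flank_len - 12))
            left = seq[p - flank_len:p + k]
            right = seq[p:p + flank_len]
            if "N" in left or "N" in right:
                continue
            if _longest_dup(left, right) != k:
                continue
            total = sum(genome.scaffolds[s].count(left) for s in names)
            if total != 1:
                continue
            sites.append(ReinsertionSite(scf, p, k, seq[p:p + k], left, right))
            break
        else:
            raise RuntimeError("could not place reinsertion site")
    return sites
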