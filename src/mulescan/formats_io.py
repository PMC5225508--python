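"""Readers and writers for the standard formats the pipeline touches.

Internally every interval is 0-based half-open; the 1-based inclusive
convention of GFF3 exists only at the file boundary.  Genome sequences
are held uppercase; ``N`` is allowed and never matches anything
downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO

logger = logging.getLogger("mulescan")

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class GenomeSet:
    """A set of scaffolds: id -> uppercase DNA string (A/C/G/T/N only)."""

    scaffolds: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.scaffolds.items()}

    @property
    def total_length(self) -> int:
        return sum(len(v) for v in self.scaffolds.values())

    def __post_init__(self) -> None:
        for sid, seq in self.scaffolds.items():
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"scaffold {sid!r} contains invalid symbols {sorted(bad)}")

    def fetch(self, scaffold: str, start: int, end: int) -> str:
        """Slice [start, end) clipped to scaffold bounds."""
        seq = self.scaffolds[scaffold]
        return seq[max(0, start):min(len(seq), end)]


@dataclass(frozen=True)
class Gene:
    id: str
    scaffold: str
    start: int   # 0-based half-open
    end: int
    strand: str = "+"


@dataclass
class GeneSet:
    genes: list[Gene] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def on_scaffold(self, scaffold: str) -> list[Gene]:
        return [g for g in self.genes if g.scaffold == scaffold]


def load_genome(path: str | Path) -> GenomeSet:
    """Read a FASTA file into a :class:`GenomeSet` (sequences uppercased).

    Duplicate record ids and non-ACGTN symbols raise :class:`FormatError`
    naming the offending record.
    """
    path = Path(path)
    scaffolds: dict[str, str] = {}
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: not a FASTA file (does not start with '>')")
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in scaffolds:
            raise FormatError(f"{path}: duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains invalid symbols {sorted(bad)}")
        scaffolds[rec.id] = seq
    logger.info("loaded %d scaffolds (%d bp) from %s",
                len(scaffolds), sum(map(len, scaffolds.values())), path)
    return GenomeSet(scaffolds)


def write_genome(genome: GenomeSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in genome.scaffolds.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def load_annotation(path: str | Path, genome: GenomeSet,
                    feature_types: Sequence[str] = ("gene",)) -> GeneSet:
    """Read gene features from a GFF3 file, converting to 0-based half-open.

    Genes on scaffolds absent from *genome*, or with coordinates beyond
    the scaffold length, raise :class:`FormatError`.
    """
    path = Path(path)
    genes: list[Gene] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 GFF3 columns")
            scaffold, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in feature_types:
                continue
            if scaffold not in genome.scaffolds:
                raise FormatError(f"{path}:{ln}: unknown scaffold {scaffold!r}")
            start_i, end_i = int(start), int(end)
            if start_i < 1 or end_i < start_i:
                raise FormatError(f"{path}:{ln}: bad coordinates {start}..{end}")
            if end_i > len(genome.scaffolds[scaffold]):
                raise FormatError(
                    f"{path}:{ln}: end {end_i} beyond scaffold length "
                    f"{len(genome.scaffolds[scaffold])}")
            gid = _gff3_attr(attrs, "ID") or f"gene{len(genes) + 1}"
            genes.append(Gene(gid, scaffold, start_i - 1, end_i,
                              strand if strand in "+-" else "+"))
    return GeneSet(genes)


def _gff3_attr(attrs: str, key: str) -> str | None:
    for pair in attrs.split(";"):
        if "=" in pair:
            k, v = pair.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def write_annotation(genes: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.genes:
            fh.write(f"{g.scaffold}\tmulescan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.id}\n")


# ---------------------------------------------------------------------------
# element export / import

def _element_attrs(el) -> str:
    attrs = [f"ID={getattr(el, 'id', 'element')}"]
    tsd = getattr(el, "tsd", None)
    if tsd is not None:
        attrs.append(f"TSD={tsd.length};tsd_seq={tsd.left}")
    tir = getattr(el, "tir", None)
    if tir is not None:
        attrs.append(f"tir_len={tir.length};tir_identity={tir.identity:.3f}")
    return ";".join(attrs)


def export_elements(elements: Iterable, path: str | Path,
                    dialect: str = "gff3") -> None:
    """Write annotated or derivative elements as GFF3 (1-based inclusive)
    or BED (0-based half-open).  TIR/TSD become GFF3 attributes."""
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
        else:
            fh.write('track name=mulescan\n')
        for el in elements:
            start, end = el.span
            if dialect == "gff3":
                fh.write(f"{el.scaffold}\tmulescan\ttransposable_element\t"
                         f"{start + 1}\t{end}\t.\t+\t.\t{_element_attrs(el)}\n")
            else:
                fh.write(f"{el.scaffold}\t{start}\t{end}\t"
                         f"{getattr(el, 'id', 'element')}\n")


@dataclass(frozen=True)
class Interval:
    scaffold: str
    span: tuple[int, int]
    id: str


def import_elements(path: str | Path, dialect: str = "gff3") -> list[Interval]:
    """Re-import element intervals written by :func:`export_elements`."""
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if dialect == "gff3":
                scaffold, start, end = parts[0], int(parts[3]) - 1, int(parts[4])
                eid = _gff3_attr(parts[8], "ID") or "element"
            else:
                scaffold, start, end = parts[0], int(parts[1]), int(parts[2])
                eid = parts[3] if len(parts) > 3 else "element"
            out.append(Interval(scaffold, (start, end), eid))
    return out


# ---------------------------------------------------------------------------
# config / logging plumbing

DEFAULT_CONFIG: dict = {
    "search": {"evalue": 1e-3, "post_filter_evalue": 1e-15,
               "gap_open": 11, "gap_extend": 1},
    "tir": {"min_len": 50, "min_identity": 0.8, "anchor_slack": 5},
    "tsd": {"len_range": [8, 10]},
    "subrepeats": {"unit_range": [9, 15], "min_copies": 3,
                   "max_spacer": 6, "max_mismatch_per_copy": 1},
    "boundaries": {"window": 20, "min_identity": 0.8, "flank_len": 10000},
    "derivatives": {"max_mismatches": 5, "min_span": 100, "max_span": 20000,
                    "flank": 100},
    "pack": {"min_identity": 0.70, "min_len": 100},
    "enrichment": {"window": 5000, "replicates": 1000},
}


def load_config(path: str | Path | None = None) -> dict:
    """Merge a YAML config over the package defaults (shallow per section)."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values or {})
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
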