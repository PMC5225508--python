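"""Insertion-site statistics: genic-proximity classification, a
randomized genomic null for enrichment testing, and position-frequency
matrices of insertion-site consensus.

The null draws sites uniformly over total genome length (scaffolds
weighted by length), classifies each replicate exactly like the
observed data, and reports the per-category mean and SD across
replicates.  Distances to genes are symmetric (strand-ignored) and the
window is inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .formats_io import GeneSet, GenomeSet

CATEGORIES = ("gene_body", "within_window", "distal")


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class _Classifier:
    """Precomputed per-scaffold interval boundaries for fast stabbing."""

    def __init__(self, genome: GenomeSet, genes: GeneSet, window: int):
        self.window = window
        self.body: dict[str, np.ndarray] = {}
        self.near: dict[str, np.ndarray] = {}
        for scf, length in genome.lengths.items():
            gs = [(g.start, g.end) for g in genes.genes if g.scaffold == scf]
            body = _merge(gs)
            # inclusive window: positions with distance <= window;
            # distance is s - pos upstream and pos - (e - 1) downstream
            near = _merge([(max(0, s - window), min(length, e + window))
                           for s, e in gs])
            self.body[scf] = np.array(body, dtype=np.int64).reshape(-1, 2)
            self.near[scf] = np.array(near, dtype=np.int64).reshape(-1, 2)

    @staticmethod
    def _inside(pos: np.ndarray, iv: np.ndarray) -> np.ndarray:
        if iv.size == 0:
            return np.zeros(len(pos), dtype=bool)
        idx = np.searchsorted(iv[:, 0], pos, side="right") - 1
        ok = idx >= 0
        res = np.zeros(len(pos), dtype=bool)
        res[ok] = pos[ok] < iv[idx[ok], 1]
        return res

    def classify(self, scaffold: str, pos: np.ndarray) -> tuple[int, int, int]:
        body = self._inside(pos, self.body[scaffold])
        near = self._inside(pos, self.near[scaffold])
        nb = int(body.sum())
        nw = int((near & ~body).sum())
        return nb, nw, len(pos) - nb - nw


def classify_proximity(site: tuple[str, int], genes: GeneSet,
                       window: int, genome: GenomeSet) -> str:
    """Classify one site as gene_body / within_window / distal.

    Inside any gene span wins; otherwise the inclusive distance to the
    nearest gene edge decides.  Ties resolve toward the more genic
    category.  Unknown scaffolds raise."""
    scaffold, pos = site
    if scaffold not in genome.scaffolds:
        raise ValueError(f"unknown scaffold {scaffold!r}")
    best = None
    for g in genes.genes:
        if g.scaffold != scaffold:
            continue
        if g.start <= pos < g.end:
            return "gene_body"
        d = g.start - pos if pos < g.start else pos - (g.end - 1)
        best = d if best is None else min(best, d)
    if best is not None and best <= window:
        return "within_window"
    return "distal"


@dataclass
class NullDistribution:
    mean: dict[str, float]
    sd: dict[str, float]
    n_sites: int
    n_replicates: int
    window: int
    seed: int


def random_null(genome: GenomeSet, genes: GeneSet, n_sites: int, window: int,
                n_replicates: int = 1000, seed: int = 0) -> NullDistribution:
    """Randomized genomic control: each replicate draws ``n_sites``
    positions uniformly over total genome length and classifies them;
    the mean and SD across replicates estimate the expected category
    counts under no insertion preference."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    clf = _Classifier(genome, genes, window)
    names = list(genome.scaffolds)
    lens = np.array([len(genome.scaffolds[s]) for s in names], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lens)])
    total = int(offsets[-1])
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_replicates, 3), dtype=np.int64)
    for r in range(n_replicates):
        flat = rng.integers(0, total, size=n_sites)
        which = np.searchsorted(offsets, flat, side="right") - 1
        for si in np.unique(which):
            pos = flat[which == si] - offsets[si]
            nb, nw, nd = clf.classify(names[si], pos)
            counts[r] += (nb, nw, nd)
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros(3)
    return NullDistribution(
        mean=dict(zip(CATEGORIES, mean.tolist())),
        sd=dict(zip(CATEGORIES, sd.tolist())),
        n_sites=n_sites, n_replicates=n_replicates, window=window, seed=seed)


@dataclass
class EnrichmentResult:
    observed: dict[str, int]
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    z: dict[str, float]
    n_sites: int
    n_replicates: int
    window: int
    seed: int


def enrichment(observed: dict[str, int],
               null: NullDistribution) -> EnrichmentResult:
    """Z-scores of observed category counts against the randomized null.

    SD 0 with a matching observation gives z = 0; SD 0 with a
    discrepant observation is flagged +/- infinity."""
    z: dict[str, float] = {}
    for cat in CATEGORIES:
        obs = observed.get(cat, 0)
        mu, sd = null.mean[cat], null.sd[cat]
        if sd == 0:
            z[cat] = 0.0 if obs == mu else math.copysign(math.inf, obs - mu)
        else:
            z[cat] = (obs - mu) / sd
    return EnrichmentResult(
        observed={c: int(observed.get(c, 0)) for c in CATEGORIES},
        null_mean=null.mean, null_sd=null.sd, z=z,
        n_sites=null.n_sites, n_replicates=null.n_replicates,
        window=null.window, seed=null.seed)


@dataclass
class PositionFrequencyMatrix:
    half_width: int
    counts: np.ndarray          # positions x 4 (A, C, G, T)
    information: np.ndarray     # bits per position, in [0, 2]

    @property
    def n_sequences(self) -> int:
        return int(self.counts[0].sum())


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def build_pfm(site_sequences: list[str]) -> PositionFrequencyMatrix:
    """Per-position base counts and information content (uniform
    background: IC_j = 2 + sum_b f_bj log2 f_bj) for windows centered on
    the insertion point.  All windows must have equal length."""
    if not site_sequences:
        raise ValueError("no sequences")
    L = len(site_sequences[0])
    if any(len(s) != L for s in site_sequences):
        raise ValueError("insertion-site windows differ in length")
    counts = np.zeros((L, 4), dtype=np.int64)
    for s in site_sequences:
        for j, c in enumerate(s.upper()):
            if c not in _BASE_INDEX:
                raise ValueError(f"non-ACGT base {c!r} in window")
            counts[j, _BASE_INDEX[c]] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    ic = np.clip(2.0 + plogp.sum(axis=1), 0.0, 2.0)
    return PositionFrequencyMatrix(half_width=L // 2, counts=counts,
                                   information=ic)
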