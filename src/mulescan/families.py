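"""Family clustering and neighbor-joining phylogeny of DDE-domain hits.

The multiple alignment is a center-star progressive alignment (the star
center is the sequence with the highest summed pairwise score); the
tree is Saitou–Nei neighbor joining with deterministic tie-breaking and
non-negative branch lengths; supports come from column-resampling
bootstrap, scored as the percentage of replicate trees containing each
internal bipartition of the full-data tree.  Families are single-linkage
clusters at a pairwise-identity threshold: "members share >95%
similarity" is transitive under single linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import global_align_dna, global_align_protein


# ---------------------------------------------------------------------------
# multiple alignment

def _pairwise(a: str, b: str, kind: str) -> tuple[int, str, str]:
    if kind == "dna":
        return global_align_dna(a, b)
    return global_align_protein(a, b)


def align_peptides(seqs: list[str], kind: str = "protein") -> list[str]:
    """Center-star progressive multiple alignment.

    All rows come back equal length and removing gaps recovers the
    inputs exactly.  Requires at least two sequences."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    n = len(seqs)
    totals = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            s, _, _ = _pairwise(seqs[i], seqs[j], kind)
            totals[i] += s
            totals[j] += s
    center = int(np.argmax(totals))

    master = seqs[center]                  # center row with accumulated gaps
    rows: dict[int, str] = {center: master}
    for j in range(n):
        if j == center:
            continue
        _, ac, aj = _pairwise(seqs[center], seqs[j], kind)
        # merge (ac, aj) into the current master ("once a gap, always a gap")
        merged_master, merged_rows, merged_new = [], {k: [] for k in rows}, []
        pi = ci = 0
        while pi < len(master) or ci < len(ac):
            m_gap = pi < len(master) and master[pi] == "-"
            c_gap = ci < len(ac) and ac[ci] == "-"
            if pi < len(master) and ci < len(ac) and not m_gap and not c_gap:
                merged_master.append(master[pi])
                for k in rows:
                    merged_rows[k].append(rows[k][pi])
                merged_new.append(aj[ci])
                pi += 1
                ci += 1
            elif m_gap:
                merged_master.append("-")
                for k in rows:
                    merged_rows[k].append(rows[k][pi])
                merged_new.append("-")
                pi += 1
            elif c_gap:
                merged_master.append("-")
                for k in rows:
                    merged_rows[k].append("-")
                merged_new.append(aj[ci])
                ci += 1
            elif pi >= len(master):
                merged_master.append("-")
                for k in rows:
                    merged_rows[k].append("-")
                merged_new.append(aj[ci])
                ci += 1
            else:
                merged_master.append("-")
                for k in rows:
                    merged_rows[k].append(rows[k][pi])
                merged_new.append("-")
                pi += 1
        master = "".join(merged_master)
        rows = {k: "".join(v) for k, v in merged_rows.items()}
        rows[j] = "".join(merged_new)

    out = [rows[i] for i in range(n)]
    assert all(len(r) == len(out[0]) for r in out)
    assert [r.replace("-", "") for r in out] == list(seqs)
    return out


# ---------------------------------------------------------------------------
# distances

def p_distance_matrix(alignment: list[str]) -> np.ndarray:
    """Pairwise p-distance (mismatches / compared sites), ignoring
    columns where either row is gapped.  Raises if a pair shares no
    comparable sites."""
    if len(alignment) < 3:
        raise ValueError("need at least 3 aligned rows")
    arr = np.array([list(r) for r in alignment])
    n = len(alignment)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = (arr[i] != "-") & (arr[j] != "-")
            m = int(mask.sum())
            if m == 0:
                raise ValueError(f"rows {i} and {j} share no comparable sites")
            d[i, j] = d[j, i] = np.sum(arr[i][mask] != arr[j][mask]) / m
    return d


# ---------------------------------------------------------------------------
# neighbor joining

class _Node:
    __slots__ = ("name", "children")      # children: list of (node, length)

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []

    def newick(self, supports: dict | None = None) -> str:
        return self._nwk(supports) + ";"

    def _nwk(self, supports) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._nwk(supports)}:{ln:.10g}"
                         for c, ln in self.children)
        label = ""
        if supports is not None:
            bp = frozenset(self.leaves())
            if bp in supports:
                label = f"{supports[bp]:.0f}"
        return f"({inner}){label}"

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    newick: str
    leaf_ids: list[str]
    bipartitions: dict[frozenset, float | None]
    root: _Node

    def topology(self) -> set[frozenset]:
        """Canonical unrooted topology: each internal bipartition as the
        frozenset of its canonical (smaller) side."""
        return set(self.bipartitions)


def _canon(bp: frozenset, full: frozenset) -> frozenset:
    """Canonical side of an unrooted bipartition: smaller set, ties by
    sorted leaf names."""
    other = full - bp
    return min(bp, other, key=lambda s: (len(s), sorted(s)))


def neighbor_joining(dist: np.ndarray, ids: list[str]) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Ties on the minimum Q criterion break on the smallest (i, j) index
    pair; negative branch lengths are clamped to zero.  The returned
    tree is unrooted (trifurcation at the last join)."""
    d = np.asarray(dist, dtype=float).copy()
    n = d.shape[0]
    if d.shape != (n, n) or n < 3:
        raise ValueError("need a square matrix with n >= 3")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    nodes: list[_Node] = [_Node(name=i) for i in ids]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, -1, -1)
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] < best[0] - 1e-12:
                    best = (q[a, b], a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the rest
        dnew = np.zeros(d.shape[0] + 1)
        for c in active:
            if c in (i, j):
                continue
            dnew[c] = 0.5 * (d[i, c] + d[j, c] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = dnew[:-1]
        d[:-1, -1] = dnew[:-1]
        nodes.append(new)
        active = [c for c in active if c not in (i, j)] + [d.shape[0] - 1]
    # final trifurcation: three-point formulas
    x, y, z = active
    lx = max(0.0, 0.5 * (d[x, y] + d[x, z] - d[y, z]))
    ly = max(0.0, 0.5 * (d[x, y] + d[y, z] - d[x, z]))
    lz = max(0.0, 0.5 * (d[x, z] + d[y, z] - d[x, y]))
    root = _Node(children=[(nodes[x], lx), (nodes[y], ly), (nodes[z], lz)])

    full = frozenset(ids)
    bps: dict[frozenset, float | None] = {}

    def collect(node: _Node):
        for c, _ in node.children:
            if c.children:
                s = frozenset(c.leaves())
                if 2 <= len(s) <= len(full) - 2:
                    bps[_canon(s, full)] = None
                collect(c)

    collect(root)
    return PhyloTree(newick=root.newick(), leaf_ids=list(ids),
                     bipartitions=bps, root=root)


def bootstrap_support(alignment: list[str], ids: list[str],
                      n_reps: int = 1000, seed: int = 0) -> PhyloTree:
    """Column-resampling bootstrap supports on the full-data NJ tree.

    Support is the percentage of replicate trees (out of ``n_reps``)
    containing each internal bipartition of the full-data tree."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(alignment) < 4:
        raise ValueError("need at least 4 rows for bootstrap supports")
    d0 = p_distance_matrix(alignment)
    if np.allclose(d0, 0.0):
        raise ValueError("degenerate alignment: all pairwise distances are "
                         "zero, tree topology is undefined")
    tree = neighbor_joining(d0, ids)
    full = frozenset(ids)
    counts = {k: 0 for k in tree.bipartitions}
    arr = np.array([list(r) for r in alignment])
    ncol = arr.shape[1]
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep = ["".join(row) for row in arr[:, cols]]
        try:
            dist = p_distance_matrix(rep)
            rep_tree = neighbor_joining(dist, ids)
        except ValueError:
            continue
        for k in counts:
            if k in rep_tree.bipartitions:
                counts[k] += 1
    supports = {k: 100.0 * c / n_reps for k, c in counts.items()}
    tree.bipartitions = supports
    # newick labels are looked up by raw node leaf-sets, so index the
    # supports under both orientations of each bipartition
    render = {}
    for k, v in supports.items():
        render[k] = v
        render[full - k] = v
    tree.newick = tree.root.newick(render)
    return tree


# ---------------------------------------------------------------------------
# family clustering

@dataclass
class FamilySet:
    families: list[tuple[str, list[str], float]]   # (id, members, min identity)
    outgroup_id: str | None = None

    def family_of(self, member: str) -> str | None:
        for fid, members, _ in self.families:
            if member in members:
                return fid
        return None


def pairwise_identity(a: str, b: str, kind: str = "dna") -> float:
    """Identity over all columns of the global alignment (gaps count
    against identity)."""
    _, aa, ab = _pairwise(a, b, kind)
    if not aa:
        return 1.0
    matches = sum(1 for x, y in zip(aa, ab) if x == y and x != "-" and x != "N")
    return matches / len(aa)


def cluster_families(seqs: dict[str, str], identity_threshold: float = 0.95,
                     kind: str = "dna",
                     outgroup_id: str | None = None) -> FamilySet:
    """Single-linkage clustering of sequences at strict identity >
    ``identity_threshold``.  Deterministic and permutation-invariant at
    the family-partition level."""
    ids = list(seqs)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ident: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            pid = pairwise_identity(seqs[a], seqs[b], kind)
            ident[tuple(sorted((a, b)))] = pid
            if pid > identity_threshold:
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for x in ids:
        groups.setdefault(find(x), []).append(x)
    families = []
    for k, members in enumerate(
            sorted(groups.values(), key=lambda g: (-len(g), sorted(g)[0])), 1):
        members = sorted(members)
        if len(members) == 1:
            w = 1.0
        else:
            w = min(ident[tuple(sorted((a, b)))]
                    for i, a in enumerate(members) for b in members[i + 1:])
        families.append((f"family{k}", members, w))
    return FamilySet(families=families, outgroup_id=outgroup_id)
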