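"""Windowed distance matrices, neighbour-joining consensus tree and
block-bootstrap node support.

Distances are plain dosage differences summed over the SNPs of fixed
100 kb coordinate windows; the genome-wide tree comes from neighbour-joining
on the *sum* of the window matrices, rooted on the outgroup (ancestral-state)
sample.  Support values are the fraction of block-bootstrap replicates
(windows resampled with replacement) whose tree contains each clade of the
consensus tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, IntrogrescanError, SiteTable


@dataclass
class DistWindow:
    """One window's symmetric pairwise distance matrix."""

    chrom: str
    start: int
    end: int
    n_sites: int
    matrix: np.ndarray


class Node:
    """Minimal rooted-tree node (children carry branch lengths)."""

    __slots__ = ("name", "children", "length", "support")

    def __init__(self, name=None):
        self.name = name
        self.children: list[Node] = []
        self.length: float = 0.0
        self.support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf():
            return [self.name]
        out = []
        for c in self.children:
            out += c.leaves()
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._nwk() for c in self.children)
        label = "" if self.support is None else f"{self.support:.3g}"
        return f"({inner}){label}:{self.length:.6g}"


@dataclass
class SupportTree:
    """Rooted topology with branch lengths and per-clade supports."""

    root: Node
    supports: dict = field(default_factory=dict)  # frozenset(leaves) -> fraction

    def newick(self) -> str:
        return self.root.newick()

    def clades(self) -> set:
        """Leaf sets of all internal nodes below the root."""
        out: set[frozenset] = set()

        def walk(n: Node):
            for c in n.children:
                if not c.is_leaf():
                    out.add(frozenset(c.leaves()))
                    walk(c)

        walk(self.root)
        return out


# ---------------------------------------------------------------- distances

def window_distances(t: SiteTable, window_bp: int = 100_000) -> list:
    """Pairwise dosage-difference matrices in fixed coordinate windows.

    Per window the distance between samples i and j is the sum over the
    window's SNPs of ``|g_i - g_j|``; sites where either genotype is missing
    contribute 0 to that pair.  Empty windows are omitted.
    """
    out: list[DistWindow] = []
    cs = t.chrom.astype(str)
    for c in t.chromosomes():
        on_c = np.flatnonzero(cs == c)
        if len(on_c) == 0:
            continue
        win = (t.pos[on_c] - 1) // window_bp
        for w in np.unique(win):
            sub = t.dosage[on_c[win == w]].astype(float)
            obs = sub != MISSING
            sub = np.where(obs, sub, 0.0)
            diff = np.abs(sub[:, :, None] - sub[:, None, :])
            pair_obs = obs[:, :, None] & obs[:, None, :]
            mat = (diff * pair_obs).sum(axis=0)
            out.append(DistWindow(chrom=c, start=int(w) * window_bp + 1,
                                  end=(int(w) + 1) * window_bp,
                                  n_sites=int((win == w).sum()), matrix=mat))
    return out


# ----------------------------------------------------------------------- NJ

def neighbour_joining(dist: np.ndarray, names: list):
    """Canonical neighbour-joining; returns an unrooted adjacency map.

    Agglomeration minimises the Q criterion
    ``Q_ij = (n - 2) d_ij - r_i - r_j``; ties break on the lowest (row,
    column) index pair, so star-like (all-equal) inputs resolve
    deterministically with zero-length internal branches.  On an additive
    distance matrix the generating topology and branch lengths are recovered
    exactly.
    """
    n = len(names)
    if n < 3:
        raise IntrogrescanError("neighbour-joining needs at least 3 taxa")
    d = np.asarray(dist, dtype=float).copy()
    if d.shape != (n, n) or not np.allclose(d, d.T) or np.abs(np.diag(d)).max() > 0:
        raise IntrogrescanError("distance matrix must be symmetric with zero diagonal")
    active = list(range(n))
    labels = {i: i for i in range(n)}  # matrix row -> node id
    next_id = n
    adj: dict[int, list] = {i: [] for i in range(n)}
    node_name = {i: names[i] for i in range(n)}

    def connect(a, b, length):
        adj.setdefault(a, []).append((b, length))
        adj.setdefault(b, []).append((a, length))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)  # argmin scans row-major: lowest (i, j) on ties
        i, j = divmod(int(flat), m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        u = next_id
        next_id += 1
        connect(u, labels[active[i]], li)
        connect(u, labels[active[j]], lj)
        # reuse matrix row i for the new node; drop row j
        new_d = 0.5 * (sub[i, :] + sub[j, :] - dij)
        ai, aj = active[i], active[j]
        for k, a in enumerate(active):
            if a in (ai, aj):
                continue
            d[ai, a] = d[a, ai] = new_d[k]
        labels[ai] = u
        active = [a for a in active if a != aj]
    a, b = active
    connect(labels[a], labels[b], d[a, b])
    return adj, node_name


def root_on_outgroup(adj: dict, node_name: dict, outgroup: str) -> Node:
    """Root the unrooted NJ tree on the midpoint of the outgroup's edge."""
    og_id = None
    for i, nm in node_name.items():
        if nm == outgroup:
            og_id = i
            break
    if og_id is None:
        raise IntrogrescanError(f"outgroup {outgroup!r} not among taxa")
    if len(adj[og_id]) != 1:
        raise IntrogrescanError("outgroup must be a leaf")
    nbr, length = adj[og_id][0]

    def build(node_id: int, parent_id: int) -> Node:
        n = Node(node_name.get(node_id))
        for child, ln in adj[node_id]:
            if child == parent_id:
                continue
            c = build(child, node_id)
            c.length = ln
            n.children.append(c)
        return n

    root = Node()
    og = Node(outgroup)
    og.length = length / 2
    rest = build(nbr, og_id)
    rest.length = length / 2
    root.children = [og, rest]
    return root


def consensus_nj(wd: list, outgroup: str, names: list) -> SupportTree:
    """Genome-wide NJ tree from the summed window distance matrices."""
    if not wd:
        raise IntrogrescanError("no distance windows")
    total = np.sum([w.matrix for w in wd], axis=0)
    adj, node_name = neighbour_joining(total, names)
    return SupportTree(root=root_on_outgroup(adj, node_name, outgroup))


def bootstrap_support(wd: list, outgroup: str, names: list,
                      n_replicates: int = 100, seed: int = 0) -> SupportTree:
    """Consensus tree with block-bootstrap clade supports.

    Each replicate resamples ``len(wd)`` windows with replacement, rebuilds
    the NJ tree, and scores every consensus clade present/absent; support is
    the presence fraction, attached to the internal nodes and to
    ``tree.supports``.
    """
    if n_replicates < 1:
        raise IntrogrescanError("need at least one bootstrap replicate")
    tree = consensus_nj(wd, outgroup, names)
    clades = tree.clades()
    hits = {c: 0 for c in clades}
    rng = np.random.default_rng(seed)
    mats = np.array([w.matrix for w in wd])
    for _ in range(n_replicates):
        pick = rng.integers(0, len(wd), size=len(wd))
        total = mats[pick].sum(axis=0)
        adj, node_name = neighbour_joining(total, names)
        rep = SupportTree(root=root_on_outgroup(adj, node_name, outgroup))
        rep_clades = rep.clades()
        for c in clades:
            if c in rep_clades:
                hits[c] += 1
    tree.supports = {c: hits[c] / n_replicates for c in clades}

    def annotate(n: Node):
        for c in n.children:
            if not c.is_leaf():
                c.support = tree.supports.get(frozenset(c.leaves()))
                annotate(c)

    annotate(tree.root)
    return tree
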