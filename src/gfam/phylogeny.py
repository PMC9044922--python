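"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap support.

The tree builder is the Saitou–Nei neighbor-joining algorithm with the
Studier–Keppler Q-criterion.  Ties in the Q minimum are broken by the
lexicographically smallest index pair and negative branch lengths are
clamped to zero, so results are deterministic across platforms.  Support
values come from column-bootstrap replicates: the percentage of replicate
trees containing each internal bipartition of the point-estimate tree.

Multiple sequence alignment is out of scope; the module consumes aligned
FASTA (equal-length sequences, '-' for gaps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core_io import ProteinRecord

logger = logging.getLogger("gfam")

GAP = "-"


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class TreeNode:
    """Node of an unrooted tree stored with an arbitrary (trifurcating) root."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child, _ in self.children for leaf in child.leaves()]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(leaf.name for leaf in self.leaves())


@dataclass
class PhyloTree:
    root: TreeNode
    taxa: tuple[str, ...]

    def newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode, length: float | None) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, bl) for c, bl in node.children)
                label = ""
                if include_support and node.support is not None:
                    label = f"{node.support:g}"
                body = f"({inner}){label}"
            return body if length is None else f"{body}:{length:g}"

        return fmt(self.root, None) + ";"

    def path_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (sums of branch lengths)."""
        adjacency: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}

        def walk(node: TreeNode) -> int:
            nid = id(node)
            adjacency.setdefault(nid, [])
            if node.is_leaf:
                names[nid] = node.name
            for child, bl in node.children:
                cid = walk(child)
                adjacency[nid].append((cid, bl))
                adjacency[cid].append((nid, bl))
            return nid

        walk(self.root)
        order = sorted(self.taxa)
        index = {name: i for i, name in enumerate(order)}
        n = len(order)
        d = np.zeros((n, n))
        leaf_ids = {name: nid for nid, name in names.items()}
        for src in order:
            dist = {leaf_ids[src]: 0.0}
            stack = [leaf_ids[src]]
            while stack:
                cur = stack.pop()
                for nxt, bl in adjacency[cur]:
                    if nxt not in dist:
                        dist[nxt] = dist[cur] + bl
                        stack.append(nxt)
            for dst in order:
                d[index[src], index[dst]] = dist[leaf_ids[dst]]
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(taxa=tuple(order), d=d)

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Internal (non-trivial) bipartitions, canonicalized to the side
        *not* containing the alphabetically first taxon."""
        reference = min(self.taxa)
        all_taxa = frozenset(self.taxa)
        out: dict[frozenset[str], TreeNode] = {}

        def walk(node: TreeNode, is_root: bool) -> None:
            for child, _ in node.children:
                if not child.is_leaf:
                    side = child.leaf_names()
                    if reference in side:
                        side = all_taxa - side
                    if 1 < len(side) < len(all_taxa) - 1:
                        out[side] = child
                walk(child, False)

        walk(self.root, True)
        return out

    @property
    def n_edges(self) -> int:
        def count(node: TreeNode) -> int:
            return len(node.children) + sum(count(c) for c, _ in node.children)

        return count(self.root)


def p_distance(
    aligned: Sequence[ProteinRecord], correction: str = "none"
) -> DistanceMatrix:
    """Pairwise-deletion p-distance matrix from an alignment.

    Sites where either sequence carries a gap are excluded per pair; a pair
    with zero comparable sites is an error, as are unequal lengths or fewer
    than three taxa.  ``correction='poisson'`` applies -ln(1 - p).
    """
    aligned = list(aligned)
    if len(aligned) < 3:
        raise ValueError("at least 3 taxa required")
    lengths = {len(r.sequence) for r in aligned}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal lengths")
    arr = np.array([list(r.sequence) for r in aligned])
    not_gap = arr != GAP
    n = len(aligned)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = not_gap[i] & not_gap[j]
            m = int(comparable.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {aligned[i].id} and {aligned[j].id}"
                )
            p = float((arr[i, comparable] != arr[j, comparable]).sum()) / m
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError("Poisson correction undefined for p >= 1")
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(taxa=tuple(r.id for r in aligned), d=d)


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining over a distance matrix (n >= 3 taxa)."""
    n = len(matrix.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    size = 2 * n
    d = np.full((size, size), np.inf)
    d[:n, :n] = matrix.d
    np.fill_diagonal(d, 0.0)
    nodes: dict[int, TreeNode] = {i: TreeNode(name=t) for i, t in enumerate(matrix.taxa)}
    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = d[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin = lexicographically smallest (i, j) tie-break
        ai, aj = np.unravel_index(int(q.argmin()), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = idx[ai], idx[aj]
        dij = d[i, j]
        bi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        bj = dij - bi
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        new = TreeNode(children=[(nodes[i], bi), (nodes[j], bj)])
        u = next_id
        next_id += 1
        nodes[u] = new
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - dij)
        d[u, u] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]
    i, j, k = active
    bi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    bj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    bk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = TreeNode(
        children=[
            (nodes[i], max(bi, 0.0)),
            (nodes[j], max(bj, 0.0)),
            (nodes[k], max(bk, 0.0)),
        ]
    )
    return PhyloTree(root=root, taxa=matrix.taxa)


def bootstrap_support(
    aligned: Sequence[ProteinRecord],
    n_reps: int = 1000,
    seed: int = 0,
    correction: str = "none",
) -> PhyloTree:
    """NJ point tree with column-bootstrap support on internal edges.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    is rebuilt with the same distance/NJ settings, and the support of an
    internal bipartition of the point tree is the percentage of replicates
    containing it.  Replicates where some pair has no comparable sites are
    skipped with a log message.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    aligned = list(aligned)
    tree = neighbor_joining(p_distance(aligned, correction))
    splits = tree.bipartitions()
    counts = {split: 0 for split in splits}
    rng = np.random.default_rng(seed)
    length = len(aligned[0].sequence)
    used = 0
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = [
            ProteinRecord(id=r.id, sequence="".join(r.sequence[c] for c in cols))
            for r in aligned
        ]
        try:
            rep = neighbor_joining(p_distance(resampled, correction))
        except ValueError as exc:
            logger.info("bootstrap replicate skipped: %s", exc)
            continue
        used += 1
        rep_splits = set(rep.bipartitions())
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    for split, node in splits.items():
        node.support = 100.0 * counts[split] / used if used else 0.0
    logger.info("bootstrap_support: %d/%d replicates used", used, n_reps)
    return tree
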