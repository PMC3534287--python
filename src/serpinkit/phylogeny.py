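"""Distance-based trees: neighbor joining, bootstrap supports, Newick output.

The agglomeration is the canonical Q-criterion neighbor joining with a
deterministic tie rule (lowest index pair in current id order) and
negative branch lengths clamped to zero.  Bootstrap supports count, for
each internal edge of the reference tree, how many site-resampled
replicate trees contain the same bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment_identity import Msa, identity_matrix, strip_allgap_sites

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "p_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "write_newick",
    "bipartitions",
    "same_topology",
    "path_distance_matrix",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        self.values = v

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class TreeNode:
    name: Optional[str] = None  # leaf label, None for internal
    children: list = field(default_factory=list)  # [(TreeNode, length)]
    support: Optional[int] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    root: TreeNode  # degree-3 basal node: the tree is unrooted
    n_bootstrap: Optional[int] = None
    clamped_branches: int = 0

    def leaf_names(self) -> list[str]:
        return self.root.leaves()


def p_distance_matrix(msa: Msa) -> DistanceMatrix:
    """1 - identity/100 over the gap-stripped site set."""
    if msa.n_sequences < 3:
        raise ValueError("need at least 3 sequences")
    stripped = strip_allgap_sites(msa)
    ident = identity_matrix(stripped)
    values = 1.0 - ident.values / 100.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(ids=ident.ids, values=values)


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Standard NJ agglomeration over the Q criterion.

    Ties on Q break toward the lowest (i, j) pair in current id order;
    negative branch lengths are clamped to 0 and counted.
    """
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in d.ids]
    dist = d.values.copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0.0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = dist.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * dist[i, j] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * dist[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dist[i, j] - li
        new = TreeNode(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        new_dist = 0.5 * (dist[i, :] + dist[j, :] - dist[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        nodes = [nodes[k] for k in keep] + [new]
        reduced = dist[np.ix_(keep, keep)]
        col = new_dist[keep]
        dist = np.zeros((m - 1, m - 1))
        dist[: m - 2, : m - 2] = reduced
        dist[-1, : m - 2] = col
        dist[: m - 2, -1] = col
    # resolve the final three nodes around one basal internal node
    a, b, c = 0, 1, 2
    la = 0.5 * (dist[a, b] + dist[a, c] - dist[b, c])
    lb = 0.5 * (dist[a, b] + dist[b, c] - dist[a, c])
    lc = 0.5 * (dist[a, c] + dist[b, c] - dist[a, b])
    root = TreeNode(
        children=[
            (nodes[a], clamp(la)),
            (nodes[b], clamp(lb)),
            (nodes[c], clamp(lc)),
        ]
    )
    return PhyloTree(root=root, clamped_branches=clamped)


def bipartitions(tree: PhyloTree) -> set[frozenset]:
    """Non-trivial leaf bipartitions, one per internal edge.

    Each split is normalised to the side not containing the reference
    (lexicographically smallest) leaf.
    """
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    splits: set[frozenset] = set()

    def visit(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(visit(child) for child, _ in node.children))
        if node is not tree.root and 2 <= len(below) <= len(all_leaves) - 2:
            splits.add(below if ref not in below else all_leaves - below)
        return below

    visit(tree.root)
    return splits


def same_topology(t1: PhyloTree, t2: PhyloTree) -> bool:
    """Unrooted topological equality via bipartition sets."""
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        return False
    return bipartitions(t1) == bipartitions(t2)


def path_distance_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances implied by the tree."""
    paths: dict[str, list[tuple[TreeNode, float]]] = {}

    def visit(node: TreeNode, trail: list) -> None:
        if node.is_leaf:
            paths[node.name] = list(trail)
            return
        for child, length in node.children:
            trail.append((child, length))
            visit(child, trail)
            trail.pop()

    visit(tree.root, [])
    ids = sorted(paths)
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[ids[i]], paths[ids[j]]
            shared = 0
            for (ni, _), (nj, _) in zip(pi, pj):
                if ni is nj:
                    shared += 1
                else:
                    break
            dij = sum(l for _, l in pi[shared:]) + sum(l for _, l in pj[shared:])
            values[i, j] = values[j, i] = dij
    return DistanceMatrix(ids=ids, values=values)


def bootstrap_support(msa: Msa, n_trials: int, seed: int) -> PhyloTree:
    """Reference NJ tree with per-edge bootstrap support counts.

    Sites are resampled with replacement from the gap-stripped site set;
    each replicate NJ tree increments the count of every reference
    bipartition it contains.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    stripped = strip_allgap_sites(msa)
    if stripped.n_sequences < 4:
        raise ValueError("bootstrap supports need at least 4 taxa")
    reference = neighbor_joining(p_distance_matrix(stripped))
    ref_splits = bipartitions(reference)
    counts = {split: 0 for split in ref_splits}
    rng = np.random.default_rng(seed)
    L = stripped.n_columns
    for _ in range(n_trials):
        cols = rng.integers(0, L, size=L)
        resampled = stripped.take_columns(list(cols))
        try:
            replicate = neighbor_joining(p_distance_matrix(resampled))
        except ValueError:
            continue  # degenerate resample (e.g. all-identical columns pair)
        for split in bipartitions(replicate):
            if split in counts:
                counts[split] += 1

    all_leaves = frozenset(reference.leaf_names())
    ref_leaf = min(all_leaves)

    def annotate(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(child) for child, _ in node.children))
        if node is not reference.root and 2 <= len(below) <= len(all_leaves) - 2:
            key = below if ref_leaf not in below else all_leaves - below
            node.support = counts[key]
        return below

    annotate(reference.root)
    reference.n_bootstrap = n_trials
    return reference


def _newick_node(node: TreeNode) -> str:
    if node.is_leaf:
        return node.name
    inner = ",".join(
        f"{_newick_node(child)}:{length:.10g}" for child, length in node.children
    )
    label = "" if node.support is None else str(node.support)
    return f"({inner}){label}"


def write_newick(tree: PhyloTree) -> str:
    """Newick string with branch lengths; supports as internal node labels."""
    return _newick_node(tree.root) + ";"
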