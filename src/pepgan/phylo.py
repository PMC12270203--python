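"""UPGMA phylogeny on raw sequence differences.

The tree is built by size-weighted average-linkage agglomeration on the
unadjusted Hamming distance matrix ("raw differences": no evolutionary
distance correction).  Join heights use the ultrametric convention
(height = join distance / 2), so every leaf is equidistant from the
root.  Ties between candidate joins break on the lexicographically
smallest id pair, making the topology deterministic.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "PhyloNode",
    "PhyloTree",
    "hamming_matrix",
    "upgma",
    "cut_tree",
    "bootstrap_support",
]


@dataclasses.dataclass
class PhyloNode:
    height: float
    name: str | None = None
    left: "PhyloNode | None" = None
    right: "PhyloNode | None" = None
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.name is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        return self.left.leaves() + self.right.leaves()  # type: ignore[union-attr]


class PhyloTree:
    """Rooted, binary, ultrametric tree over peptide ids."""

    def __init__(self, root: PhyloNode, ids: Sequence[str]) -> None:
        self.root = root
        self.ids = list(ids)

    @property
    def height(self) -> float:
        return self.root.height

    def internal_nodes(self) -> Iterator[PhyloNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                yield node
                stack.extend([node.left, node.right])  # type: ignore[list-item]

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes (the tree's bipartitions)."""
        return {frozenset(node.leaves()) for node in self.internal_nodes()}

    def to_newick(self) -> str:
        def fmt(node: PhyloNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{bl:.6g}"
            label = "" if node.support is None else f"{node.support:g}"
            inner = ",".join(fmt(c, node.height) for c in (node.left, node.right))
            return f"({inner}){label}:{bl:.6g}"

        n = self.root
        if n.is_leaf:
            return f"{n.name}:0;"
        label = "" if n.support is None else f"{n.support:g}"
        inner = ",".join(fmt(c, n.height) for c in (n.left, n.right))
        return f"({inner}){label};"


def hamming_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Pairwise count of differing positions between equal-length sequences."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"ragged sequence lengths {sorted(lengths)}")
    arr = np.frombuffer("".join(sequences).encode(), dtype="S1").reshape(
        len(sequences), lengths.pop()
    )
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(float)


def upgma(dist: np.ndarray, ids: Sequence[str] | None = None) -> PhyloTree:
    """Size-weighted average-linkage agglomeration of a distance matrix.

    Nodes join at height = distance / 2; the merged cluster's distance to
    any other cluster is the size-weighted mean of its parts' distances.
    """
    d = np.asarray(dist, dtype=float).copy()
    n = d.shape[0]
    if n < 2 or d.shape[1] != n:
        raise ValueError("need a square distance matrix with >= 2 leaves")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]

    nodes: dict[int, PhyloNode] = {i: PhyloNode(height=0.0, name=ids[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    min_id = {i: ids[i] for i in range(n)}  # lexicographic tie-break key
    active = set(range(n))
    next_idx = n
    big = np.full((2 * n, 2 * n), np.inf)
    big[:n, :n] = d

    while len(active) > 1:
        act = sorted(active)
        sub = big[np.ix_(act, act)].copy()
        np.fill_diagonal(sub, np.inf)
        dij = sub.min()
        cand_i, cand_j = np.nonzero(sub == dij)
        # among equally close pairs, take the lexicographically smallest id pair
        best = None
        for a, b in zip(cand_i, cand_j):
            if a >= b:
                continue
            i_, j_ = act[a], act[b]
            lo, hi = sorted((min_id[i_], min_id[j_]))
            key = (lo, hi, i_, j_)
            if best is None or key < best:
                best = key
                i, j = i_, j_
        node = PhyloNode(height=dij / 2.0, left=nodes[i], right=nodes[j])
        nodes[next_idx] = node
        sizes[next_idx] = sizes[i] + sizes[j]
        min_id[next_idx] = min(min_id[i], min_id[j])
        active -= {i, j}
        for k in active:
            big[next_idx, k] = big[k, next_idx] = (
                sizes[i] * big[i, k] + sizes[j] * big[j, k]
            ) / (sizes[i] + sizes[j])
        active.add(next_idx)
        next_idx += 1

    return PhyloTree(nodes[next_idx - 1], ids)


def cut_tree(tree: PhyloTree, height: float = 4.10) -> list[list[str]]:
    """Partition leaves into clades: maximal subtrees below the cut height.

    A cut above the root yields one clade; a cut at 0 makes every leaf
    its own clade.  Clades are returned sorted by their smallest id.
    """
    if height < 0:
        raise ValueError("cut height must be non-negative")
    clades: list[list[str]] = []

    def walk(node: PhyloNode) -> None:
        if node.height <= height:
            clades.append(sorted(node.leaves()))
        else:
            walk(node.left)  # type: ignore[arg-type]
            walk(node.right)  # type: ignore[arg-type]

    walk(tree.root)
    return sorted(clades, key=lambda c: c[0])


def bootstrap_support(
    sequences: Sequence[str],
    ids: Sequence[str] | None = None,
    replicates: int = 50,
    seed: int = 0,
) -> PhyloTree:
    """Felsenstein bootstrap: resample alignment columns, rebuild UPGMA,
    and annotate each internal node with the percentage of replicates
    recovering its leaf set."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if len(sequences) < 3:
        raise ValueError("bootstrap needs at least 3 sequences")
    ids = list(ids) if ids is not None else [str(i) for i in range(len(sequences))]
    tree = upgma(hamming_matrix(sequences), ids)
    L = len(sequences[0])
    arr = np.frombuffer("".join(sequences).encode(), dtype="S1").reshape(len(sequences), L)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {frozenset(c): 0 for c in (tree.clades())}
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        sub = arr[:, cols]
        d = (sub[:, None, :] != sub[None, :, :]).sum(axis=2).astype(float)
        rep = upgma(d, ids)
        rep_clades = rep.clades()
        for clade in counts:
            if clade in rep_clades:
                counts[clade] += 1
    for node in tree.internal_nodes():
        node.support = 100.0 * counts[frozenset(node.leaves())] / replicates
    return tree
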