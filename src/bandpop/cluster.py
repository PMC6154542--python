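"""Jaccard similarity, UPGMA dendrograms and band-bootstrap support.

Relationships among individuals are summarised by Jaccard's similarity on
their band profiles, ``J = a / (a + b + c)`` — shared presences over all
bands present in at least one of the two profiles; shared absences carry no
information for dominant markers and are ignored.  The distance ``1 - J``
feeds UPGMA (unweighted average-linkage) agglomeration, producing a rooted
ultrametric tree whose node heights are half the merge distance.

Clade stability is assessed by bootstrap over *bands*: columns are resampled
with replacement, the tree rebuilt, and each original internal bipartition's
recovery percentage recorded.  Supports below 50% are conventionally left
off drawings but are retained in the data structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import BandMatrix

__all__ = [
    "TreeNode",
    "Dendrogram",
    "jaccard_similarity",
    "similarity_matrix",
    "upgma",
    "bootstrap_support",
    "write_newick",
    "read_newick",
]


@dataclass
class TreeNode:
    """Node of a rooted ultrametric tree (leaf iff ``children`` is empty)."""

    height: float
    children: tuple["TreeNode", ...] = ()
    label: str | None = None
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> tuple[str, ...]:
        if self.is_leaf:
            return (self.label,)  # type: ignore[return-value]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return tuple(out)


@dataclass
class Dendrogram:
    """Rooted ultrametric UPGMA tree over individuals."""

    root: TreeNode

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return self.root.leaves()

    def internal_nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                out.append(node)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def bipartitions(self) -> list[frozenset[str]]:
        """Leaf sets of non-root internal nodes (the clades supports attach to)."""
        return [
            frozenset(node.leaves())
            for node in self.internal_nodes()
            if node is not self.root
        ]

    def cophenetic_matrix(self, order: Sequence[str] | None = None) -> pd.DataFrame:
        """Pairwise cophenetic distances (twice the lowest common ancestor height)."""
        labels = list(order) if order is not None else list(self.leaf_names)
        idx = {v: i for i, v in enumerate(labels)}
        d = np.zeros((len(labels), len(labels)))

        def walk(node: TreeNode) -> list[int]:
            if node.is_leaf:
                return [idx[node.label]]
            child_sets = [walk(c) for c in node.children]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            d[i, j] = d[j, i] = 2.0 * node.height
            return [i for s in child_sets for i in s]

        walk(self.root)
        return pd.DataFrame(d, index=labels, columns=labels)

    def cut(self, k: int) -> dict[str, int]:
        """Group labels from cutting the tree into ``k`` clusters.

        The cut is placed just below the ``k-1`` highest internal nodes, the
        height at which exactly ``k`` groups exist for a binary tree.
        """
        n = len(self.leaf_names)
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        heights = sorted((node.height for node in self.internal_nodes()), reverse=True)
        cutoff = heights[k - 2] if k >= 2 else float("inf")
        clusters: list[tuple[str, ...]] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf or node.height < cutoff:
                clusters.append(node.leaves())
            else:
                for c in node.children:
                    walk(c)

        walk(self.root)
        return {leaf: ci for ci, group in enumerate(clusters) for leaf in group}

    def to_newick(self, min_support: float | None = None) -> str:
        """Newick string; supports below ``min_support`` are left unlabelled
        (the conventional "only supports above 50% are presented" rendering),
        while the data structure keeps every support."""
        return _newick_string(self.root, min_support) + ";"


def jaccard_similarity(x: Sequence[int], y: Sequence[int]) -> float:
    """Jaccard similarity ``a/(a+b+c)`` of two 0/1 band vectors."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    union = (x | y).sum()
    if union == 0:
        raise ValueError("both profiles are all-zero; Jaccard undefined")
    return float((x & y).sum() / union)


def similarity_matrix(m: BandMatrix, on_empty: str = "error") -> pd.DataFrame:
    """Symmetric Jaccard similarity matrix of all individuals.

    ``on_empty`` controls all-zero profiles: ``"error"`` (default) raises
    naming the individual; ``"zero"`` assigns similarity 0 to any pair with
    exactly one empty profile and 1 when both are empty (identical
    profiles), which keeps band-bootstrap replicates well defined.
    """
    x = m.scores.astype(bool)
    empty = ~x.any(axis=1)
    if empty.any() and on_empty == "error":
        bad = [i for i, e in zip(m.individual_ids, empty) if e]
        raise ValueError(f"all-zero band profile for individual(s) {bad}")
    inter = (x.astype(np.int32) @ x.T.astype(np.int32)).astype(float)
    sums = x.sum(axis=1)
    union = sums[:, None] + sums[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    labels = list(m.individual_ids)
    return pd.DataFrame(sim, index=labels, columns=labels)


def upgma(d, labels: Sequence[str] | None = None) -> Dendrogram:
    """Average-linkage agglomeration of a distance matrix.

    The merge at each step takes the pair at minimal distance, ties broken
    by the lexicographically smallest (row, column) index pair so that runs
    are reproducible across platforms.  Node height is merge distance / 2.
    """
    if isinstance(d, pd.DataFrame):
        if labels is None:
            labels = list(d.index)
        d = d.to_numpy(dtype=float)
    else:
        d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length must match matrix size")
    if n == 0:
        raise ValueError("empty distance matrix")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.diag(d).any():
        raise ValueError("distance matrix must have zero diagonal")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")

    work = d.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    nodes: list[TreeNode] = [TreeNode(0.0, label=str(v)) for v in labels]
    slot: list[int] = list(range(n))  # slot -> node index
    for _ in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], work, np.inf)
        # row-major argmin gives the smallest (row, col) pair among ties
        flat = int(np.argmin(masked))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        dist = work[i, j]
        merged = TreeNode(dist / 2.0, children=(nodes[slot[i]], nodes[slot[j]]))
        nodes.append(merged)
        # average-linkage update into slot i; retire slot j
        new_row = (sizes[i] * work[i] + sizes[j] * work[j]) / (sizes[i] + sizes[j])
        work[i, :] = new_row
        work[:, i] = new_row
        work[i, i] = np.inf
        active[j] = False
        sizes[i] += sizes[j]
        slot[i] = len(nodes) - 1
    root = nodes[-1] if n > 1 else nodes[0]
    return Dendrogram(root)


def bootstrap_support(
    m: BandMatrix, replicates: int = 1000, seed: int | None = None
) -> Dendrogram:
    """UPGMA tree with band-bootstrap clade supports.

    Bands (columns) are resampled with replacement ``replicates`` times; each
    original internal bipartition's support is the percentage of replicate
    trees containing the same leaf set.
    """
    if replicates < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    tree = upgma(1.0 - similarity_matrix(m))
    targets = {frozenset(node.leaves()): node for node in tree.internal_nodes()}
    hits = {key: 0 for key in targets}
    rng = np.random.default_rng(seed)
    labels = list(m.individual_ids)
    for _ in range(replicates):
        cols = rng.integers(0, m.n_bands, size=m.n_bands)
        resampled = BandMatrix(
            m.scores[:, cols],
            m.individual_ids,
            m.population_labels,
            [f"bs{i}" for i in range(m.n_bands)],
            [m.band_primer[c] for c in cols],
        )
        rep_tree = upgma(1.0 - similarity_matrix(resampled, on_empty="zero"), labels)
        rep_sets = {frozenset(node.leaves()) for node in rep_tree.internal_nodes()}
        for key in hits:
            if key in rep_sets:
                hits[key] += 1
    for key, node in targets.items():
        node.support = 100.0 * hits[key] / replicates
    return tree


def _newick_string(node: TreeNode, min_support: float | None = None) -> str:
    if node.is_leaf:
        return _quote(node.label)
    parts = []
    for child in node.children:
        blen = node.height - child.height
        parts.append(f"{_newick_string(child, min_support)}:{blen:.10g}")
    label = ""
    if node.support is not None and (min_support is None or node.support >= min_support):
        label = f"{node.support:.10g}"
    return f"({','.join(parts)}){label}"


def _quote(label: str | None) -> str:
    label = "" if label is None else str(label)
    if any(ch in label for ch in "(),:;'\" \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(t: Dendrogram, path, min_support: float | None = None) -> None:
    """Serialize to Newick: branch lengths from heights, supports as node labels."""
    with open(path, "w") as fh:
        fh.write(t.to_newick(min_support) + "\n")


def read_newick(path_or_string) -> Dendrogram:
    """Parse a Newick tree written by :func:`write_newick` back to a Dendrogram."""
    import dendropy

    src = str(path_or_string)
    if src.rstrip().endswith(";") and "(" in src:
        tree = dendropy.Tree.get(data=src, schema="newick")
    else:
        tree = dendropy.Tree.get(path=src, schema="newick")

    def depth_of(node) -> float:
        depth = 0.0
        while node.parent_node is not None:
            depth += node.edge.length or 0.0
            node = node.parent_node
        return depth

    total = max(depth_of(leaf) for leaf in tree.leaf_node_iter())

    def convert(node) -> TreeNode:
        if node.is_leaf():
            return TreeNode(0.0, label=node.taxon.label if node.taxon else node.label)
        children = tuple(convert(c) for c in node.child_nodes())
        support = None
        if node.label not in (None, ""):
            support = float(node.label)
        return TreeNode(total - depth_of(node), children=children, support=support)

    return Dendrogram(convert(tree.seed_node))
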