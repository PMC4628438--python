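"""UPGMA dendrograms with locus-bootstrap support and majority-rule consensus.

UPGMA (unweighted pair-group method with arithmetic mean) repeatedly merges
the pair of clusters with the smallest average pairwise distance; the merge
node sits at half the merge distance, so the tree is ultrametric.  Average
linkage is updated with cluster-size weighting.  Ties on the minimal
distance are broken deterministically: each active cluster is labelled by
its lexicographically smallest leaf, and the smallest (label, label) pair
merges first.

Support values come from resampling loci (characters) with replacement —
the natural bootstrap unit for a dominant-marker matrix — recomputing
distances and the UPGMA tree per replicate, and scoring each clade of the
full-data tree by the percentage of replicate trees containing the same
leaf subset.  A majority-rule (>50 %) consensus tree is built from the same
replicate clade frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix

from .containers import BinaryProfileMatrix
from .distance import _pairwise_from_array
from .errors import ValidationError

__all__ = [
    "TreeNode",
    "BootstrapConfig",
    "upgma",
    "bootstrap_support",
    "count_significant_clusters",
]


@dataclass
class TreeNode:
    """A rooted dendrogram node.

    ``height`` is the merge distance / 2 (leaves sit at height 0); branch
    lengths are implicit, parent height minus child height.  ``support`` is
    a bootstrap percentage in [0, 100], or None where not annotated.
    """

    name: str | None = None
    height: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def walk(self):
        """Yield every node, pre-order."""
        yield self
        for child in self.children:
            yield from child.walk()

    def internal_nodes(self, include_root: bool = True) -> list["TreeNode"]:
        nodes = [n for n in self.walk() if not n.is_leaf]
        if not include_root and nodes and nodes[0] is self:
            nodes = nodes[1:]
        return nodes

    def clades(self, trivial: bool = False) -> set[frozenset]:
        """Leaf-name sets of internal nodes; the full set and singletons are
        excluded unless ``trivial``."""
        all_leaves = frozenset(self.leaf_names())
        out = set()
        for node in self.walk():
            names = frozenset(node.leaf_names())
            if not trivial and (len(names) <= 1 or names == all_leaves):
                continue
            out.add(names)
        return out

    def clade_heights(self) -> dict[frozenset, float]:
        return {
            frozenset(node.leaf_names()): node.height
            for node in self.walk()
            if not node.is_leaf
        }


@dataclass(frozen=True)
class BootstrapConfig:
    """Locus-bootstrap settings.

    support_threshold is the percentage above which a clade is reported as a
    significant cluster; 95 is the conventional choice and any reported
    count must name the threshold used.
    """

    n_replicates: int = 1000
    seed: int = 0
    support_threshold: float = 95.0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if not (50.0 < self.support_threshold <= 100.0):
            raise ValidationError("support_threshold must be in (50, 100]")


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Size-weighted average-linkage agglomeration of a distance matrix."""
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ValidationError("UPGMA needs at least 2 isolates")
    D = np.array(dm.data, dtype=float)
    if np.isnan(D).any():
        raise ValidationError("distance matrix contains NaN")

    nodes: dict[int, TreeNode] = {i: TreeNode(name=ids[i]) for i in range(n)}
    labels: dict[int, str] = {i: ids[i] for i in range(n)}  # smallest leaf name
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    active = set(range(n))
    big = np.full((2 * n - 1, 2 * n - 1), np.inf)
    big[:n, :n] = D
    np.fill_diagonal(big, np.inf)
    next_id = n

    while len(active) > 1:
        idx = sorted(active)
        sub = big[np.ix_(idx, idx)]
        dmin = sub.min()
        # deterministic tie-break: lexicographically smallest label pair
        best = None
        for r, c in np.argwhere(sub == dmin):
            if r >= c:
                continue
            i, j = idx[r], idx[c]
            pair = tuple(sorted((labels[i], labels[j])))
            if best is None or pair < best[0]:
                best = (pair, i, j)
        _, i, j = best
        si, sj = sizes[i], sizes[j]
        parent = TreeNode(height=dmin / 2.0, children=[nodes[i], nodes[j]])
        k = next_id
        next_id += 1
        for m in active - {i, j}:
            big[k, m] = big[m, k] = (si * big[i, m] + sj * big[j, m]) / (si + sj)
        nodes[k] = parent
        labels[k] = min(labels[i], labels[j])
        sizes[k] = si + sj
        active -= {i, j}
        active.add(k)

    root = nodes[active.pop()]
    _enforce_monotone(root)
    return root


def _enforce_monotone(node: TreeNode) -> None:
    """Clamp parent heights up to the max child height (guards float noise)."""
    for child in node.children:
        _enforce_monotone(child)
    if node.children:
        node.height = max([node.height] + [c.height for c in node.children])


def bootstrap_support(
    matrix: BinaryProfileMatrix,
    config: BootstrapConfig = BootstrapConfig(),
    metric: str = "dice",
) -> tuple[TreeNode, TreeNode]:
    """Locus-bootstrap the Dice/UPGMA analysis.

    Returns ``(tree, consensus)``: the full-data UPGMA tree with every
    non-root internal node annotated with its replicate support percentage,
    and the majority-rule (>50 %) consensus of the replicate trees.
    Deterministic for a fixed config seed.
    """
    if matrix.n_isolates < 3:
        raise ValidationError("bootstrap needs at least 3 isolates")
    if matrix.n_loci < 2:
        raise ValidationError("bootstrap needs at least 2 loci")

    ids = matrix.isolate_ids
    X = matrix.calls.to_numpy().astype(np.float64)
    n_loci = X.shape[1]
    full_tree = upgma(DistanceMatrix(_pairwise_from_array(X, metric, "zero"), ids=ids))

    rng = np.random.default_rng(config.seed)
    counts: dict[frozenset, int] = {}
    heights: dict[frozenset, float] = {}
    root_heights = []
    for _ in range(config.n_replicates):
        cols = rng.integers(0, n_loci, size=n_loci)
        Xb = X[:, cols]
        tree_b = upgma(DistanceMatrix(_pairwise_from_array(Xb, metric, "zero"), ids=ids))
        root_heights.append(tree_b.height)
        for clade, h in tree_b.clade_heights().items():
            if len(clade) == len(ids):
                continue
            counts[clade] = counts.get(clade, 0) + 1
            heights[clade] = heights.get(clade, 0.0) + h

    all_leaves = frozenset(ids)
    for node in full_tree.internal_nodes(include_root=False):
        clade = frozenset(node.leaf_names())
        node.support = 100.0 * counts.get(clade, 0) / config.n_replicates
    full_tree.support = None

    consensus = _majority_rule_consensus(
        ids,
        {c: k / config.n_replicates for c, k in counts.items()},
        {c: heights[c] / counts[c] for c in counts},
        float(np.mean(root_heights)),
    )
    return full_tree, consensus


def _majority_rule_consensus(
    ids: list[str],
    freqs: dict[frozenset, float],
    mean_heights: dict[frozenset, float],
    root_height: float,
) -> TreeNode:
    """Build the >50 % majority-rule consensus tree.

    Majority clades are pairwise compatible (two clades each in >half the
    replicate trees must co-occur in at least one tree, hence nest or are
    disjoint), so a tree always exists.  Node heights are mean replicate
    merge heights, clamped so a parent is never below a child.
    """
    majority = [c for c, f in freqs.items() if f > 0.5]
    majority.sort(key=len)

    node_of: dict[frozenset, TreeNode] = {
        frozenset([i]): TreeNode(name=i) for i in ids
    }
    # attach smaller clades into larger ones bottom-up
    placed: list[frozenset] = [frozenset([i]) for i in ids]
    for clade in majority:
        direct = _maximal_subsets(clade, placed)
        node = TreeNode(
            height=mean_heights[clade],
            support=round(100.0 * freqs[clade], 10),
            children=[node_of[c] for c in direct],
        )
        node_of[clade] = node
        placed = [c for c in placed if c not in direct] + [clade]
    root_children = _maximal_subsets(frozenset(ids), placed)
    root = TreeNode(height=root_height, children=[node_of[c] for c in root_children])
    _enforce_monotone(root)
    return root


def _maximal_subsets(parent: frozenset, candidates: list[frozenset]) -> list[frozenset]:
    inside = [c for c in candidates if c <= parent and c != parent]
    out = [c for c in inside if not any(c < other for other in inside)]
    return sorted(out, key=lambda c: min(c))


def count_significant_clusters(
    tree: TreeNode, threshold: float = 95.0, collapse_identical: bool = True
) -> int:
    """Count non-root internal nodes with support >= threshold (percent).

    A set of isolates with identical profiles merges at height 0 in an
    order fixed only by the tie-break, and those arbitrary internal
    resolutions inherit perfect support from the determinism of the
    algorithm, not from signal in the data.  With ``collapse_identical``
    (default) a maximal zero-height clade therefore counts as one cluster
    and its internal resolutions are ignored; pass False for the literal
    per-node count.
    """
    internals = tree.internal_nodes(include_root=False)
    if internals and all(n.support is None for n in internals):
        raise ValidationError("tree carries no bootstrap supports")

    def countable(node: TreeNode, parent: TreeNode) -> bool:
        if not collapse_identical:
            return True
        return not (node.height == 0.0 and parent.height == 0.0)

    total = 0
    for parent in tree.walk():
        for node in parent.children:
            if node.is_leaf or parent is node:
                continue
            if node.support is not None and node.support >= threshold and countable(
                node, parent
            ):
                total += 1
    return total
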