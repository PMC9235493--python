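"""Average-linkage feature trees, one per dataset.

Each dataset's features are clustered with UPGMA on an association-derived
dissimilarity: d = 1 - |s| for signed measures (anticorrelated features belong
together), d = 1 - s for measures already in [0, 1].  The resulting binary
tree drives the hypothesis descent; every node's leaf set is a contiguous span
in the tree's leaf order, which is what lets the descent treat blocks as index
rectangles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from .config import AnalysisConfig
from .io import FeatureTable
from .preprocess import discretize_table
from .similarity import (
    _corr_matrix,
    _entropy,
    _rank_rows,
    _xicor_matrix,
    _dcor_statistic,
    mutual_information,
    spearman_assoc,
    pearson_assoc,
)


@dataclass
class TreeNode:
    """A cluster: a contiguous [start, stop) span of the tree's leaf order."""

    start: int
    stop: int
    height: float
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def size(self) -> int:
        return self.stop - self.start


@dataclass
class ClusterTree:
    """Binary average-linkage tree over one dataset's features."""

    root: TreeNode
    leaf_order: np.ndarray  # position in leaf order -> original feature index
    feature_ids: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return self.leaf_order.size

    def leaves(self, node: TreeNode) -> np.ndarray:
        """Original feature indices under ``node``."""
        return self.leaf_order[node.start:node.stop]

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences to the parent."""

        def render(node: TreeNode, parent_height: float) -> str:
            bl = max(parent_height - node.height, 0.0)
            if node.is_leaf:
                idx = int(self.leaf_order[node.start])
                name = self.feature_ids[idx] if self.feature_ids else str(idx)
                return f"{name}:{bl:g}"
            return f"({render(node.left, node.height)},{render(node.right, node.height)}):{bl:g}"

        return render(self.root, self.root.height) + ";"


def association_distance(table: FeatureTable, config: AnalysisConfig) -> np.ndarray:
    """Within-dataset dissimilarity matrix under the configured measure.

    Undefined similarities (constant features) become distance 1; the diagonal
    is 0 and the matrix is symmetric with entries in [0, 1].
    """
    if table.n_features < 2:
        raise ValueError("need at least 2 features to build a tree")
    V = table.values
    measure = config.measure
    complete = np.isfinite(V).all()
    if measure in ("spearman", "pearson"):
        if complete:
            A = _rank_rows(V) if measure == "spearman" else V
            C = _corr_matrix(A, A)
        else:
            assoc = spearman_assoc if measure == "spearman" else pearson_assoc
            C = np.eye(table.n_features)
            for i in range(table.n_features):
                for j in range(i + 1, table.n_features):
                    C[i, j] = C[j, i] = assoc(V[i], V[j]).statistic
        D = 1.0 - np.abs(C)
        const = np.array([np.unique(r[np.isfinite(r)]).size < 2 for r in V])
        D[const, :] = 1.0
        D[:, const] = 1.0
    elif measure == "xicor":
        S, _ = _xicor_matrix(V, V, config.seed)
        S = np.clip(np.maximum(S, S.T), 0.0, 1.0)  # symmetrize by max direction
        D = 1.0 - S
    elif measure == "dcor":
        D = np.zeros((table.n_features, table.n_features))
        for i in range(table.n_features):
            for j in range(i + 1, table.n_features):
                a, b = V[i], V[j]
                m = np.isfinite(a) & np.isfinite(b)
                s = _dcor_statistic(a[m], b[m]) if m.sum() >= 2 else 0.0
                D[i, j] = D[j, i] = 1.0 - np.clip(s, 0.0, 1.0)
    else:  # mi / nmi -> NMI similarity (bounded in [0, 1])
        disc = discretize_table(table, config.bins_override)
        n_f = table.n_features
        D = np.zeros((n_f, n_f))
        labels = []
        ents = []
        for i in range(n_f):
            li = disc.labels[i]
            li = li[np.isfinite(li)].astype(int) if np.isfinite(li).any() else np.array([0])
            labels.append(disc.labels[i])
            ents.append(_entropy(li))
        for i in range(n_f):
            for j in range(i + 1, n_f):
                a, b = labels[i], labels[j]
                m = np.isfinite(a) & np.isfinite(b)
                if m.sum() < 2 or ents[i] == 0 or ents[j] == 0:
                    s = 0.0
                else:
                    ai, bi = a[m].astype(int), b[m].astype(int)
                    ha, hb = _entropy(ai), _entropy(bi)
                    s = mutual_information(ai, bi) / np.sqrt(ha * hb) if ha > 0 and hb > 0 else 0.0
                D[i, j] = D[j, i] = 1.0 - np.clip(s, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2.0, 0.0, 1.0)


def build_tree(D: np.ndarray, feature_ids: list[str] | None = None) -> ClusterTree:
    """UPGMA (average linkage) tree from a square dissimilarity matrix."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n == 1:
        return ClusterTree(TreeNode(0, 1, 0.0), np.array([0]), feature_ids or [])
    Z = sch.linkage(squareform(D, checks=False), method="average")
    return tree_from_linkage(Z, feature_ids)


def tree_from_linkage(Z: np.ndarray, feature_ids: list[str] | None = None) -> ClusterTree:
    """Convert a scipy linkage matrix into a span-indexed ClusterTree."""
    scipy_root = sch.to_tree(Z)
    leaf_order: list[int] = []

    def convert(node) -> TreeNode:
        if node.is_leaf():
            leaf_order.append(node.id)
            k = len(leaf_order)
            return TreeNode(k - 1, k, 0.0)
        left = convert(node.left)
        right = convert(node.right)
        return TreeNode(left.start, right.stop, float(node.dist), left, right)

    root = convert(scipy_root)
    return ClusterTree(root, np.asarray(leaf_order, dtype=int), feature_ids or [])
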