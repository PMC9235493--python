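"""Hierarchical descent through the coupled hypothesis tree.

Starting from the pair of tree roots, each coupled (X-cluster, Y-cluster)
hypothesis block is tested against the false-negative tolerance: the block is
significant when the fraction of its cells whose pairwise p-value misses the
global BH threshold is at most FNT.  A failing block is cut along the X or Y
tree — whichever child split yields the higher Gini impurity gain on the
binary rejection labels; exact ties cut both ways at once — and the children
are tested recursively.  Descent stops at the first significant block on a
path, so reported blocks are maximal, disjoint rectangles; leaf-leaf blocks
survive only if their single p-value rejects.

With FNT = 0 the procedure reduces exactly to all-against-all BH testing:
the union of reported cells equals the BH rejection set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fdr import FdrContext
from .hierarchy import ClusterTree, TreeNode

SIGNIFICANT = "significant"
SPLIT = "split"
REJECTED_LEAF = "rejected_leaf"


@dataclass
class HypothesisBlock:
    """One coupled cluster-pair hypothesis and its decision."""

    x_indices: tuple[int, ...]
    y_indices: tuple[int, ...]
    decision: str
    fail_fraction: float
    best_p: float
    best_q: float
    rank: int | None = None

    @property
    def n_cells(self) -> int:
        return len(self.x_indices) * len(self.y_indices)


@dataclass
class BlockReport:
    """Ranked significant blocks; rectangles are pairwise disjoint."""

    blocks: list[HypothesisBlock] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.blocks)


def block_fail_fraction(block: HypothesisBlock, P: np.ndarray, ctx: FdrContext) -> float:
    """Fraction of the block's cells failing BH rejection (1.0 when nothing rejects)."""
    if ctx.n_rejected == 0:
        return 1.0
    sub = ctx.reject(P[np.ix_(block.x_indices, block.y_indices)])
    return float(1.0 - sub.mean())


def block_significant(block: HypothesisBlock, P: np.ndarray, ctx: FdrContext, fnt: float) -> bool:
    """Dense-block rule: significant iff fail_fraction <= FNT (inclusive)."""
    return block_fail_fraction(block, P, ctx) <= fnt


def gini_impurity(labels) -> float:
    """Binary Gini impurity 1 - p1^2 - p0^2 of rejection indicators."""
    labels = np.asarray(labels, dtype=bool).ravel()
    if labels.size == 0:
        raise ValueError("empty label collection")
    p1 = labels.mean()
    return float(1.0 - p1 * p1 - (1.0 - p1) * (1.0 - p1))


def split_gain(labels: np.ndarray, side: str, cut: int) -> float:
    """Gini gain of cutting a block's cell labels at ``cut`` along one side.

    ``labels`` is the block's 2D rejection matrix in tree-leaf order; side "X"
    cuts rows [0:cut)/[cut:), side "Y" cuts columns.  Children are weighted by
    cell count.
    """
    labels = np.asarray(labels, dtype=bool)
    if side == "X":
        a, b = labels[:cut, :], labels[cut:, :]
    elif side == "Y":
        a, b = labels[:, :cut], labels[:, cut:]
    else:
        raise ValueError("side must be 'X' or 'Y'")
    if a.size == 0 or b.size == 0:
        raise ValueError("cut does not split the block")
    n = labels.size
    child = (a.size * gini_impurity(a) + b.size * gini_impurity(b)) / n
    return max(gini_impurity(labels) - child, 0.0)


def choose_split(labels: np.ndarray, x_cut: int | None, y_cut: int | None) -> str:
    """Pick the cut side by Gini gain: strictly higher wins, exact tie -> BOTH.

    A side with no cut (leaf node) is not a candidate; both sides leaves is a
    caller error (terminal blocks are handled before splitting).
    """
    if x_cut is None and y_cut is None:
        raise ValueError("cannot split a leaf-leaf block")
    if x_cut is None:
        return "Y"
    if y_cut is None:
        return "X"
    gx = split_gain(labels, "X", x_cut)
    gy = split_gain(labels, "Y", y_cut)
    if gx > gy:
        return "X"
    if gy > gx:
        return "Y"
    return "BOTH"


def _prefix_counts(R: np.ndarray) -> np.ndarray:
    """2D prefix sums with a zero border, for O(1) rectangle reject counts."""
    C = np.zeros((R.shape[0] + 1, R.shape[1] + 1), dtype=np.int64)
    C[1:, 1:] = R.cumsum(axis=0).cumsum(axis=1)
    return C


def descend(
    x_tree: ClusterTree,
    y_tree: ClusterTree,
    P: np.ndarray,
    ctx: FdrContext,
    fnt: float,
    Q: np.ndarray | None = None,
) -> BlockReport:
    """Run the full hypothesis-tree descent and return the significant blocks.

    P (and optionally Q) are indexed by original feature order; the trees'
    leaf orders define the contiguous spans each cluster occupies, so every
    hypothesis block is a rectangle in permuted coordinates.
    """
    if not 0.0 <= fnt <= 1.0:
        raise ValueError("fnt must be in [0, 1]")
    R = ctx.reject(P)
    perm = np.ix_(x_tree.leaf_order, y_tree.leaf_order)
    Rp = R[perm]
    Pp = P[perm]
    Qp = Q[perm] if Q is not None else None
    C = _prefix_counts(Rp)
    any_reject = ctx.n_rejected > 0

    def rejected(xn: TreeNode, yn: TreeNode) -> int:
        return int(
            C[xn.stop, yn.stop] - C[xn.start, yn.stop]
            - C[xn.stop, yn.start] + C[xn.start, yn.start]
        )

    def impurity(xn: TreeNode, yn: TreeNode) -> float:
        n = xn.size * yn.size
        p1 = rejected(xn, yn) / n
        return 1.0 - p1 * p1 - (1.0 - p1) * (1.0 - p1)

    def gain(xn: TreeNode, yn: TreeNode, side: str) -> float:
        parent = impurity(xn, yn)
        n = xn.size * yn.size
        if side == "X":
            kids = ((xn.left, yn), (xn.right, yn))
        else:
            kids = ((xn, yn.left), (xn, yn.right))
        child = sum(a.size * b.size * impurity(a, b) for a, b in kids) / n
        return max(parent - child, 0.0)

    significant: list[HypothesisBlock] = []
    seen: set[tuple[int, int, int, int]] = set()
    stack: list[tuple[TreeNode, TreeNode]] = [(x_tree.root, y_tree.root)]
    while stack:
        xn, yn = stack.pop()
        key = (xn.start, xn.stop, yn.start, yn.stop)
        if key in seen:
            continue
        seen.add(key)
        n_cells = xn.size * yn.size
        ff = 1.0 - rejected(xn, yn) / n_cells if any_reject else 1.0
        if ff <= fnt:
            sub_p = Pp[xn.start:xn.stop, yn.start:yn.stop]
            best_q = float(Qp[xn.start:xn.stop, yn.start:yn.stop].min()) if Qp is not None else float("nan")
            significant.append(
                HypothesisBlock(
                    x_indices=tuple(int(i) for i in x_tree.leaves(xn)),
                    y_indices=tuple(int(j) for j in y_tree.leaves(yn)),
                    decision=SIGNIFICANT,
                    fail_fraction=ff,
                    best_p=float(sub_p.min()),
                    best_q=best_q,
                )
            )
            continue
        if xn.is_leaf and yn.is_leaf:
            continue  # single pair failing BH: discard
        x_cut = None if xn.is_leaf else gain(xn, yn, "X")
        y_cut = None if yn.is_leaf else gain(xn, yn, "Y")
        if x_cut is None:
            side = "Y"
        elif y_cut is None:
            side = "X"
        elif x_cut > y_cut:
            side = "X"
        elif y_cut > x_cut:
            side = "Y"
        else:
            side = "BOTH"
        if side == "X":
            stack += [(xn.left, yn), (xn.right, yn)]
        elif side == "Y":
            stack += [(xn, yn.left), (xn, yn.right)]
        else:  # cross-product of both cuts
            stack += [
                (xn.left, yn.left), (xn.left, yn.right),
                (xn.right, yn.left), (xn.right, yn.right),
            ]
    return BlockReport(blocks=significant)


def rank_blocks(
    report: BlockReport,
    x_feature_ids: list[str] | None = None,
    y_feature_ids: list[str] | None = None,
) -> BlockReport:
    """Order blocks by best p ascending (ties: more cells, then feature IDs)."""

    def ids(idx: tuple[int, ...], names: list[str] | None) -> tuple:
        if names is None:
            return tuple(idx)
        return tuple(sorted(names[i] for i in idx))

    report.blocks.sort(
        key=lambda b: (
            b.best_p,
            -b.n_cells,
            ids(b.x_indices, x_feature_ids),
            ids(b.y_indices, y_feature_ids),
        )
    )
    for r, b in enumerate(report.blocks, start=1):
        b.rank = r
    return report


def report_cells(report: BlockReport) -> set[tuple[int, int]]:
    """All (x, y) feature-index cells covered by the report's blocks."""
    cells: set[tuple[int, int]] = set()
    for b in report.blocks:
        cells.update((i, j) for i in b.x_indices for j in b.y_indices)
    return cells
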