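"""Hallagram, clustermap and per-block diagnostic plots.

Plotting is pure presentation: nothing here feeds back into the analysis.
Signed measures (Spearman, Pearson, XICOR) get a diverging colormap centered
at 0; nonnegative measures (MI, NMI, dCor) get a sequential one.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Rectangle

from .descent import BlockReport, HypothesisBlock
from .hierarchy import ClusterTree, TreeNode
from .io import CATEGORICAL, FeatureTable

_SIGNED = {"spearman", "pearson", "xicor"}


def _cmap(measure: str):
    if measure in _SIGNED:
        return "RdBu_r", -1.0, 1.0
    return "viridis", 0.0, None


def _placeholder(path: str, message: str) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.text(0.5, 0.5, message, ha="center", va="center")
    ax.set_axis_off()
    fig.savefig(path)
    plt.close(fig)


def hallagram(est, path: str) -> None:
    """Block heatmap of a fitted analysis.

    Only features participating in the strongest ``max_blocks_shown`` blocks
    are plotted, ordered by their tree position; those blocks are outlined in
    black with rank labels, lower-ranked blocks are boxed in gray (clipped to
    the shown features), and marginally significant cells (p <= k_BH) are
    dotted.
    """
    report: BlockReport = est.report_
    if len(report) == 0:
        _placeholder(path, "no significant blocks")
        return
    shown = report.blocks[: est.max_blocks_shown]
    rest = report.blocks[est.max_blocks_shown:]
    x_feats = {i for b in shown for i in b.x_indices}
    y_feats = {j for b in shown for j in b.y_indices}
    x_pos_full = [i for i in est.x_tree_.leaf_order if i in x_feats]
    y_pos_full = [j for j in est.y_tree_.leaf_order if j in y_feats]
    xmap = {f: k for k, f in enumerate(x_pos_full)}
    ymap = {f: k for k, f in enumerate(y_pos_full)}
    S = est.results_.S[np.ix_(x_pos_full, y_pos_full)]
    R = est.fdr_.reject(est.results_.P)[np.ix_(x_pos_full, y_pos_full)]
    cmap, vmin, vmax = _cmap(est.results_.measure)
    h = max(3.0, 0.25 * len(x_pos_full) + 1.5)
    w = max(3.5, 0.25 * len(y_pos_full) + 2.0)
    fig, ax = plt.subplots(figsize=(w, h))
    im = ax.imshow(S, cmap=cmap, vmin=vmin, vmax=vmax, aspect="auto", interpolation="nearest")
    dots = np.argwhere(R)
    if dots.size:
        ax.scatter(dots[:, 1], dots[:, 0], s=12, c="white", edgecolors="black", linewidths=0.4, zorder=3)

    def outline(block: HypothesisBlock, color: str, label: bool) -> None:
        xs = [xmap[i] for i in block.x_indices if i in xmap]
        ys = [ymap[j] for j in block.y_indices if j in ymap]
        if not xs or not ys:
            return
        r0, r1 = min(xs), max(xs)
        c0, c1 = min(ys), max(ys)
        ax.add_patch(
            Rectangle((c0 - 0.5, r0 - 0.5), c1 - c0 + 1, r1 - r0 + 1,
                      fill=False, edgecolor=color, linewidth=1.8, zorder=4)
        )
        if label:
            ax.text((c0 + c1) / 2, (r0 + r1) / 2, str(block.rank),
                    ha="center", va="center", fontsize=9, fontweight="bold",
                    color="black",
                    bbox=dict(boxstyle="circle,pad=0.15", fc="white", ec="black", alpha=0.8),
                    zorder=5)

    for b in shown:
        outline(b, "black", label=True)
    for b in rest:
        outline(b, "gray", label=False)
    ax.set_xticks(range(len(y_pos_full)))
    ax.set_xticklabels([est.y_table_.feature_ids[j] for j in y_pos_full], rotation=90, fontsize=7)
    ax.set_yticks(range(len(x_pos_full)))
    ax.set_yticklabels([est.x_table_.feature_ids[i] for i in x_pos_full], fontsize=7)
    fig.colorbar(im, ax=ax, label=est.results_.measure)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _draw_dendrogram(ax, tree: ClusterTree, orientation: str) -> None:
    """Minimal dendrogram: leaves at 0..n-1 positions along the shared axis."""

    def walk(node: TreeNode) -> float:
        pos = (node.start + node.stop - 1) / 2.0
        if node.is_leaf:
            return pos
        pl = walk(node.left)
        pr = walk(node.right)
        hl, hr, h = node.left.height, node.right.height, node.height
        if orientation == "top":
            ax.plot([pl, pl, pr, pr], [hl, h, h, hr], color="black", linewidth=0.8)
        else:
            ax.plot([hl, h, h, hr], [pl, pl, pr, pr], color="black", linewidth=0.8)
        return pos

    walk(tree.root)
    ax.set_axis_off()


def clustermap(est, path: str) -> None:
    """Full association heatmap with both feature dendrograms in the margins."""
    x_tree, y_tree = est.x_tree_, est.y_tree_
    S = est.results_.S[np.ix_(x_tree.leaf_order, y_tree.leaf_order)]
    xmap = {f: k for k, f in enumerate(x_tree.leaf_order)}
    ymap = {f: k for k, f in enumerate(y_tree.leaf_order)}
    cmap, vmin, vmax = _cmap(est.results_.measure)
    fig = plt.figure(figsize=(8, 7))
    gs = fig.add_gridspec(2, 2, width_ratios=(1, 5), height_ratios=(1, 5),
                          wspace=0.02, hspace=0.02)
    ax_top = fig.add_subplot(gs[0, 1])
    ax_left = fig.add_subplot(gs[1, 0])
    ax = fig.add_subplot(gs[1, 1])
    _draw_dendrogram(ax_top, y_tree, "top")
    ax_top.set_xlim(-0.5, y_tree.n_leaves - 0.5)
    ax_top.invert_yaxis()
    _draw_dendrogram(ax_left, x_tree, "left")
    ax_left.set_ylim(-0.5, x_tree.n_leaves - 0.5)
    ax_left.invert_yaxis()
    ax_left.invert_xaxis()
    im = ax.imshow(S, cmap=cmap, vmin=vmin, vmax=vmax, aspect="auto", interpolation="nearest")
    for b in est.report_.blocks:
        rows = [xmap[i] for i in b.x_indices]
        cols = [ymap[j] for j in b.y_indices]
        ax.add_patch(
            Rectangle((min(cols) - 0.5, min(rows) - 0.5),
                      max(cols) - min(cols) + 1, max(rows) - min(rows) + 1,
                      fill=False, edgecolor="black", linewidth=1.5)
        )
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label=est.results_.measure, shrink=0.7)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def block_diagnostic(
    block: HypothesisBlock,
    x_table: FeatureTable,
    y_table: FeatureTable,
    path: str,
    results=None,
) -> None:
    """Grid of raw-data panels, one per cell of the block.

    Continuous x continuous cells get scatterplots; cells with a categorical
    member get grouped strip plots.  When ``results`` (PairwiseResults) is
    given, each panel is annotated with its statistic, p and q.
    """
    nx, ny = len(block.x_indices), len(block.y_indices)
    fig, axes = plt.subplots(nx, ny, figsize=(2.6 * ny, 2.2 * nx), squeeze=False)
    rng = np.random.default_rng(0)
    for a, i in enumerate(block.x_indices):
        for b_, j in enumerate(block.y_indices):
            ax = axes[a][b_]
            xv = x_table.values[i]
            yv = y_table.values[j]
            mask = np.isfinite(xv) & np.isfinite(yv)
            xv, yv = xv[mask], yv[mask]
            x_cat = x_table.kinds[i] == CATEGORICAL
            y_cat = y_table.kinds[j] == CATEGORICAL
            if x_cat and not y_cat:
                ax.scatter(xv + rng.uniform(-0.15, 0.15, xv.size), yv, s=8, alpha=0.7)
            elif y_cat and not x_cat:
                ax.scatter(xv, yv + rng.uniform(-0.15, 0.15, yv.size), s=8, alpha=0.7)
            elif x_cat and y_cat:
                ax.scatter(xv + rng.uniform(-0.2, 0.2, xv.size),
                           yv + rng.uniform(-0.2, 0.2, yv.size), s=8, alpha=0.7)
            else:
                ax.scatter(xv, yv, s=8, alpha=0.7)
            ax.set_xlabel(x_table.feature_ids[i], fontsize=7)
            ax.set_ylabel(y_table.feature_ids[j], fontsize=7)
            ax.tick_params(labelsize=6)
            if results is not None:
                ax.set_title(
                    f"s={results.S[i, j]:.2f} p={results.P[i, j]:.2g} q={results.Q[i, j]:.2g}",
                    fontsize=7,
                )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
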