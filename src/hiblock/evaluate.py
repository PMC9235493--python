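"""Scoring reported blocks against planted truth, and the benchmark driver.

Power and FDR are measured at the pairwise (cell) level: a reported block
contributes all of its cells, which puts the hierarchical method and the
naive all-against-all (AllA) baseline on a common footing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fdr
from .config import AnalysisConfig, CONTINUOUS_MEASURES
from .descent import BlockReport, descend, report_cells
from .hierarchy import association_distance, build_tree
from .similarity import pairwise_matrix
from .synth import BenchmarkGrid, SyntheticTruth, default_blocks, generate_paired


@dataclass
class EvalResult:
    power: float
    fdr: float
    n_true_pairs: int
    n_reported_pairs: int
    n_true_positives: int


def expand_to_pairs(report: BlockReport) -> set[tuple[int, int]]:
    """Union of all cells of all reported blocks (blocks are disjoint)."""
    return report_cells(report)


def score(reported: BlockReport | set, truth: SyntheticTruth) -> EvalResult:
    """Pairwise-level power and FDR of a report (or a raw pair set)."""
    pairs = reported if isinstance(reported, set) else expand_to_pairs(reported)
    true_pairs = truth.true_pairs
    tp = len(pairs & true_pairs)
    n_rep = len(pairs)
    n_true = len(true_pairs)
    power = tp / n_true if n_true else 0.0
    fdr_val = (n_rep - tp) / n_rep if n_rep else 0.0
    return EvalResult(power, fdr_val, n_true, n_rep, tp)


def alla_baseline(P: np.ndarray, alpha: float) -> set[tuple[int, int]]:
    """All-against-all: BH over all pairs, report each rejected pair alone."""
    ctx = fdr.bh_threshold(P, alpha)
    idx = np.argwhere(ctx.reject(P))
    return {(int(i), int(j)) for i, j in idx}


def _measure_compatible(measure: str, assoc_type: str) -> bool:
    return not (measure in CONTINUOUS_MEASURES and assoc_type in ("mixed", "categorical"))


def run_benchmark(
    grid: BenchmarkGrid,
    seed: int = 0,
    n_permutations: int = 200,
) -> pd.DataFrame:
    """Run the full replicate x condition grid for both methods.

    Returns a tidy frame with one row per (replicate, assoc_type, measure,
    alpha, fnt, method).  The AllA baseline does not depend on FNT and is
    reported once per FNT value for ease of plotting.  The pairwise matrix and
    both feature trees are computed once per (replicate, type, measure) and
    reused across alpha/FNT conditions.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(grid.replicates)
    rows: list[dict] = []
    for rep in range(grid.replicates):
        rep_ss = rep_seeds[rep]
        for assoc_type in grid.assoc_types:
            block_rng = np.random.default_rng(rep_ss.spawn(1)[0])
            blocks = default_blocks(
                block_rng,
                n_blocks=grid.n_blocks,
                size_range=grid.size_range,
                strength_range=grid.strength_range,
                assoc_type=assoc_type,
                shared_noise=grid.shared_noise,
                strength_jitter=grid.strength_jitter,
                capacity=(grid.n_x, grid.n_y),
            )
            xt, yt, truth = generate_paired(
                grid.n_x, grid.n_y, grid.n_samples, blocks, seed=rep_ss.spawn(2)[1]
            )
            for measure in grid.measures:
                if not _measure_compatible(measure, assoc_type):
                    continue
                cfg = AnalysisConfig(
                    measure=measure, n_permutations=n_permutations,
                    seed=int(rep_ss.generate_state(1)[0] % (2**31)),
                )
                res = pairwise_matrix(xt, yt, cfg)
                x_tree = build_tree(association_distance(xt, cfg), xt.feature_ids)
                y_tree = build_tree(association_distance(yt, cfg), yt.feature_ids)
                for alpha in grid.alphas:
                    ctx = fdr.bh_threshold(res.P, alpha)
                    alla = score(alla_baseline(res.P, alpha), truth)
                    for fnt in grid.fnts:
                        rep_blocks = descend(x_tree, y_tree, res.P, ctx, fnt, res.Q)
                        hier = score(rep_blocks, truth)
                        base = dict(
                            replicate=rep, assoc_type=assoc_type, measure=measure,
                            alpha=alpha, fnt=fnt,
                        )
                        rows.append(dict(base, method="hierarchical",
                                         power=hier.power, fdr=hier.fdr,
                                         n_reported=hier.n_reported_pairs,
                                         n_true=hier.n_true_pairs))
                        rows.append(dict(base, method="alla",
                                         power=alla.power, fdr=alla.fdr,
                                         n_reported=alla.n_reported_pairs,
                                         n_true=alla.n_true_pairs))
    return pd.DataFrame(rows)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and Monte-Carlo standard error of power/FDR per condition."""
    g = results.groupby(["assoc_type", "measure", "alpha", "fnt", "method"], as_index=False)
    out = g.agg(
        power_mean=("power", "mean"),
        power_se=("power", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0),
        fdr_mean=("fdr", "mean"),
        fdr_se=("fdr", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0),
        n_replicates=("power", "size"),
    )
    return out
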