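"""The end-to-end analysis as a scikit-learn-style estimator.

``HierarchicalBlockAnalysis.fit(X, Y)`` runs the whole pipeline — variance
filtering, pairwise testing, the global BH threshold, per-dataset clustering,
Gini-guided descent and block ranking — and exposes the results as fitted
attributes.  Inputs may be FeatureTables, pandas DataFrames (features x
samples) or plain arrays.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import fields as dc_fields

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import fdr
from .config import AnalysisConfig
from .descent import BlockReport, descend, rank_blocks
from .hierarchy import association_distance, build_tree
from .io import FeatureTable, align_tables, read_feature_table
from .preprocess import default_bin_count, filter_low_variance
from .similarity import pairwise_matrix

logger = logging.getLogger("hiblock")

_CONFIG_FIELDS = [f.name for f in dc_fields(AnalysisConfig)]


def _as_table(data, prefix: str) -> FeatureTable:
    if isinstance(data, FeatureTable):
        return data
    if isinstance(data, pd.DataFrame):
        return FeatureTable.from_dataframe(data)
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2D feature x sample matrix")
    return FeatureTable(
        [f"{prefix}{i}" for i in range(arr.shape[0])],
        [f"s{j}" for j in range(arr.shape[1])],
        arr,
        ["continuous"] * arr.shape[0],
    )


class HierarchicalBlockAnalysis(BaseEstimator):
    """Hierarchical block-wise association discovery between two paired tables.

    Parameters mirror :class:`~hiblock.config.AnalysisConfig`: the pairwise
    ``measure``, target FDR ``alpha`` for the global BH threshold, the
    false-negative tolerance ``fnt`` for block significance, permutation count
    and seed for permutation-based measures, the variance-filter threshold,
    and the discretization override.

    Fitted attributes
    -----------------
    x_table_, y_table_ : the filtered, sample-aligned inputs
    results_           : PairwiseResults (statistic / p / q matrices)
    fdr_               : FdrContext (global BH threshold k_BH)
    x_tree_, y_tree_   : per-dataset average-linkage ClusterTrees
    report_            : ranked BlockReport of significant blocks
    """

    def __init__(
        self,
        measure: str = "spearman",
        alpha: float = 0.05,
        fnt: float = 0.2,
        n_permutations: int = 1000,
        seed: int = 0,
        variance_frequency_threshold: float = 1.0,
        max_blocks_shown: int = 30,
        bins_override: int | None = None,
    ):
        self.measure = measure
        self.alpha = alpha
        self.fnt = fnt
        self.n_permutations = n_permutations
        self.seed = seed
        self.variance_frequency_threshold = variance_frequency_threshold
        self.max_blocks_shown = max_blocks_shown
        self.bins_override = bins_override

    def _config(self) -> AnalysisConfig:
        return AnalysisConfig(**{k: getattr(self, k) for k in _CONFIG_FIELDS})

    def fit(self, X, Y):
        """Run the analysis on two paired feature tables."""
        cfg = self._config()  # validates parameters
        xt = _as_table(X, "X")
        yt = _as_table(Y, "Y")
        xt, yt = align_tables(xt, yt)
        if xt.sample_ids != yt.sample_ids:  # pragma: no cover - align guarantees
            raise ValueError("sample axes not aligned")
        xt = filter_low_variance(xt, cfg.variance_frequency_threshold)
        yt = filter_low_variance(yt, cfg.variance_frequency_threshold)
        self.x_table_, self.y_table_ = xt, yt
        self.results_ = pairwise_matrix(xt, yt, cfg)
        self.fdr_ = fdr.bh_threshold(self.results_.P, cfg.alpha)
        if xt.n_features > 1:
            self.x_tree_ = build_tree(association_distance(xt, cfg), xt.feature_ids)
        else:
            self.x_tree_ = build_tree(np.zeros((1, 1)), xt.feature_ids)
        if yt.n_features > 1:
            self.y_tree_ = build_tree(association_distance(yt, cfg), yt.feature_ids)
        else:
            self.y_tree_ = build_tree(np.zeros((1, 1)), yt.feature_ids)
        report = descend(
            self.x_tree_, self.y_tree_, self.results_.P, self.fdr_, cfg.fnt, self.results_.Q
        )
        self.report_ = rank_blocks(report, xt.feature_ids, yt.feature_ids)
        return self

    # -- result accessors ---------------------------------------------------

    def significant_pairs_(self) -> set[tuple[int, int]]:
        """All (x, y) feature-index cells inside significant blocks."""
        from .descent import report_cells

        return report_cells(self.report_)

    def associations_frame(self) -> pd.DataFrame:
        """One row per X x Y feature pair: statistic, p-value, q-value."""
        xt, yt = self.x_table_, self.y_table_
        n_x, n_y = xt.n_features, yt.n_features
        idx = np.indices((n_x, n_y)).reshape(2, -1)
        return pd.DataFrame(
            {
                "X_feature": [xt.feature_ids[i] for i in idx[0]],
                "Y_feature": [yt.feature_ids[j] for j in idx[1]],
                "statistic": self.results_.S.ravel(),
                "p_value": self.results_.P.ravel(),
                "q_value": self.results_.Q.ravel(),
            }
        )

    def blocks_frame(self) -> pd.DataFrame:
        """One row per significant block, ranked."""
        xt, yt = self.x_table_, self.y_table_
        rows = []
        for b in self.report_.blocks:
            rows.append(
                {
                    "rank": b.rank,
                    "X_features": ";".join(xt.feature_ids[i] for i in b.x_indices),
                    "Y_features": ";".join(yt.feature_ids[j] for j in b.y_indices),
                    "best_p": b.best_p,
                    "best_q": b.best_q,
                    "block_size": b.n_cells,
                }
            )
        return pd.DataFrame(
            rows, columns=["rank", "X_features", "Y_features", "best_p", "best_q", "block_size"]
        )


def run(config: AnalysisConfig, x_path: str, y_path: str, out_dir: str, plots: bool = True) -> BlockReport:
    """File-to-file pipeline: read, analyze, write reports and plots.

    Writes ``all_associations.tsv``, ``sig_clusters.tsv``, the hallagram
    (PNG + PDF unless ``plots`` is off) and ``run_config.json`` recording the
    resolved parameters (derived bin count, k_BH, seed) for reproducibility.
    """
    os.makedirs(out_dir, exist_ok=True)
    xt = read_feature_table(x_path)
    yt = read_feature_table(y_path)
    est = HierarchicalBlockAnalysis(**config.to_dict())
    est.fit(xt, yt)
    est.associations_frame().to_csv(
        os.path.join(out_dir, "all_associations.tsv"), sep="\t", index=False, float_format="%.10g"
    )
    est.blocks_frame().to_csv(
        os.path.join(out_dir, "sig_clusters.tsv"), sep="\t", index=False, float_format="%.10g"
    )
    resolved = dict(
        config.to_dict(),
        n_bins=config.bins_override or default_bin_count(est.x_table_.n_samples),
        k_bh=est.fdr_.k_bh,
        n_tests=est.fdr_.m,
        n_significant_blocks=len(est.report_),
    )
    with open(os.path.join(out_dir, "run_config.json"), "w", encoding="utf-8") as fh:
        json.dump(resolved, fh, indent=2, sort_keys=True)
    if plots:
        from .viz import hallagram

        hallagram(est, os.path.join(out_dir, "hallagram.png"))
        hallagram(est, os.path.join(out_dir, "hallagram.pdf"))
    logger.info(
        "run complete: %d features x %d features, k_BH = %.3g, %d significant block(s)",
        est.x_table_.n_features, est.y_table_.n_features, est.fdr_.k_bh, len(est.report_),
    )
    return est.report_
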