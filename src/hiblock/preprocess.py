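"""Variance filtering and equal-frequency discretization.

Information-theoretic association measures (MI, NMI) need a uniform discrete
representation; continuous features are binned once, up front, into
equal-frequency (quantile) bins.  The default bin count follows the cube-root
rule: max(2, round(n_samples ** (1/3))) with half-up rounding.  Near-constant
features are dropped before testing via a mode-frequency threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import CATEGORICAL, CONTINUOUS, FeatureTable

logger = logging.getLogger("hiblock")


@dataclass
class DiscretizedTable:
    """Bin labels per feature; categorical features pass through as codes."""

    feature_ids: list[str]
    labels: np.ndarray  # n_features x n_samples, float with NaN for missing
    n_bins: list[int]   # effective distinct-label count per feature


def filter_low_variance(table: FeatureTable, freq_threshold: float = 1.0) -> FeatureTable:
    """Drop features whose most common non-missing value reaches ``freq_threshold``.

    At the default threshold of 1.0 only strictly constant features are
    removed.  Removals are logged; removing everything is an error.
    """
    if not 0.0 < freq_threshold <= 1.0:
        raise ValueError("freq_threshold must be in (0, 1]")
    keep: list[int] = []
    removed: list[str] = []
    for i in range(table.n_features):
        row = table.values[i]
        row = row[np.isfinite(row)]
        if row.size == 0:
            removed.append(table.feature_ids[i])
            continue
        _, counts = np.unique(row, return_counts=True)
        if counts.max() / row.size >= freq_threshold:
            removed.append(table.feature_ids[i])
        else:
            keep.append(i)
    if removed:
        logger.warning("variance filter removed %d feature(s): %s", len(removed), ", ".join(removed))
    if not keep:
        raise ValueError("variance filter removed all features")
    return table.select_features(keep)


def default_bin_count(n_samples: int) -> int:
    """Cube-root bin rule: max(2, round-half-up(n_samples^(1/3)))."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples to bin")
    root = float(n_samples) ** (1.0 / 3.0)
    return max(2, int(np.floor(root + 0.5)))


def discretize_feature(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning with tie preservation.

    Non-missing values are sorted and split into ``n_bins`` contiguous groups
    of as-equal-as-possible size; identical values always land in the same bin
    (ties never straddle a boundary, which can merge bins).  Bin indices are
    consecutive integers ordered by value; missing values stay NaN.

    The scheme depends only on the value ranks, so it is invariant to strictly
    monotone transforms of the input.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    mask = np.isfinite(values)
    v = values[mask]
    n = v.size
    if n == 0:
        return out
    order = np.argsort(v, kind="stable")
    # target bin of each sorted position, then pull ties into the bin of the
    # group's first occurrence
    target = (np.arange(n) * n_bins) // n
    sorted_v = v[order]
    bins_sorted = np.empty(n, dtype=int)
    group_start = 0
    for i in range(n):
        if i > 0 and sorted_v[i] != sorted_v[i - 1]:
            group_start = i
        bins_sorted[i] = target[group_start]
    # relabel to consecutive indices in value order
    uniq = np.unique(bins_sorted)
    relabel = {b: k for k, b in enumerate(uniq)}
    bins = np.empty(n, dtype=float)
    bins[order] = [relabel[b] for b in bins_sorted]
    out[mask] = bins
    return out


def discretize_table(table: FeatureTable, n_bins: int | None = None) -> DiscretizedTable:
    """Bin every continuous feature; categorical features pass through as codes."""
    k = n_bins if n_bins is not None else default_bin_count(table.n_samples)
    labels = np.full(table.values.shape, np.nan)
    eff_bins: list[int] = []
    for i in range(table.n_features):
        if table.kinds[i] == CONTINUOUS:
            labels[i] = discretize_feature(table.values[i], k)
        else:
            labels[i] = table.values[i]
        row = labels[i][np.isfinite(labels[i])]
        eff_bins.append(int(np.unique(row).size) if row.size else 0)
    return DiscretizedTable(list(table.feature_ids), labels, eff_bins)
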