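"""Global Benjamini-Hochberg threshold and q-values over all pairwise tests.

The block procedure hinges on a single global BH threshold k_BH computed once
over the full p-value matrix: sort the m p-values ascending, take the largest
p_(i) with p_(i) <= i * alpha / m (0 if none).  A pairwise test "rejects" iff
its p-value is at most k_BH.  q-values are the usual step-up running minima of
m * p_(i) / i, so {q <= alpha} and {p <= k_BH} coincide for every alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FdrContext:
    """The global BH decision rule for one analysis.

    k_bh is an observed p-value when anything rejects, else 0.0; n_rejected
    disambiguates the corner where the only rejectable p-values are exactly 0.
    """

    k_bh: float
    alpha: float
    m: int
    n_rejected: int

    def reject(self, p: np.ndarray) -> np.ndarray:
        """Boolean rejection mask for p-values under this rule."""
        p = np.asarray(p, dtype=float)
        if self.n_rejected == 0:
            return np.zeros(p.shape, dtype=bool)
        return p <= self.k_bh


def _validate(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_threshold(pvalues: np.ndarray, alpha: float) -> FdrContext:
    """Benjamini-Hochberg step-up threshold over a flat collection of p-values."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p = _validate(pvalues)
    m = p.size
    ps = np.sort(p)
    crit = (np.arange(1, m + 1) / m) * alpha
    ok = np.nonzero(ps <= crit)[0]
    if ok.size == 0:
        return FdrContext(k_bh=0.0, alpha=alpha, m=m, n_rejected=0)
    r = ok[-1] + 1  # number of rejections
    return FdrContext(k_bh=float(ps[r - 1]), alpha=alpha, m=m, n_rejected=int(r))


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up q-values, returned in the input's order (and shape)."""
    arr = np.asarray(pvalues, dtype=float)
    p = _validate(arr)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.reshape(arr.shape)
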