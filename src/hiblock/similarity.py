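"""Pairwise association statistics and p-values.

Six measures are supported.  Pearson uses the exact normal-theory null
(equivalently the t-approximation); Spearman uses a moment-matched symmetric
beta null — the Pearson-system density on [-c, c] whose variance and kurtosis
equal the exact permutation-null moments of rho, computed in closed form from
rank power sums.  For Pearson data this family reduces exactly to the
classical null; for Spearman it corrects the t-approximation's inflated far
tail (which otherwise distorts FDR near small BH thresholds).  Chatterjee's
xi (XICOR) uses its one-sided asymptotic normal null sqrt(n) * xi ~ N(0, 2/5);
mutual information, its normalized form MI / sqrt(H(X) H(Y)), and distance
correlation use permutation nulls with an add-one estimator,
p = (1 + #{|stat_perm| >= |stat|}) / (1 + B).

Missing data are handled pairwise complete-case; pairs with fewer than
``MIN_COMPLETE`` complete observations are reported as uninformative (p = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

import numpy as np
from scipy import stats

from . import fdr
from .config import AnalysisConfig, CONTINUOUS_MEASURES, DISCRETE_MEASURES
from .io import CATEGORICAL, FeatureTable
from .preprocess import discretize_table

logger = logging.getLogger("hiblock")

#: fewest complete pairs for which a test is attempted
MIN_COMPLETE = 5

#: variance of the asymptotic null of sqrt(n) * xi (no-tie case)
_XI_NULL_VAR = 2.0 / 5.0


@dataclass(frozen=True)
class AssocResult:
    statistic: float
    p_value: float
    n_used: int


@dataclass
class PairwiseResults:
    """Statistic, p-value and BH q-value matrices over all X x Y feature pairs."""

    S: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    measure: str


def _degenerate(n: int, why: str) -> AssocResult:
    logger.warning("association undefined (%s); reporting statistic 0, p = 1", why)
    return AssocResult(0.0, 1.0, n)


def _complete(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def _corr_pvalue(r: float, n: int) -> float:
    """Two-sided p from the t-approximation on a correlation coefficient."""
    r = float(np.clip(r, -1.0, 1.0))
    if n < 3:
        return 1.0
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _exact_rho_kurtosis(n: int) -> float:
    """Exact kurtosis of Spearman's rho under the permutation null (no ties).

    rho is proportional to W = sum_i u_i u_pi(i) with u the centered ranks;
    the 2nd and 4th permutation moments of W follow from sums over equality
    patterns of the index tuple, leaving only even rank power sums (odd ones
    vanish by symmetry).
    """
    u = np.arange(1, n + 1) - (n + 1) / 2.0
    s2 = float(np.sum(u ** 2))
    s4 = float(np.sum(u ** 4))

    def falling(m: int) -> float:
        out = 1.0
        for t in range(m):
            out *= n - t
        return out

    n4 = s4                     # pattern {4}
    n31 = -s4                   # {3,1} (x4)
    n22 = s2 * s2 - s4          # {2,2} (x3)
    n211 = -s2 * s2 + 2 * s4    # {2,1,1} (x6)
    n1111 = 3 * s2 * s2 - 6 * s4  # {1,1,1,1}
    ew2 = s2 * s2 / (n - 1)
    ew4 = (
        n4 * n4 / falling(1)
        + 4 * n31 * n31 / falling(2)
        + 3 * n22 * n22 / falling(2)
        + 6 * n211 * n211 / falling(3)
        + n1111 * n1111 / falling(4)
    )
    return ew4 / (ew2 * ew2)


@lru_cache(maxsize=None)
def _spearman_beta_null(n: int) -> tuple[float, float]:
    """Moment-matched symmetric beta null for Spearman's rho.

    Returns (a, c) such that rho/c ~ 2*Beta(a, a) - 1 matches the exact null
    variance 1/(n-1) and kurtosis.  Fed the Pearson normal-theory kurtosis
    3(n-1)/(n+1) the same mapping recovers a = (n-2)/2, c = 1 — the exact
    Pearson null — so this is a strict generalization of the classical
    correlation null within the symmetric-beta family.
    """
    kurt = _exact_rho_kurtosis(n)
    two_a = 3.0 * (kurt - 1.0) / (3.0 - kurt)
    c = float(np.sqrt((two_a + 1.0) / (n - 1)))
    return two_a / 2.0, c


def _spearman_pvalue(rho, n: int):
    """Two-sided Spearman null p-value (vectorized) from the beta null."""
    a, c = _spearman_beta_null(n)
    z = np.clip((np.abs(rho) / c + 1.0) / 2.0, 0.0, 1.0)
    return 2.0 * stats.beta.sf(z, a, a)


def spearman_assoc(x: np.ndarray, y: np.ndarray) -> AssocResult:
    """Spearman's rank correlation with average-rank ties, beta-null p."""
    x, y = _complete(x, y)
    n = x.size
    if n < 3:
        return _degenerate(n, "fewer than 3 complete pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return _degenerate(n, "constant vector")
    rho = float(np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1])
    if n < MIN_COMPLETE:
        logger.warning("only %d complete pairs; p-value reported as 1", n)
        return AssocResult(rho, 1.0, n)
    return AssocResult(rho, float(_spearman_pvalue(rho, n)), n)


def pearson_assoc(x: np.ndarray, y: np.ndarray) -> AssocResult:
    """Product-moment correlation with t-approximation p."""
    x, y = _complete(x, y)
    n = x.size
    if n < 3:
        return _degenerate(n, "fewer than 3 complete pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return _degenerate(n, "constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    if n < MIN_COMPLETE:
        logger.warning("only %d complete pairs; p-value reported as 1", n)
        return AssocResult(r, 1.0, n)
    return AssocResult(r, _corr_pvalue(r, n), n)


def mutual_information(xd: np.ndarray, yd: np.ndarray) -> float:
    """Plug-in MI (nats) of two integer label vectors via the joint table."""
    xd = np.asarray(xd, dtype=int)
    yd = np.asarray(yd, dtype=int)
    nx, ny = xd.max() + 1, yd.max() + 1
    joint = np.bincount(xd * ny + yd, minlength=nx * ny).reshape(nx, ny).astype(float)
    n = joint.sum()
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def _entropy(labels: np.ndarray) -> float:
    counts = np.bincount(np.asarray(labels, dtype=int)).astype(float)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def permutation_pvalue(
    stat_fn: Callable[[np.ndarray, np.ndarray], float],
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int,
    seed,
) -> float:
    """Permutation p-value with the add-one estimator and |stat| convention.

    Only y is permuted; the result is deterministic under ``seed`` (an int or
    a numpy Generator/SeedSequence).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    obs = abs(stat_fn(x, y))
    hits = 0
    y = np.asarray(y)
    for _ in range(n_perm):
        if abs(stat_fn(x, rng.permutation(y))) >= obs:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def mi_assoc(xd: np.ndarray, yd: np.ndarray, n_perm: int = 1000, seed=0) -> AssocResult:
    """Mutual information on discretized vectors, permutation p."""
    xd, yd = _complete(xd, yd)
    n = xd.size
    if n < MIN_COMPLETE:
        return _degenerate(n, f"fewer than {MIN_COMPLETE} complete pairs")
    if np.unique(xd).size < 2 or np.unique(yd).size < 2:
        return AssocResult(0.0, 1.0, n)
    xi, yi = xd.astype(int), yd.astype(int)
    stat = mutual_information(xi, yi)
    p = permutation_pvalue(mutual_information, xi, yi, n_perm, seed)
    return AssocResult(stat, p, n)


def nmi_assoc(xd: np.ndarray, yd: np.ndarray, n_perm: int = 1000, seed=0) -> AssocResult:
    """MI normalized by sqrt(H(X) H(Y)), in [0, 1]; permutation p."""
    xd, yd = _complete(xd, yd)
    n = xd.size
    if n < MIN_COMPLETE:
        return _degenerate(n, f"fewer than {MIN_COMPLETE} complete pairs")
    xi, yi = xd.astype(int), yd.astype(int)

    def nmi(a, b):
        hx, hy = _entropy(a), _entropy(b)
        if hx == 0.0 or hy == 0.0:
            return 0.0
        return mutual_information(a, b) / np.sqrt(hx * hy)

    stat = nmi(xi, yi)
    if stat == 0.0 and (np.unique(xi).size < 2 or np.unique(yi).size < 2):
        return AssocResult(0.0, 1.0, n)
    p = permutation_pvalue(nmi, xi, yi, n_perm, seed)
    return AssocResult(float(stat), p, n)


def _xi_statistic(x: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> float:
    """Chatterjee's xi of y on x; ties in x broken uniformly at random."""
    n = x.size
    order = rng.permutation(n)
    order = order[np.argsort(x[order], kind="stable")]
    ys = y[order]
    r = stats.rankdata(ys, method="max")
    l = stats.rankdata(-ys, method="max")
    denom = 2.0 * np.sum(l * (n - l))
    if denom == 0.0:
        return 0.0
    return float(1.0 - n * np.sum(np.abs(np.diff(r))) / denom)


def xicor_assoc(x: np.ndarray, y: np.ndarray, seed=0) -> AssocResult:
    """Chatterjee's rank coefficient xi (how well Y is a function of X).

    Asymmetric by construction; the one-sided p comes from the asymptotic
    normal null sqrt(n) * xi ~ N(0, 2/5).
    """
    x, y = _complete(x, y)
    n = x.size
    if n < MIN_COMPLETE:
        return _degenerate(n, f"fewer than {MIN_COMPLETE} complete pairs")
    if np.unique(y).size < 2:
        return _degenerate(n, "constant y")
    rng = np.random.default_rng(seed)
    xi = _xi_statistic(x, y, rng)
    p = float(stats.norm.sf(np.sqrt(n) * xi / np.sqrt(_XI_NULL_VAR)))
    return AssocResult(xi, p, n)


def _dcor_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation via double-centered distance matrices."""
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    dvx = (A * A).mean()
    dvy = (B * B).mean()
    if dvx <= 0.0 or dvy <= 0.0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvx * dvy)))


def dcor_assoc(x: np.ndarray, y: np.ndarray, n_perm: int = 1000, seed=0) -> AssocResult:
    """Distance correlation (0 iff independence in the population); permutation p."""
    x, y = _complete(x, y)
    n = x.size
    if n < MIN_COMPLETE:
        return _degenerate(n, f"fewer than {MIN_COMPLETE} complete pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return _degenerate(n, "constant vector")
    stat = _dcor_statistic(x, y)
    p = permutation_pvalue(_dcor_statistic, x, y, n_perm, seed)
    return AssocResult(stat, p, n)


# ---------------------------------------------------------------------------
# full pairwise matrix


def _rank_rows(M: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, M)


def _standardize_rows(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    sd[sd == 0] = np.nan
    return (M - mu) / sd


def _corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-by-row correlation matrix of two aligned matrices (no missing)."""
    n = A.shape[1]
    C = _standardize_rows(A) @ _standardize_rows(B).T / n
    return np.clip(np.nan_to_num(C, nan=0.0), -1.0, 1.0)


def _corr_pvalue_matrix(C: np.ndarray, n: int, measure: str) -> np.ndarray:
    if measure == "spearman":
        P = _spearman_pvalue(C, n)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = C * np.sqrt((n - 2) / (1.0 - C * C))
        P = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        P[np.abs(C) >= 1.0] = 0.0
    return np.clip(P, 0.0, 1.0)


def _xicor_matrix(X: np.ndarray, Y: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized xi over all row pairs: xi of each Y row as a function of each X row."""
    n = X.shape[1]
    Ry = np.apply_along_axis(lambda v: stats.rankdata(v, method="max"), 1, Y)
    Ly = np.apply_along_axis(lambda v: stats.rankdata(-v, method="max"), 1, Y)
    denom = 2.0 * np.sum(Ly * (n - Ly), axis=1)  # per Y feature
    S = np.zeros((X.shape[0], Y.shape[0]))
    for i in range(X.shape[0]):
        rng = np.random.default_rng([seed, i])
        order = rng.permutation(n)
        order = order[np.argsort(X[i, order], kind="stable")]
        num = n * np.sum(np.abs(np.diff(Ry[:, order], axis=1)), axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            S[i] = np.where(denom > 0, 1.0 - num / denom, 0.0)
    P = stats.norm.sf(np.sqrt(n) * S / np.sqrt(_XI_NULL_VAR))
    P[:, denom == 0] = 1.0
    return S, np.clip(P, 0.0, 1.0)


def pairwise_matrix(x: FeatureTable, y: FeatureTable, config: AnalysisConfig) -> PairwiseResults:
    """Test every X x Y feature pair and fill statistic/p/q matrices.

    Continuous-only measures reject categorical features outright; mi/nmi
    discretize continuous features first (cube-root rule unless overridden).
    q-values come from one global BH pass over all m = n_x * n_y p-values.
    """
    measure = config.measure
    if measure in CONTINUOUS_MEASURES:
        for t, name in ((x, "X"), (y, "Y")):
            bad = [t.feature_ids[i] for i, k in enumerate(t.kinds) if k == CATEGORICAL]
            if bad:
                raise ValueError(
                    f"measure {measure!r} cannot handle categorical {name} feature(s) "
                    f"{bad}; use 'mi' or 'nmi'"
                )
        S, P = _continuous_pairwise(x, y, config)
    elif measure in DISCRETE_MEASURES:
        S, P = _discrete_pairwise(x, y, config)
    else:  # pragma: no cover - config validates
        raise ValueError(f"unknown measure {measure!r}")
    Q = fdr.bh_qvalues(P)
    return PairwiseResults(S=S, P=P, Q=Q, measure=measure)


def _continuous_pairwise(x: FeatureTable, y: FeatureTable, config: AnalysisConfig):
    Xv, Yv = x.values, y.values
    complete = np.isfinite(Xv).all() and np.isfinite(Yv).all()
    n = Xv.shape[1]
    if config.measure in ("spearman", "pearson") and complete:
        A = _rank_rows(Xv) if config.measure == "spearman" else Xv
        B = _rank_rows(Yv) if config.measure == "spearman" else Yv
        S = _corr_matrix(A, B)
        P = _corr_pvalue_matrix(S, n, config.measure)
        # constant rows have no defined correlation: statistic 0, p 1
        const_x = np.array([np.unique(r[np.isfinite(r)]).size < 2 for r in Xv])
        const_y = np.array([np.unique(r[np.isfinite(r)]).size < 2 for r in Yv])
        S[const_x, :] = 0.0
        S[:, const_y] = 0.0
        P[const_x, :] = 1.0
        P[:, const_y] = 1.0
        return S, P
    if config.measure == "xicor" and complete:
        return _xicor_matrix(Xv, Yv, config.seed)
    # general (slow) path: per-pair, pairwise complete
    fn = {
        "spearman": lambda a, b, i, j: spearman_assoc(a, b),
        "pearson": lambda a, b, i, j: pearson_assoc(a, b),
        "xicor": lambda a, b, i, j: xicor_assoc(a, b, seed=[config.seed, i, j]),
        "dcor": lambda a, b, i, j: dcor_assoc(a, b, config.n_permutations, [config.seed, i, j]),
    }[config.measure]
    S = np.zeros((x.n_features, y.n_features))
    P = np.ones_like(S)
    for i in range(x.n_features):
        for j in range(y.n_features):
            r = fn(Xv[i], Yv[j], i, j)
            S[i, j], P[i, j] = r.statistic, r.p_value
    return S, P


def _discrete_pairwise(x: FeatureTable, y: FeatureTable, config: AnalysisConfig):
    xd = discretize_table(x, config.bins_override)
    yd = discretize_table(y, config.bins_override)
    assoc = mi_assoc if config.measure == "mi" else nmi_assoc
    S = np.zeros((x.n_features, y.n_features))
    P = np.ones_like(S)
    for i in range(x.n_features):
        for j in range(y.n_features):
            r = assoc(xd.labels[i], yd.labels[j], config.n_permutations, [config.seed, i, j])
            S[i, j], P[i, j] = r.statistic, r.p_value
    return S, P
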