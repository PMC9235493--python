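"""Paired synthetic datasets with planted block associations.

Each planted block draws one latent standard-normal signal z over the samples.
X-side members load on z directly; Y-side members load on a per-block response
f(z) — linear, quadratic, logarithmic, sinusoidal, stepwise, parabolic — that
is standardized before mixing.  A member equals
sqrt(strength) * signal + sqrt(1 - strength) * noise, so ``strength`` is the
fraction of each member's variance carried by the cross-dataset block signal.
The noise term is itself structured: a fraction ``shared_noise`` of it is a
dataset-side latent common to the block's members, mimicking how co-expressed
or co-occurring features covary within one omics layer beyond what they share
with the other layer.  Within-dataset block correlation is therefore
strength + (1 - strength) * shared_noise, higher than the cross-dataset
correlation (= strength for linear blocks).  Mixed blocks
emit the Y side as stepwise bin labels (categorical features); categorical
blocks emit both sides as labels.  All features outside blocks are independent
standard normal noise, so any cross-dataset pair not inside a planted
rectangle is null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CATEGORICAL, CONTINUOUS, FeatureTable

ASSOC_TYPES = (
    "linear", "quadratic", "logarithmic", "sinusoidal",
    "stepwise", "parabolic", "mixed", "categorical",
)

#: levels used for stepwise responses and label-valued features
_N_LEVELS = 3


@dataclass
class BlockSpec:
    """One planted block: sizes, relationship shape and signal strength."""

    x_size: int
    y_size: int
    assoc_type: str = "linear"
    strength: float = 0.7
    shared_noise: float = 0.8
    strength_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.x_size < 1 or self.y_size < 1:
            raise ValueError("block sizes must be positive")
        if self.assoc_type not in ASSOC_TYPES:
            raise ValueError(f"unknown assoc_type {self.assoc_type!r}")
        if not 0.0 < self.strength <= 1.0:
            raise ValueError("strength must be in (0, 1]")
        if not 0.0 <= self.shared_noise <= 1.0:
            raise ValueError("shared_noise must be in [0, 1]")
        if self.strength_jitter < 0.0:
            raise ValueError("strength_jitter must be non-negative")


@dataclass
class SyntheticTruth:
    """The planted rectangles, and the set of truly associated feature pairs."""

    rectangles: list[tuple[tuple[int, ...], tuple[int, ...]]] = field(default_factory=list)
    assoc_types: list[str] = field(default_factory=list)

    @property
    def true_pairs(self) -> set[tuple[int, int]]:
        pairs: set[tuple[int, int]] = set()
        for xs, ys in self.rectangles:
            pairs.update((i, j) for i in xs for j in ys)
        return pairs

    @property
    def n_true_pairs(self) -> int:
        return sum(len(xs) * len(ys) for xs, ys in self.rectangles)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _response(z: np.ndarray, assoc_type: str) -> np.ndarray:
    if assoc_type == "linear":
        f = z
    elif assoc_type == "quadratic":
        f = z ** 2
    elif assoc_type == "logarithmic":
        f = np.log(np.abs(z) + 0.5)
    elif assoc_type == "sinusoidal":
        f = np.sin(2.0 * np.pi * z)
    elif assoc_type in ("stepwise", "mixed", "categorical"):
        f = _step_levels(z).astype(float)
    elif assoc_type == "parabolic":
        f = (z - np.median(z)) ** 2
    else:  # pragma: no cover - BlockSpec validates
        raise ValueError(assoc_type)
    return _standardize(f)


def _step_levels(z: np.ndarray) -> np.ndarray:
    """Tercile-threshold levels 0/1/2 of z."""
    lo, hi = np.quantile(z, [1 / 3, 2 / 3])
    return np.digitize(z, [lo, hi])


def _noisy_labels(levels: np.ndarray, strength: float, rng: np.random.Generator) -> np.ndarray:
    """Label noise for categorical members: resample with prob 1 - strength."""
    out = levels.copy()
    flip = rng.random(levels.size) > strength
    out[flip] = rng.integers(0, _N_LEVELS, size=int(flip.sum()))
    return out


def generate_paired(
    n_x: int,
    n_y: int,
    n_samples: int,
    blocks: list[BlockSpec],
    noise_sd: float = 1.0,
    seed=0,
) -> tuple[FeatureTable, FeatureTable, SyntheticTruth]:
    """Generate two paired feature tables with the given planted blocks.

    Block feature sets are disjoint and placed at the front of each table (the
    downstream method is invariant to feature order, and clustering re-orders
    features anyway).  Deterministic under ``seed``.
    """
    if sum(b.x_size for b in blocks) > n_x or sum(b.y_size for b in blocks) > n_y:
        raise ValueError("planted block sizes exceed table dimensions")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_x, n_samples))
    Y = rng.standard_normal((n_y, n_samples))
    x_kinds = [CONTINUOUS] * n_x
    y_kinds = [CONTINUOUS] * n_y
    x_cat: dict[str, list[str]] = {}
    y_cat: dict[str, list[str]] = {}
    truth = SyntheticTruth()
    xi = yi = 0
    labels = [f"L{k}" for k in range(_N_LEVELS)]
    for b in blocks:
        z = rng.standard_normal(n_samples)
        q, r = np.sqrt(b.shared_noise), np.sqrt(1.0 - b.shared_noise)

        def loading() -> tuple[float, float]:
            """Per-member signal fraction: block strength with optional jitter."""
            si = b.strength + rng.uniform(-b.strength_jitter, b.strength_jitter)
            si = float(np.clip(si, 0.05, 1.0))
            return np.sqrt(si), np.sqrt(1.0 - si) * noise_sd
        eta_x = rng.standard_normal(n_samples)
        eta_y = rng.standard_normal(n_samples)
        xs = tuple(range(xi, xi + b.x_size))
        ys = tuple(range(yi, yi + b.y_size))
        x_signal = _standardize(z)
        if b.assoc_type == "categorical":
            levels = _step_levels(z)
            for i in xs:
                X[i] = _noisy_labels(levels, b.strength, rng)
                x_kinds[i] = CATEGORICAL
                x_cat[f"X{i}"] = list(labels)
        else:
            for i in xs:
                s, t = loading()
                noise = q * eta_x + r * rng.standard_normal(n_samples)
                X[i] = s * x_signal + t * noise
        if b.assoc_type in ("mixed", "categorical"):
            levels = _step_levels(z)
            for j in ys:
                Y[j] = _noisy_labels(levels, b.strength, rng)
                y_kinds[j] = CATEGORICAL
                y_cat[f"Y{j}"] = list(labels)
        else:
            y_signal = _response(z, b.assoc_type)
            for j in ys:
                s, t = loading()
                noise = q * eta_y + r * rng.standard_normal(n_samples)
                Y[j] = s * y_signal + t * noise
        truth.rectangles.append((xs, ys))
        truth.assoc_types.append(b.assoc_type)
        xi += b.x_size
        yi += b.y_size
    samples = [f"s{k}" for k in range(n_samples)]
    xt = FeatureTable([f"X{i}" for i in range(n_x)], samples, X, x_kinds, x_cat)
    yt = FeatureTable([f"Y{j}" for j in range(n_y)], list(samples), Y, y_kinds, y_cat)
    return xt, yt, truth


def default_blocks(
    rng: np.random.Generator,
    n_blocks: int | None = 5,
    size_range: tuple[int, int] = (3, 8),
    strength_range: tuple[float, float] = (0.42, 0.62),
    assoc_type: str = "linear",
    shared_noise: float = 0.2,
    strength_jitter: float = 0.3,
    capacity: tuple[int, int] | None = None,
) -> list[BlockSpec]:
    """Benchmark block layout.

    Sizes are uniform on ``size_range`` (inclusive) and per-block strength
    uniform on ``strength_range``.  With ``n_blocks=None`` and a ``capacity``
    (n_x, n_y), blocks are drawn until the next one would overflow either
    feature axis — the cluster-rich regime the method targets, where nearly
    every feature belongs to some co-varying block.
    """
    lo, hi = size_range
    blocks: list[BlockSpec] = []
    used_x = used_y = 0
    while True:
        if n_blocks is not None and len(blocks) >= n_blocks:
            break
        xs = int(rng.integers(lo, hi + 1))
        ys = int(rng.integers(lo, hi + 1))
        if capacity is not None and (used_x + xs > capacity[0] or used_y + ys > capacity[1]):
            if n_blocks is None:
                break
            raise ValueError("requested blocks exceed capacity")
        blocks.append(
            BlockSpec(
                x_size=xs,
                y_size=ys,
                assoc_type=assoc_type,
                strength=float(rng.uniform(*strength_range)),
                shared_noise=shared_noise,
                strength_jitter=strength_jitter,
            )
        )
        used_x += xs
        used_y += ys
    return blocks


@dataclass
class BenchmarkGrid:
    """One simulation experiment: replicates x conditions to sweep."""

    replicates: int
    n_x: int
    n_y: int
    n_samples: int
    alphas: tuple[float, ...]
    fnts: tuple[float, ...]
    assoc_types: tuple[str, ...]
    measures: tuple[str, ...]
    n_blocks: int | None = None  # None: fill the feature axes with blocks
    size_range: tuple[int, int] = (3, 8)
    strength_range: tuple[float, float] = (0.42, 0.62)
    shared_noise: float = 0.2
    strength_jitter: float = 0.3


def benchmark_config(variant: str) -> BenchmarkGrid:
    """The two standard benchmark grids.

    "fig2": linear blocks, Spearman, target FDR swept over
    {0.05, 0.1, 0.25, 0.5} at FNT 0.2 plus an FNT sweep.
    "fig3": all relationship shapes crossed with the fast measures
    (spearman, pearson, mi, xicor); the permutation-heavy dcor/nmi are left
    out of the grid.
    """
    if variant == "fig2":
        return BenchmarkGrid(
            replicates=50, n_x=200, n_y=200, n_samples=50,
            alphas=(0.05, 0.1, 0.25, 0.5),
            fnts=(0.2, 0.0, 0.1, 0.3, 0.5),
            assoc_types=("linear",),
            measures=("spearman",),
        )
    if variant == "fig3":
        return BenchmarkGrid(
            replicates=50, n_x=200, n_y=200, n_samples=50,
            alphas=(0.05,),
            fnts=(0.2,),
            assoc_types=ASSOC_TYPES,
            measures=("spearman", "pearson", "mi", "xicor"),
        )
    raise ValueError("variant must be 'fig2' or 'fig3'")
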