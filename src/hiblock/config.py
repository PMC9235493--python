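"""Run configuration shared by the estimator, the pipeline and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

#: association measures operating on raw continuous values
CONTINUOUS_MEASURES = ("spearman", "pearson", "xicor", "dcor")
#: measures requiring a discrete representation (and accepting categoricals)
DISCRETE_MEASURES = ("mi", "nmi")
MEASURES = CONTINUOUS_MEASURES + DISCRETE_MEASURES


@dataclass
class AnalysisConfig:
    """All knobs of one paired-table analysis.

    alpha is the target FDR for the global BH threshold; fnt is the
    false-negative tolerance — the fraction of pairwise tests inside a block
    allowed to miss BH rejection while the block still counts as significant.
    """

    measure: str = "spearman"
    alpha: float = 0.05
    fnt: float = 0.2
    n_permutations: int = 1000
    seed: int = 0
    variance_frequency_threshold: float = 1.0
    max_blocks_shown: int = 30
    bins_override: int | None = None

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; choose one of {MEASURES}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 <= self.fnt <= 1.0:
            raise ValueError("fnt must be in [0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if not 0.0 < self.variance_frequency_threshold <= 1.0:
            raise ValueError("variance_frequency_threshold must be in (0, 1]")
        if self.max_blocks_shown < 1:
            raise ValueError("max_blocks_shown must be positive")
        if self.bins_override is not None and self.bins_override < 1:
            raise ValueError("bins_override must be positive")

    def to_dict(self) -> dict:
        return asdict(self)
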