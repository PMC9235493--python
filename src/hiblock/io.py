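"""Feature tables: the tab-separated feature x sample matrices the tool consumes.

A feature table has features on rows and samples on columns, with the first
column holding feature IDs and the header row holding sample IDs.  Features are
either continuous (numeric) or categorical (labels); two tables entering a
paired analysis must share an identical, identically ordered sample axis.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("hiblock")

#: cell contents treated as missing in TSV input
MISSING_TOKENS = {"", "NA", "NaN", "nan"}

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass
class FeatureTable:
    """A named feature x sample matrix with per-feature kind.

    ``values`` is a float matrix; continuous features hold raw measurements,
    categorical features hold non-negative integer category codes (the code
    order follows sorted label order), and missing cells hold NaN in both
    cases.  ``categories`` maps a categorical feature ID to its label list so
    codes can be round-tripped back to labels.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    kinds: list[str]
    categories: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name} ID: {i!r}")
                seen.add(i)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(self.kinds) != len(self.feature_ids):
            raise ValueError("one kind per feature required")
        for k in self.kinds:
            if k not in (CONTINUOUS, CATEGORICAL):
                raise ValueError(f"unknown feature kind {k!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def select_features(self, idx: np.ndarray | list[int]) -> "FeatureTable":
        idx = np.asarray(idx, dtype=int)
        fids = [self.feature_ids[i] for i in idx]
        return FeatureTable(
            feature_ids=fids,
            sample_ids=list(self.sample_ids),
            values=self.values[idx],
            kinds=[self.kinds[i] for i in idx],
            categories={f: self.categories[f] for f in fids if f in self.categories},
        )

    def select_samples(self, idx: np.ndarray | list[int]) -> "FeatureTable":
        idx = np.asarray(idx, dtype=int)
        return FeatureTable(
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
            kinds=list(self.kinds),
            categories=dict(self.categories),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Feature x sample DataFrame with labels restored for categorical rows."""
        df = pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids, dtype=object)
        for i, fid in enumerate(self.feature_ids):
            if self.kinds[i] == CATEGORICAL:
                labels = self.categories.get(fid, [])
                row = [
                    labels[int(v)] if np.isfinite(v) else np.nan
                    for v in self.values[i]
                ]
                df.loc[fid] = row
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kinds: dict[str, str] | None = None) -> "FeatureTable":
        """Build a table from a feature x sample DataFrame, inferring kinds.

        A row is continuous when every non-missing cell parses as a number;
        otherwise categorical.  ``kinds`` overrides inference per feature ID.
        """
        feature_ids = [str(f) for f in df.index]
        sample_ids = [str(s) for s in df.columns]
        values = np.full(df.shape, np.nan)
        out_kinds: list[str] = []
        categories: dict[str, list[str]] = {}
        raw = df.to_numpy(dtype=object)
        for i, fid in enumerate(feature_ids):
            cells = raw[i]
            present = [c for c in cells if not _is_missing(c)]
            numeric = _try_numeric(present)
            kind = CONTINUOUS if numeric is not None else CATEGORICAL
            if kinds and fid in kinds:
                kind = kinds[fid]
                if kind == CONTINUOUS and numeric is None:
                    raise ValueError(f"feature {fid!r} declared continuous but holds non-numeric labels")
            if kind == CONTINUOUS:
                for j, c in enumerate(cells):
                    if not _is_missing(c):
                        values[i, j] = float(c)
            else:
                labels = sorted({str(c) for c in present})
                code = {lab: k for k, lab in enumerate(labels)}
                categories[fid] = labels
                for j, c in enumerate(cells):
                    if not _is_missing(c):
                        values[i, j] = code[str(c)]
            out_kinds.append(kind)
        return cls(feature_ids, sample_ids, values, out_kinds, categories)


def _is_missing(cell: object) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and np.isnan(cell):
        return True
    return isinstance(cell, str) and cell.strip() in MISSING_TOKENS


def _try_numeric(cells: list[object]) -> list[float] | None:
    out = []
    for c in cells:
        try:
            out.append(float(c))
        except (TypeError, ValueError):
            return None
    return out


def read_feature_table(path: str, kinds: dict[str, str] | None = None) -> FeatureTable:
    """Read a TSV feature table (header = sample IDs, first column = feature IDs).

    Missing cells are empty or "NA".  Kind inference is automatic (all-numeric
    row -> continuous, else categorical); pass ``kinds`` to override.
    Duplicate IDs and ragged rows raise with the offending ID / line number.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        sample_ids = [c.strip() for c in header[1:]]
        width = len(header)
        feature_ids: list[str] = []
        rows: list[list[str]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(row)} fields, expected {width})"
                )
            feature_ids.append(row[0].strip())
            rows.append(row[1:])
    df = pd.DataFrame(rows, index=feature_ids, columns=sample_ids, dtype=object)
    return FeatureTable.from_dataframe(df, kinds=kinds)


def write_feature_table(table: FeatureTable, path: str) -> None:
    df = table.to_dataframe()
    df.index.name = "feature"
    df.to_csv(path, sep="\t", na_rep="NA")


def align_tables(x: FeatureTable, y: FeatureTable) -> tuple[FeatureTable, FeatureTable]:
    """Restrict both tables to their shared samples, in x's sample order.

    Dropped samples are logged as a warning; an empty intersection is an error
    (the paired analysis is undefined without co-indexed samples).
    """
    shared = set(x.sample_ids) & set(y.sample_ids)
    if not shared:
        raise ValueError("tables share no sample IDs; cannot pair")
    keep = [s for s in x.sample_ids if s in shared]
    dropped = sorted((set(x.sample_ids) | set(y.sample_ids)) - shared)
    if dropped:
        logger.warning("dropping %d unshared sample(s): %s", len(dropped), ", ".join(dropped))
    xi = [x.sample_ids.index(s) for s in keep]
    ypos = {s: j for j, s in enumerate(y.sample_ids)}
    yi = [ypos[s] for s in keep]
    return x.select_samples(xi), y.select_samples(yi)
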