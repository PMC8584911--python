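"""Tabular I/O, normalization and stratified splitting for expression data.

The on-disk convention is plain TSV with a header row. Expression tables may
be stored samples-in-rows or features-in-rows; the ``transpose`` flag resolves
the orientation at load time, and the in-memory convention is always
samples x features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split


class ValidationError(ValueError):
    """Input violates a structural contract (duplicate IDs, non-finite cell...)."""


class ParseError(ValueError):
    """A cell of an input table could not be parsed as a number."""


@dataclass
class ExpressionMatrix:
    """A samples x features matrix of non-negative expression values.

    Attributes
    ----------
    sample_ids : list of str
        Unique row identifiers (patients / cells).
    feature_ids : list of str
        Unique column identifiers (genes / lncRNAs).
    values : ndarray of shape (n_samples, n_features)
        Expression values; finite reals.
    normalized : bool
        True once per-feature min-max scaling to [0, 1] has been applied.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_s, n_f = self.values.shape
        if len(self.sample_ids) != n_s or len(self.feature_ids) != n_f:
            raise ValidationError(
                f"ID lengths ({len(self.sample_ids)}, {len(self.feature_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValidationError(f"duplicate {name} IDs: {dupes[:5]}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_index(self, feature_ids: Sequence[str]) -> np.ndarray:
        """Column indices of the given feature IDs (error on unknown IDs)."""
        lookup = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in lookup]
        if missing:
            raise KeyError(f"unknown feature IDs: {sorted(missing)[:5]}")
        return np.array([lookup[f] for f in feature_ids], dtype=int)

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.feature_index(feature_ids)
        return ExpressionMatrix(
            sample_ids=list(self.sample_ids),
            feature_ids=[self.feature_ids[i] for i in idx],
            values=self.values[:, idx].copy(),
            normalized=self.normalized,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class LabelVector:
    """Class labels (e.g. cancer-type codes) aligned to sample IDs."""

    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValidationError("sample_ids and labels must have equal length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample IDs in label table")

    def aligned_to(self, m: ExpressionMatrix) -> np.ndarray:
        """Labels reordered to match the matrix's sample order."""
        lookup = dict(zip(self.sample_ids, self.labels))
        missing = [s for s in m.sample_ids if s not in lookup]
        if missing:
            raise ValidationError(f"samples without labels: {sorted(missing)[:5]}")
        return np.array([lookup[s] for s in m.sample_ids])


@dataclass
class ClinicalTable:
    """Right-censored survival records: time on study and event indicator."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    time_unit: str = "unspecified"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not (len(self.sample_ids) == len(self.time) == len(self.event)):
            raise ValidationError("clinical table columns have unequal lengths")
        if not np.all(self.time > 0):
            raise ValidationError("survival times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event indicator must be 0 (censored) or 1 (event)")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"duplicate column IDs in {path.name}: {dupes[:5]}")
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def load_expression(path: str | Path, transpose: bool = False) -> ExpressionMatrix:
    """Load a TSV expression table.

    Parameters
    ----------
    path : path to a tab-separated file with a header row and ID first column.
    transpose : set True when the file stores features as rows.
    """
    df = _read_tsv(path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"{Path(path).name}: cannot parse cell at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} (value {df.iat[r, c]!r})"
        )
    if transpose:
        numeric = numeric.T
    return ExpressionMatrix(
        sample_ids=[str(i) for i in numeric.index],
        feature_ids=[str(c) for c in numeric.columns],
        values=numeric.to_numpy(dtype=float),
    )


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def load_labels(path: str | Path, label_column: str | None = None) -> LabelVector:
    df = _read_tsv(path)
    col = label_column if label_column is not None else df.columns[0]
    return LabelVector(
        sample_ids=[str(i) for i in df.index],
        labels=[str(v) for v in df[col]],
    )


def write_labels(v: LabelVector, path: str | Path) -> None:
    pd.DataFrame({"label": v.labels}, index=v.sample_ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def load_clinical(path: str | Path) -> ClinicalTable:
    df = _read_tsv(path)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValidationError(f"clinical table must have a {col!r} column")
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    for col, series in (("time", time), ("event", event)):
        if series.isna().any():
            row = df.index[int(np.argwhere(series.isna().to_numpy())[0])]
            raise ParseError(f"cannot parse {col!r} at row {row!r}")
    return ClinicalTable(
        sample_ids=[str(i) for i in df.index],
        time=time.to_numpy(dtype=float),
        event=event.to_numpy(dtype=float).astype(int),
    )


def write_clinical(t: ClinicalTable, path: str | Path) -> None:
    pd.DataFrame({"time": t.time, "event": t.event}, index=t.sample_ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def min_max_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each feature column to [0, 1] via (x - min) / (max - min).

    Constant (zero-variance) columns map to all-zero so that dimensionality is
    preserved; such columns carry no signal either way. Statistics are computed
    on the full matrix, before any train/test split.
    """
    if m.normalized:
        raise ValidationError("matrix is already normalized")
    lo = m.values.min(axis=0)
    hi = m.values.max(axis=0)
    span = hi - lo
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    values = (m.values - lo) / safe_span
    values[:, constant] = 0.0
    return replace(m, values=values, normalized=True)


def stratified_split(
    m: ExpressionMatrix,
    labels: LabelVector,
    test_fraction: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test partition of sample indices.

    The per-class test proportion is within one sample of ``test_fraction``;
    the result is deterministic for a fixed seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    y = labels.aligned_to(m)
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < 2]
    if small.size:
        raise ValidationError(
            f"class {small[0]!r} has a single sample and cannot be split"
        )
    idx = np.arange(m.n_samples)
    train, test = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed, shuffle=True
    )
    return np.sort(train), np.sort(test)
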