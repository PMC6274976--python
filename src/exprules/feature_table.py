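"""Labeled gene x feature table: data model, validation and TSV/CSV I/O.

The table is the unit every pipeline stage consumes: one row per transcript,
a binary class label (lncRNA = positive, mRNA = negative) and a fixed-order
list of numeric feature columns.  Feature order in files is authoritative;
indices are 0-based internally and 1-based in user-facing reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

POSITIVE_LABEL = "lncRNA"
NEGATIVE_LABEL = "mRNA"

#: Canonical name of the specificity column; its values live in [0, 1] and
#: are exempt from the "expression column" semantics.
SPECIFICITY_FEATURE = "Expression specificity"


class FeatureTableError(ValueError):
    """Raised on any structural or value-level violation of the table contract."""


@dataclass
class FeatureTable:
    """Validated sample x feature matrix with binary labels.

    Parameters
    ----------
    sample_ids:
        Unique row identifiers.
    labels:
        Integer array, 1 = positive (lncRNA), 0 = negative (mRNA).
    feature_names:
        Unique column names, order authoritative.
    values:
        ``(n_samples, n_features)`` float array; finite, expression columns
        non-negative.
    """

    sample_ids: list[str]
    labels: np.ndarray
    feature_names: list[str]
    values: np.ndarray
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.sample_ids), -1)
        if self.validate:
            self._check()

    def _check(self) -> None:
        n, m = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise FeatureTableError(
                f"row mismatch: {len(self.sample_ids)} ids, {len(self.labels)} labels, "
                f"{n} value rows"
            )
        if len(self.feature_names) != m:
            raise FeatureTableError(
                f"column mismatch: {len(self.feature_names)} names vs {m} value columns"
            )
        if len(set(self.sample_ids)) != n:
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise FeatureTableError(f"duplicate sample ids: {dupes[:5]}")
        if len(set(self.feature_names)) != m:
            raise FeatureTableError("duplicate feature names")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise FeatureTableError("labels must be 0/1")
        if n and m and not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise FeatureTableError(
                f"non-finite value at row {self.sample_ids[r]!r}, "
                f"column {self.feature_names[c]!r}"
            )
        for j, name in enumerate(self.feature_names):
            if name == SPECIFICITY_FEATURE:
                col = self.values[:, j]
                if n and (col.min() < -1e-9 or col.max() > 1 + 1e-9):
                    raise FeatureTableError(
                        f"specificity column {name!r} outside [0, 1]"
                    )
            elif n and self.values[:, j].min() < 0:
                r = int(np.argmin(self.values[:, j]))
                raise FeatureTableError(
                    f"negative expression value at row {self.sample_ids[r]!r}, "
                    f"column {name!r}"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def label_texts(self) -> list[str]:
        return [POSITIVE_LABEL if y else NEGATIVE_LABEL for y in self.labels]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_names == other.feature_names
            and np.array_equal(self.labels, other.labels)
            and self.values.shape == other.values.shape
            and np.allclose(self.values, other.values, rtol=1e-9, atol=1e-12)
        )


def _parse_label(text: str, row_id: str) -> int:
    t = str(text).strip().lower()
    if t == POSITIVE_LABEL.lower():
        return 1
    if t == NEGATIVE_LABEL.lower():
        return 0
    raise FeatureTableError(f"unknown class label {text!r} at row {row_id!r}")


def _delimiter_for(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_feature_table(path: str | Path, delimiter: str | None = None) -> FeatureTable:
    """Read a labeled feature table from a delimited text file.

    Layout: header row, first column = id, second column = class
    ("lncRNA"/"mRNA", case-insensitive), remaining columns numeric features.
    The delimiter defaults from the extension (.csv = comma, else tab).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, header=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FeatureTableError("file needs at least id and class columns")
    ids = [str(v) for v in df.iloc[:, 0]]
    labels = np.array(
        [_parse_label(lab, rid) for rid, lab in zip(ids, df.iloc[:, 1])], dtype=int
    )
    feature_names = [str(c) for c in df.columns[2:]]
    values = np.empty((len(ids), len(feature_names)), dtype=float)
    for j, col in enumerate(df.columns[2:]):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = np.asarray(parsed.isna())
        if bad.any():
            r = int(np.argmax(bad))
            raise FeatureTableError(
                f"non-numeric cell {df[col].iloc[r]!r} at row {ids[r]!r}, "
                f"column {feature_names[j]!r}"
            )
        values[:, j] = parsed.to_numpy(dtype=float)
    return FeatureTable(ids, labels, feature_names, values)


def write_feature_table(
    table: FeatureTable, path: str | Path, delimiter: str | None = None
) -> None:
    """Write a table so that :func:`read_feature_table` recovers it.

    Values are rendered with 12 significant digits.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df.insert(0, "class", table.label_texts())
    df.insert(0, "id", table.sample_ids)
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def select_features(table: FeatureTable, subset: Sequence[int]) -> FeatureTable:
    """Column-slice a table by 0-based feature indices, preserving order."""
    subset = list(subset)
    if len(set(subset)) != len(subset):
        raise FeatureTableError(f"duplicate feature indices in subset: {subset}")
    for i in subset:
        if not 0 <= i < table.n_features:
            raise FeatureTableError(
                f"feature index {i} out of range [0, {table.n_features})"
            )
    return FeatureTable(
        sample_ids=list(table.sample_ids),
        labels=table.labels.copy(),
        feature_names=[table.feature_names[i] for i in subset],
        values=table.values[:, subset] if subset else np.empty((table.n_samples, 0)),
    )
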