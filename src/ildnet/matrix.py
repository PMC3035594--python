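"""Expression-matrix container shared by every analysis stage.

An :class:`ExpressionMatrix` holds log2 intensities as a pandas DataFrame
(rows = features, columns = samples) together with the feature kind
("mrna" or "mirna").  All downstream operations take and return this
container, so the pandas representation stays an implementation detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MRNA = "mrna"
MIRNA = "mirna"
_KINDS = (MRNA, MIRNA)


@dataclass
class ExpressionMatrix:
    """Log2 expression values for one platform.

    Parameters
    ----------
    values
        DataFrame of finite log2 intensities, index = feature ids,
        columns = sample ids.  Both axes must be unique.
    feature_kind
        Either ``"mrna"`` or ``"mirna"``.
    """

    values: pd.DataFrame
    feature_kind: str = MRNA

    def __post_init__(self) -> None:
        if self.feature_kind not in _KINDS:
            raise ValueError(f"feature_kind must be one of {_KINDS}, got {self.feature_kind!r}")
        if not self.values.index.is_unique:
            raise ValueError("duplicate feature ids")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [i for i in ids]
        missing = set(ids) - set(self.values.index)
        if missing:
            raise KeyError(f"features not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.values.loc[ids], self.feature_kind)

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        missing = set(ids) - set(self.values.columns)
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.values[list(ids)], self.feature_kind)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: first column ``feature_id``, one column per sample."""
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, feature_kind: str = MRNA) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, feature_kind)


@dataclass
class SampleMetadata:
    """Per-sample annotations: group label, FVC class, diagnosis, sex."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("group", "fvc_class", "diagnosis", "sex")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"metadata missing column {col!r}")
        if not self.table.index.is_unique:
            raise ValueError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Group labels aligned to *sample_ids* (raises on unknown id)."""
        return self.table.loc[list(sample_ids), "group"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def group_masks(labels: Sequence, case_label="case", control_label="control") -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks for the two groups, in (case, control) order."""
    lab = np.asarray(labels)
    case = lab == case_label
    control = lab == control_label
    return case, control
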