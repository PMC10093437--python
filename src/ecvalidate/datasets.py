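"""Tabular classification dataset container.

A :class:`Dataset` is a continuous feature matrix, a categorical label
vector and a vector of stable integer sample ids.  Ids are the currency of
error consistency — an error set is a set of sample *identities*, so ids
must survive shuffling, fold assignment and down-sampling unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError


@dataclass
class Dataset:
    features: np.ndarray  # (N, f) float
    labels: np.ndarray    # (N,) categorical
    ids: np.ndarray       # (N,) int, unique
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.ids = np.asarray(self.ids, dtype=int)
        if self.features.ndim != 2:
            raise InvalidInputError("features must be a 2-D matrix")
        n = self.features.shape[0]
        if len(self.labels) != n or len(self.ids) != n:
            raise InvalidInputError("features, labels and ids must have equal length")
        if len(np.unique(self.ids)) != n:
            raise InvalidInputError("sample ids must be unique")
        if pd.isna(self.labels).any():
            raise InvalidInputError("labels must not contain missing values")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, indices: Sequence[int]) -> "Dataset":
        """Row subset by positional index; original sample ids are kept."""
        idx = np.asarray(indices, dtype=int)
        return Dataset(self.features[idx], self.labels[idx], self.ids[idx],
                       meta=dict(self.meta))

    def label_of(self) -> dict[int, Any]:
        """Mapping sample id → true label."""
        return dict(zip(self.ids.tolist(), self.labels.tolist()))

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_column: str,
                       id_column: str | None = None) -> "Dataset":
        """Build a Dataset from a DataFrame with one label column.

        Feature columns must be numeric; ids default to the 0-based row
        position when no id column is given.
        """
        if label_column not in frame.columns:
            raise InvalidInputError(f"label column {label_column!r} not found")
        feature_cols = [c for c in frame.columns if c not in (label_column, id_column)]
        if not feature_cols:
            raise InvalidInputError("no feature columns present")
        bad = [c for c in feature_cols
               if not pd.api.types.is_numeric_dtype(frame[c])]
        if bad:
            raise InvalidInputError(
                f"non-numeric feature column(s): {', '.join(map(repr, bad))}")
        if frame[label_column].isna().any():
            raise InvalidInputError("labels must not contain missing values")
        if id_column is not None:
            if id_column not in frame.columns:
                raise InvalidInputError(f"id column {id_column!r} not found")
            ids = frame[id_column].to_numpy()
            if pd.Series(ids).duplicated().any():
                raise InvalidInputError("duplicate sample ids in id column")
        else:
            ids = np.arange(len(frame))
        return cls(frame[feature_cols].to_numpy(dtype=float),
                   frame[label_column].to_numpy(), ids,
                   meta={"feature_names": feature_cols})

    def to_dataframe(self, label_column: str = "label",
                     id_column: str = "sample_id") -> pd.DataFrame:
        names = self.meta.get("feature_names")
        if not names or len(names) != self.n_features:
            names = [f"feature_{k}" for k in range(self.n_features)]
        frame = pd.DataFrame(self.features, columns=names)
        frame[label_column] = self.labels
        frame[id_column] = self.ids
        return frame
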