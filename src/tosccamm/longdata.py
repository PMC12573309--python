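"""Long-format two-view longitudinal data containers.

A :class:`LongitudinalView` holds one dataset in long format: one row per
individual-visit, with an individual identifier, an observation time and a
numeric feature vector.  Individuals may have any number of visits (including
none), visit times are arbitrary reals and need not form a common grid, and
missingness is encoded as *absent rows* — a stored row never contains NaN.

A :class:`PairedLongitudinalData` couples two views (conventionally ``X`` with
``p`` features and ``Y`` with ``q`` features) over an overlapping set of
individuals.  The two views may cover different individuals-per-visit, different
numbers of visits per individual and non-matching time grids; that asymmetry is
the whole point of the trajectory-based alignment performed downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalView",
    "PairedLongitudinalData",
    "read_long_csv",
    "write_long_csv",
    "standardize_columns",
]


@dataclass
class LongitudinalView:
    """One longitudinal dataset in long format.

    Parameters
    ----------
    ids
        Individual identifier per row (length = number of visit rows).
    times
        Observation time per row, in study-time units (arbitrary reals).
    features
        ``(n_rows, p)`` numeric matrix; row ``r`` is the feature vector
        observed for ``ids[r]`` at ``times[r]``.
    feature_names
        Column labels, length ``p``.
    """

    ids: np.ndarray
    times: np.ndarray
    features: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.times = np.asarray(self.times, dtype=float)
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim == 1:
            self.features = self.features.reshape(-1, 1)
        n = len(self.ids)
        if len(self.times) != n or self.features.shape[0] != n:
            raise ValueError(
                f"ids ({n}), times ({len(self.times)}) and features "
                f"({self.features.shape[0]} rows) must have equal length"
            )
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.features.shape[1])]
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length does not match feature columns")
        if n and not np.all(np.isfinite(self.times)):
            raise ValueError("observation times must be finite")
        if n and not np.all(np.isfinite(self.features)):
            bad = np.argwhere(~np.isfinite(self.features))[0]
            raise ValueError(
                f"non-finite feature value at row {bad[0]}, column "
                f"{self.feature_names[bad[1]]} (missingness must be encoded as absent rows)"
            )

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def unique_ids(self) -> list:
        """Distinct individuals in order of first appearance."""
        return list(pd.unique(self.ids))

    def block(self, individual) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(times, submatrix)`` for one individual.

        The block is the ``m_i × p`` stack of that individual's visits in row
        order; an unknown id yields an empty ``0 × p`` block (an individual may
        be absent from a view entirely).
        """
        mask = self.ids == individual
        return self.times[mask], self.features[mask]

    def subset(self, individuals: Sequence) -> "LongitudinalView":
        """Rows belonging to the given individuals, original order preserved."""
        keep = set(individuals)
        mask = np.fromiter((i in keep for i in self.ids), bool, count=self.n_rows)
        return LongitudinalView(
            self.ids[mask], self.times[mask], self.features[mask], list(self.feature_names)
        )

    def to_frame(self, id_col: str = "id", time_col: str = "time") -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df.insert(0, time_col, self.times)
        df.insert(0, id_col, self.ids)
        return df

    def copy(self) -> "LongitudinalView":
        return LongitudinalView(
            self.ids.copy(), self.times.copy(), self.features.copy(), list(self.feature_names)
        )


@dataclass
class PairedLongitudinalData:
    """Two longitudinal views over an overlapping set of individuals."""

    x_view: LongitudinalView
    y_view: LongitudinalView

    def __post_init__(self) -> None:
        x_ids = set(self.x_view.unique_ids)
        y_ids = set(self.y_view.unique_ids)
        only = x_ids.symmetric_difference(y_ids)
        if x_ids and y_ids and not (x_ids & y_ids):
            warnings.warn("the two views share no individual ids", stacklevel=2)
        elif only:
            warnings.warn(
                f"{len(only)} id(s) appear in only one view; they are retained "
                "(trajectory predictions for them use fixed effects only)",
                stacklevel=2,
            )

    @property
    def individuals(self) -> list:
        """Union of ids across views, X-view order first."""
        seen = list(pd.unique(self.x_view.ids))
        extra = [i for i in pd.unique(self.y_view.ids) if i not in set(seen)]
        return seen + extra

    @property
    def union_times(self) -> np.ndarray:
        """Sorted union time vector t = ∪_i (tx_i ∪ ty_i)."""
        return np.unique(np.concatenate([self.x_view.times, self.y_view.times]))


def read_long_csv(path, id_col: str = "id", time_col: str = "time") -> LongitudinalView:
    """Read a long-format CSV/TSV file into a :class:`LongitudinalView`.

    The delimiter is inferred from the extension (``.tsv``/``.txt`` → tab,
    otherwise comma).  Rows are kept in file order; duplicate ``(id, time)``
    rows are valid distinct visits and kept.  All non-id, non-time columns must
    be numeric.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype={id_col: str})
    for col in (id_col, time_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    feat_cols = [c for c in df.columns if c not in (id_col, time_col)]
    feats = df[feat_cols]
    for col in feat_cols:
        coerced = pd.to_numeric(feats[col], errors="coerce")
        bad = coerced.isna() & feats[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {feats[col].iloc[row]!r} in column {col!r}, "
                f"data row {row} of {path}"
            )
    return LongitudinalView(
        ids=df[id_col].to_numpy(dtype=object),
        times=pd.to_numeric(df[time_col]).to_numpy(dtype=float),
        features=feats.to_numpy(dtype=float),
        feature_names=feat_cols,
    )


def write_long_csv(view: LongitudinalView, path, id_col: str = "id", time_col: str = "time") -> None:
    """Write a view in long format; floats carry 17 significant digits so a
    read→write→read round trip is exact."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    view.to_frame(id_col, time_col).to_csv(path, sep=sep, index=False, float_format="%.17g")


def standardize_columns(
    view: LongitudinalView, *, ddof: int = 1
) -> tuple[LongitudinalView, np.ndarray, np.ndarray]:
    """Center each feature column to mean 0 and scale to unit sample variance.

    Zero-variance columns are centered only and their scale recorded as 1.
    Returns ``(standardized_view, centers, scales)`` so the transform can be
    reported and inverted.
    """
    if view.n_rows < 2:
        raise ValueError("standardization needs at least 2 rows (variance undefined)")
    centers = view.features.mean(axis=0)
    scales = view.features.std(axis=0, ddof=ddof)
    scales = np.where(scales <= 0.0, 1.0, scales)
    out = LongitudinalView(
        view.ids.copy(),
        view.times.copy(),
        (view.features - centers) / scales,
        list(view.feature_names),
    )
    return out, centers, scales
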