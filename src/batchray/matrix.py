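"""Core in-memory containers: feature-by-sample matrix and sample annotations.

The matrix convention throughout the package is the dominant omics one:
features (genes, probes) in rows, samples in columns, with unique string
identifiers on both axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, MatrixParseError

logger = logging.getLogger(__name__)


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise MatrixParseError(f"duplicate {kind} ID: {x!r}")
        seen.add(x)


@dataclass
class FeatureMatrix:
    """A numeric feature x sample matrix with identifiers.

    Parameters
    ----------
    values
        Real matrix of shape (n_features, n_samples).
    feature_ids
        Unique row identifiers, length n_features.
    sample_ids
        Unique column identifiers, length n_samples.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(x) for x in self.feature_ids]
        self.sample_ids = [str(x) for x in self.sample_ids]
        if self.values.ndim != 2:
            raise MatrixParseError("matrix values must be 2-dimensional")
        n, d = self.values.shape
        if len(self.feature_ids) != n:
            raise MatrixParseError(
                f"{len(self.feature_ids)} feature IDs for {n} rows"
            )
        if len(self.sample_ids) != d:
            raise MatrixParseError(
                f"{len(self.sample_ids)} sample IDs for {d} columns"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def subset_samples(self, sample_ids: list[str]) -> "FeatureMatrix":
        """Return a matrix restricted to ``sample_ids`` in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return FeatureMatrix(self.values[:, idx], list(self.feature_ids), list(sample_ids))

    def subset_features(self, feature_ids: list[str]) -> "FeatureMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return FeatureMatrix(self.values[idx, :], list(feature_ids), list(self.sample_ids))


@dataclass
class SampleAnnotation:
    """Per-sample categorical/ordinal labels for one or more variables.

    ``level_order`` optionally fixes an explicit level ordering per variable
    (used for trend trajectories); when present for a variable it must list
    every observed level exactly once.
    """

    table: pd.DataFrame  # index = sample IDs, one column per variable
    level_order: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise MatrixParseError(f"duplicate sample ID in annotation: {dups[0]!r}")
        self.table = self.table.astype("string")
        for var, order in self.level_order.items():
            observed = set(self.labels_for(var, self.sample_ids).dropna())
            if set(order) != observed or len(order) != len(set(order)):
                raise MatrixParseError(
                    f"level_order for {var!r} must contain every observed "
                    f"level exactly once (observed: {sorted(observed)})"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def variables(self) -> list[str]:
        return list(self.table.columns)

    def labels_for(self, variable: str, sample_ids: list[str]) -> pd.Series:
        """Labels of ``variable`` for ``sample_ids``, index-aligned."""
        if variable not in self.table.columns:
            raise KeyError(
                f"variable {variable!r} not in annotation; "
                f"available: {self.variables}"
            )
        return self.table[variable].reindex(sample_ids)

    def levels(self, variable: str) -> list[str]:
        """Levels of ``variable`` in explicit order if set, else sorted."""
        if variable in self.level_order:
            return list(self.level_order[variable])
        return sorted(self.table[variable].dropna().unique())


def align_samples(
    m: FeatureMatrix, a: SampleAnnotation, variable: str
) -> tuple[FeatureMatrix, pd.Series]:
    """Restrict matrix and labels to samples carrying a label for ``variable``.

    The intersection keeps the matrix's sample order; dropped samples are
    logged loudly, never silently reordered.
    """
    labels = a.labels_for(variable, m.sample_ids)
    keep = [s for s, v in zip(m.sample_ids, labels) if pd.notna(v)]
    dropped = m.n_samples - len(keep)
    if dropped:
        logger.warning(
            "%d of %d samples lack a %r label and were dropped",
            dropped, m.n_samples, variable,
        )
    if len(keep) < 2:
        raise DegenerateDataError(
            f"fewer than 2 samples ({len(keep)}) remain after aligning "
            f"with variable {variable!r}"
        )
    sub = m.subset_samples(keep)
    return sub, a.labels_for(variable, keep)
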