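"""Reading and writing matrices and annotations, plus feature filtering.

Delimited matrices follow the standard omics layout: first column holds the
feature IDs, the header row holds the sample IDs, tab-delimited by default.
MatrixMarket (MTX) input needs sidecar ID files ``<stem>.rows.txt`` and
``<stem>.cols.txt`` (one ID per line).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import EmptyMatrixError, MatrixParseError
from .matrix import FeatureMatrix, SampleAnnotation

logger = logging.getLogger(__name__)

_DELIMS = {"tsv": "\t", "csv": ","}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "txt"):
        return "tsv"
    if suffix == "csv":
        return "csv"
    if suffix == "mtx":
        return "mtx"
    raise MatrixParseError(f"cannot infer matrix format from {path.name!r}")


def read_matrix(path: str | Path, format: str | None = None) -> FeatureMatrix:
    """Read a feature x sample matrix from TSV, CSV or MTX.

    Raises :class:`MatrixParseError` naming the offending row/column on
    duplicate IDs or non-numeric cells.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        return _read_mtx(path)
    if fmt not in _DELIMS:
        raise MatrixParseError(f"unknown matrix format {fmt!r}")
    # pandas mangles duplicate header entries ("s1.1"), so vet the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(_DELIMS[fmt])
    sample_ids = header[1:]
    if not sample_ids:
        raise MatrixParseError(f"{path.name}: header row has no sample IDs")
    dup = {s for s in sample_ids if sample_ids.count(s) > 1}
    if dup:
        raise MatrixParseError(f"{path.name}: duplicate sample ID {sorted(dup)[0]!r}")
    df = pd.read_csv(path, sep=_DELIMS[fmt], index_col=0, dtype=str)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        bad = _first_non_numeric(df)
        raise MatrixParseError(
            f"{path.name}: non-numeric value {bad[2]!r} at "
            f"feature {bad[0]!r}, sample {bad[1]!r}"
        ) from None
    m = FeatureMatrix(values, list(df.index), list(df.columns))
    logger.info("read %d features x %d samples from %s", m.n_features, m.n_samples, path)
    return m


def _first_non_numeric(df: pd.DataFrame) -> tuple[str, str, str]:
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        bad = converted.isna() & ~raw_na
        if bad.any():
            i = bad.idxmax()
            return str(i), str(col), str(df.at[i, col])
    raise AssertionError("no non-numeric cell found")  # pragma: no cover


def _sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".rows.txt"), stem.with_suffix(".cols.txt")


def _read_mtx(path: Path) -> FeatureMatrix:
    rows_path, cols_path = _sidecars(path)
    for p, kind in ((rows_path, "row"), (cols_path, "column")):
        if not p.exists():
            raise MatrixParseError(f"missing {kind}-ID sidecar file {p.name!r}")
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    feature_ids = rows_path.read_text().split()
    sample_ids = cols_path.read_text().split()
    return FeatureMatrix(np.asarray(mat, dtype=float), feature_ids, sample_ids)


def write_matrix(m: FeatureMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a matrix as TSV/CSV (full precision) or MTX with sidecar IDs."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        rows_path, cols_path = _sidecars(path)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.values))
        rows_path.write_text("\n".join(m.feature_ids) + "\n")
        cols_path.write_text("\n".join(m.sample_ids) + "\n")
        return
    if fmt not in _DELIMS:
        raise MatrixParseError(f"unknown matrix format {fmt!r}")
    m.to_frame().to_csv(path, sep=_DELIMS[fmt], index_label="id", float_format="%.17g")


def read_annotations(
    path: str | Path,
    variables: list[str] | None = None,
    level_order: dict[str, list[str]] | None = None,
) -> SampleAnnotation:
    """Read a sample annotation TSV (first column = sample ID).

    ``variables`` restricts to the named columns; requesting an absent
    variable raises with the list of available columns.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.name is None or df.shape[1] == 0:
        raise MatrixParseError(f"{path.name}: expected a sample-ID column plus variables")
    if variables is not None:
        missing = [v for v in variables if v not in df.columns]
        if missing:
            raise KeyError(
                f"variable(s) {missing} not in {path.name}; "
                f"available: {list(df.columns)}"
            )
        df = df[variables]
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("%d samples in %s lack labels for some variable", n_missing, path.name)
    return SampleAnnotation(df, level_order or {})


@dataclass
class FilterReport:
    """Counts of feature rows removed by each filtering rule."""

    na_removed: int = 0
    constant_removed: int = 0

    @property
    def total_removed(self) -> int:
        return self.na_removed + self.constant_removed


def filter_features(
    m: FeatureMatrix, drop_na: bool = True, drop_constant: bool = False
) -> tuple[FeatureMatrix, FilterReport]:
    """Drop feature rows with non-finite values and/or zero variance.

    Idempotent; raises :class:`EmptyMatrixError` if nothing survives.
    """
    report = FilterReport()
    keep = np.ones(m.n_features, dtype=bool)
    if drop_na:
        finite = np.isfinite(m.values).all(axis=1)
        report.na_removed = int((~finite).sum())
        keep &= finite
    if drop_constant:
        with np.errstate(invalid="ignore"):
            spread = np.nanmax(m.values, axis=1) - np.nanmin(m.values, axis=1)
        constant = keep & ~(spread > 0)
        report.constant_removed = int(constant.sum())
        keep &= ~constant
    if not keep.any():
        raise EmptyMatrixError("all feature rows removed by filtering")
    if report.total_removed:
        logger.info(
            "filtered %d features (%d non-finite, %d constant)",
            report.total_removed, report.na_removed, report.constant_removed,
        )
    kept_ids = [f for f, k in zip(m.feature_ids, keep) if k]
    return m.subset_features(kept_ids), report


def exclude_features(m: FeatureMatrix, ids: list[str]) -> FeatureMatrix:
    """Remove the named features, preserving the order of the rest.

    IDs not present are ignored with a logged count (they may belong to a
    platform-wide exclusion list).
    """
    drop = set(ids)
    absent = drop - set(m.feature_ids)
    if absent:
        logger.info("%d excluded feature IDs not present in matrix", len(absent))
    kept = [f for f in m.feature_ids if f not in drop]
    if not kept:
        raise EmptyMatrixError("excluding these features empties the matrix")
    removed = m.n_features - len(kept)
    if removed:
        logger.info("excluded %d features", removed)
    return m.subset_features(kept)
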