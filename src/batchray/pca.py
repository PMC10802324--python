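"""Sample-mode principal component analysis with per-group centroids.

Samples are the observations: each sample is a point in feature space, the
matrix is centered feature-wise (each gene's mean across samples subtracted),
and components are extracted by thin SVD of the centered matrix — the
numerically stable route when features vastly outnumber samples. Eigenvalues
use the 1/(D-1) covariance denominator; explained-variance fractions are
denominator-independent.

Sign convention: each component is oriented so its largest-magnitude feature
loading is positive (ties broken by lowest feature index), making scores
reproducible across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError
from .matrix import FeatureMatrix, SampleAnnotation

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Scores and spectrum of a fitted PCA.

    Attributes
    ----------
    scores
        (n_samples, n_components) sample coordinates on the components.
    eigenvalues
        Variances of the score columns (1/(D-1) denominator), non-increasing.
    explained_fraction
        Fraction of total variance captured by each kept component.
    loadings
        (n_features, n_components) orthonormal feature-space directions.
    feature_means
        Per-feature means subtracted during centering.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    sample_ids: list[str]
    loadings: np.ndarray
    feature_means: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


@dataclass
class GroupCentroids:
    """Arithmetic mean of member scores per group, in score space."""

    centroids: np.ndarray  # (n_groups, n_components)
    group_labels: list[str]
    group_sizes: np.ndarray

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    def frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.centroids.shape[1])]
        df = pd.DataFrame(self.centroids, index=self.group_labels, columns=cols)
        df.insert(0, "size", self.group_sizes)
        return df

    def coords(self, group: str) -> np.ndarray:
        return self.centroids[self.group_labels.index(group)]


def center_matrix(m: FeatureMatrix) -> tuple[FeatureMatrix, np.ndarray]:
    """Subtract each feature's mean across samples; returns the mean vector."""
    means = m.values.mean(axis=1)
    centered = FeatureMatrix(
        m.values - means[:, None], list(m.feature_ids), list(m.sample_ids)
    )
    return centered, means


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    # orient each component so its largest-|.| loading is positive;
    # np.argmax returns the first (lowest feature index) on ties
    for l in range(loadings.shape[1]):
        col = loadings[:, l]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, l] *= -1
            scores[:, l] *= -1


def compute_pca(m: FeatureMatrix, n_components: int = 2) -> PCAResult:
    """Fit PCA on the (internally centered) matrix and return the top
    ``n_components`` scores, eigenvalues and explained fractions.
    """
    max_l = min(m.n_features, m.n_samples)
    if not 1 <= n_components <= max_l:
        raise ValueError(
            f"n_components={n_components} outside [1, min(N, D)={max_l}]"
        )
    if not np.isfinite(m.values).all():
        raise ValueError("matrix contains non-finite values; filter first")
    centered, means = center_matrix(m)
    # thin SVD of the N x D centered matrix: columns of U are feature-space
    # directions, rows of (S * Vt).T are sample scores
    u, s, vt = np.linalg.svd(centered.values, full_matrices=False)
    total = float((s**2).sum())
    if total == 0.0:
        raise DegenerateDataError("matrix has zero total variance")
    loadings = u[:, :n_components]
    scores = (vt[:n_components].T * s[:n_components]).copy()
    _fix_signs(loadings, scores)
    eigenvalues = s[:n_components] ** 2 / (m.n_samples - 1)
    explained = s[:n_components] ** 2 / total
    return PCAResult(
        scores=scores,
        eigenvalues=eigenvalues,
        explained_fraction=explained,
        sample_ids=list(m.sample_ids),
        loadings=loadings,
        feature_means=means,
    )


def compute_centroids(
    r: PCAResult, a: SampleAnnotation, variable: str
) -> GroupCentroids:
    """Per-group arithmetic mean of score rows for ``variable``.

    Groups with zero members among the analyzed samples are omitted with a
    warning; every analyzed sample must carry a label.
    """
    labels = a.labels_for(variable, r.sample_ids)
    if labels.isna().any():
        missing = [s for s, v in labels.items() if pd.isna(v)]
        raise ValueError(
            f"{len(missing)} analyzed samples lack a {variable!r} label "
            f"(first: {missing[0]!r}); align samples first"
        )
    levels = a.levels(variable)
    observed = set(labels)
    kept, rows, sizes = [], [], []
    for lev in levels:
        if lev not in observed:
            logger.warning("group %r has no members among analyzed samples; omitted", lev)
            continue
        mask = (labels == lev).to_numpy()
        kept.append(lev)
        rows.append(r.scores[mask].mean(axis=0))
        sizes.append(int(mask.sum()))
    return GroupCentroids(
        centroids=np.vstack(rows),
        group_labels=kept,
        group_sizes=np.asarray(sizes, dtype=int),
    )
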