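"""Synthetic grouped Gaussian matrices with known batch structure.

Every scenario the visual/QC workflow targets — plain batch shifts, temporal
drift, and a hidden dichotomy (e.g., sex-linked probes) — can be generated
with controlled effect sizes, so the whole pipeline is testable without any
external download. Samples are spherical Gaussians in feature space; group
means are displaced along a configurable subspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix, SampleAnnotation, align_samples

DICHOTOMY_PREFIX = "dichot_"

_SUBSPACES = ("all-features", "first-axis", "random-direction")


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic grouped-Gaussian scenario.

    Attributes
    ----------
    n_groups
        Number of batches K.
    samples_per_group
        Either one int (balanced) or a list of K ints.
    n_features
        Dimensionality d of the feature space.
    group_mean_shift
        Per-feature displacement delta between consecutive group means.
    within_sd
        Within-group standard deviation sigma (spherical).
    shift_subspace
        Where the shift lives: every feature, the first coordinate axis, or
        a random unit direction.
    drift_per_step
        Centroid displacement per ordinal batch for trend scenarios.
    dichotomy_fraction
        Fraction of features carrying a hidden binary effect.
    dichotomy_effect
        Half-separation added (+/-) to affected features by the hidden
        binary variable.
    seed
        Seed for the scenario's private random generator.
    """

    n_groups: int = 3
    samples_per_group: int | list[int] = 20
    n_features: int = 200
    group_mean_shift: float = 1.0
    within_sd: float = 1.0
    shift_subspace: str = "random-direction"
    drift_per_step: float = 0.5
    dichotomy_fraction: float = 0.1
    dichotomy_effect: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_features < 1:
            raise ValueError("n_groups and n_features must be positive")
        if self.within_sd <= 0:
            raise ValueError("within_sd must be > 0")
        if not 0 <= self.dichotomy_fraction <= 1:
            raise ValueError("dichotomy_fraction must be in [0, 1]")
        if self.shift_subspace not in _SUBSPACES:
            raise ValueError(f"shift_subspace must be one of {_SUBSPACES}")
        sizes = self.group_sizes()
        if any(s < 1 for s in sizes):
            raise ValueError("samples_per_group entries must be positive")

    def group_sizes(self) -> list[int]:
        if isinstance(self.samples_per_group, int):
            return [self.samples_per_group] * self.n_groups
        sizes = list(self.samples_per_group)
        if len(sizes) != self.n_groups:
            raise ValueError("samples_per_group list must have n_groups entries")
        return sizes

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes())


def _shift_direction(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Unit-free shift vector: group j mean = j * group_mean_shift * direction,
    where direction has per-feature entries (not normalised for
    'all-features', so delta stays in per-feature units)."""
    d = spec.n_features
    if spec.shift_subspace == "all-features":
        return np.ones(d)
    if spec.shift_subspace == "first-axis":
        e = np.zeros(d)
        e[0] = 1.0
        return e
    v = rng.standard_normal(d)
    return v / np.linalg.norm(v)


def _ids(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    features = [f"f{i:05d}" for i in range(spec.n_features)]
    samples = [f"s{i:04d}" for i in range(spec.n_samples)]
    return features, samples


def _gaussian_groups(
    spec: SyntheticSpec, step: float, rng: np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    """Samples x features draw with group j mean at j*step*direction."""
    direction = _shift_direction(spec, rng)
    sizes = spec.group_sizes()
    blocks, labels = [], []
    for j, s in enumerate(sizes):
        mean = j * step * direction
        blocks.append(mean + spec.within_sd * rng.standard_normal((s, spec.n_features)))
        labels.extend([j] * s)
    return np.vstack(blocks), labels


def generate_grouped(spec: SyntheticSpec) -> tuple[FeatureMatrix, SampleAnnotation]:
    """K spherical Gaussian batches, group j mean = base + j*delta along the
    chosen subspace; annotation variable ``batch``."""
    rng = np.random.default_rng(spec.seed)
    data, idx = _gaussian_groups(spec, spec.group_mean_shift, rng)
    feature_ids, sample_ids = _ids(spec)
    matrix = FeatureMatrix(data.T, feature_ids, sample_ids)
    labels = [f"batch{j + 1}" for j in idx]
    table = pd.DataFrame({"batch": labels}, index=sample_ids)
    return matrix, SampleAnnotation(table)


def generate_trend(spec: SyntheticSpec) -> tuple[FeatureMatrix, SampleAnnotation]:
    """Ordinal batches whose means advance ``drift_per_step`` per batch along
    a fixed direction; the annotation carries an explicit level order."""
    rng = np.random.default_rng(spec.seed)
    data, idx = _gaussian_groups(spec, spec.drift_per_step, rng)
    feature_ids, sample_ids = _ids(spec)
    matrix = FeatureMatrix(data.T, feature_ids, sample_ids)
    order = [f"t{j + 1:02d}" for j in range(spec.n_groups)]
    labels = [order[j] for j in idx]
    table = pd.DataFrame({"time": labels}, index=sample_ids)
    return matrix, SampleAnnotation(table, level_order={"time": order})


def generate_dichotomy(spec: SyntheticSpec) -> tuple[FeatureMatrix, SampleAnnotation]:
    """Batches plus a hidden binary variable ``sex`` affecting a feature
    subset.

    A fraction ``dichotomy_fraction`` of features (IDs prefixed with
    ``dichot_`` so they can be excluded wholesale) get +effect for one sex
    and -effect for the other; batch labels are assigned independently of
    sex, mimicking a dichotomy that no pre-defined batch variable explains.
    """
    if spec.dichotomy_fraction <= 0:
        raise ValueError("dichotomy_fraction must be > 0 for a dichotomy scenario")
    rng = np.random.default_rng(spec.seed)
    data, idx = _gaussian_groups(spec, spec.group_mean_shift, rng)
    n = spec.n_samples
    sex = rng.permutation(np.array(["female", "male"]).repeat([n // 2, n - n // 2]))
    n_affected = max(1, round(spec.dichotomy_fraction * spec.n_features))
    affected = rng.choice(spec.n_features, size=n_affected, replace=False)
    signs = np.where(sex == "male", 1.0, -1.0)
    data[:, affected] += signs[:, None] * spec.dichotomy_effect
    feature_ids, sample_ids = _ids(spec)
    feature_ids = [
        DICHOTOMY_PREFIX + f if i in set(affected.tolist()) else f
        for i, f in enumerate(feature_ids)
    ]
    matrix = FeatureMatrix(data.T, feature_ids, sample_ids)
    table = pd.DataFrame(
        {"batch": [f"batch{j + 1}" for j in idx], "sex": sex}, index=sample_ids
    )
    return matrix, SampleAnnotation(table)


def mean_center_by_batch(
    m: FeatureMatrix, a: SampleAnnotation, variable: str
) -> FeatureMatrix:
    """Location-only batch correction: per feature, subtract each batch's
    mean and restore the global feature mean.

    This deliberately simple correction removes a pure mean-shift batch
    effect exactly, which is all the before/after QC workflow needs; it is
    not a shrinkage-based method and does not touch scale effects.
    """
    sub, labels = align_samples(m, a, variable)
    values = sub.values.copy()
    global_mean = values.mean(axis=1, keepdims=True)
    lab = labels.to_numpy()
    for lev in pd.unique(lab):
        cols = lab == lev
        values[:, cols] -= values[:, cols].mean(axis=1, keepdims=True)
    values += global_mean
    return FeatureMatrix(values, list(sub.feature_ids), list(sub.sample_ids))


def population_dsc(spec: SyntheticSpec, step: float | None = None) -> float:
    """Closed-form population DSC of a grouped scenario:
    sqrt(sum_j pi_j ||mu_j - M_o||^2) / sqrt(sum_j pi_j d sigma_j^2)."""
    if step is None:
        step = spec.group_mean_shift
    sizes = np.asarray(spec.group_sizes(), dtype=float)
    pi = sizes / sizes.sum()
    if spec.shift_subspace == "all-features":
        norm = np.sqrt(spec.n_features)
    else:
        norm = 1.0
    offsets = np.arange(spec.n_groups) * step * norm
    center = float((pi * offsets).sum())
    db = float(np.sqrt((pi * (offsets - center) ** 2).sum()))
    dw = spec.within_sd * np.sqrt(spec.n_features)
    return db / dw
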