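"""The dispersion separability criterion (DSC) with a permutation p-value.

The DSC quantifies how dispersed pre-defined groups of samples are relative
to the dispersion of samples within their groups:

    DSC = D_b / D_w,
    D_b = sqrt(trace S_b),   D_w = sqrt(trace S_w),

where S_b is the between-group scatter matrix (size-weighted outer products
of centroid deviations from the global mean) and S_w the within-group scatter
matrix (size-weighted within-group covariances), with group priors estimated
as pi_j = s_j / N. D_b is the root-mean-square distance between group
centroids and the global mean; D_w the root-mean-square distance of samples
from their group centroid. Because a trace of a sum of outer products is a
plain sum of squared coordinates, both traces reduce to streaming sums:

    D_w^2 = (1/N) sum_j sum_{h in j} sum_i (x_hij - mu_ij)^2
    D_b^2 = (1/N) sum_j s_j sum_i (mu_ij - M_i)^2

:func:`dsc_fast` implements the streaming form (no matrix products);
:func:`dsc_naive` builds S_b and S_w explicitly and serves as the
independent oracle — the equivalence of the two is the derivation made
executable.

Significance comes from a one-tailed permutation test: group labels are
shuffled (group sizes preserved) and the p-value is the fraction of permuted
DSC values greater than or equal to the observed one.

Rule of thumb for interpretation: DSC below 0.3 indicates reasonable
consistency among groups, 0.3-0.6 moderate differences, above 0.6 strong
differences. Outlier samples can inflate the DSC while leaving the p-value
non-significant, especially with small groups — always read the two
together.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ZeroWithinDispersionError
from .matrix import FeatureMatrix, SampleAnnotation, align_samples
from .pca import PCAResult

logger = logging.getLogger(__name__)

LOW_THRESHOLD = 0.3
STRONG_THRESHOLD = 0.6


@dataclass
class DSCResult:
    """Between/within dispersions and their ratio for one grouping."""

    dsc: float
    db: float
    dw: float
    n_samples: int
    n_groups: int
    space_tag: str = "overall"

    @property
    def interpretation(self) -> str:
        return interpret_dsc(self.dsc)


@dataclass
class PermutationResult:
    """Null DSC values from label permutations and the one-tailed p-value."""

    observed_dsc: float
    null_dsc: np.ndarray
    n_perm: int
    p_value: float
    seed: int | None = None


def _encode_labels(labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = np.asarray(pd.Series(labels).astype(str))
    groups, inv = np.unique(arr, return_inverse=True)
    counts = np.bincount(inv)
    return groups, inv, counts


def _db2_dw2(data: np.ndarray, inv: np.ndarray, k: int) -> tuple[float, float]:
    """Streaming-sum squared dispersions (no matrix products)."""
    n = data.shape[0]
    counts = np.bincount(inv, minlength=k).astype(float)
    sums = np.zeros((k, data.shape[1]))
    np.add.at(sums, inv, data)
    mu = sums / counts[:, None]
    grand = data.mean(axis=0)
    db2 = float((counts[:, None] * (mu - grand) ** 2).sum()) / n
    dw2 = float(((data - mu[inv]) ** 2).sum()) / n
    return db2, dw2


def _validate(data: np.ndarray, counts: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D (samples x dims) array")
    if len(counts) < 2:
        raise ValueError("DSC needs at least 2 groups")
    if not np.isfinite(data).all():
        raise ValueError("data contain non-finite values")
    if (counts == 1).any():
        logger.warning(
            "%d singleton group(s): they contribute 0 to within-group "
            "dispersion and can inflate the DSC misleadingly",
            int((counts == 1).sum()),
        )
    return data


def _finish(db2: float, dw2: float, n: int, k: int, space_tag: str) -> DSCResult:
    db, dw = float(np.sqrt(db2)), float(np.sqrt(dw2))
    if dw == 0.0:
        if db > 0.0:
            raise ZeroWithinDispersionError(db)
        warnings.warn(
            "degenerate data: zero between- and within-group dispersion; DSC set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
        dsc = 0.0
    else:
        dsc = db / dw
    return DSCResult(dsc=dsc, db=db, dw=dw, n_samples=n, n_groups=k, space_tag=space_tag)


def dsc_fast(data, labels, space_tag: str = "overall") -> DSCResult:
    """DSC via the trace formulation: streaming sums over samples and
    dimensions, no scatter matrices formed.

    Parameters
    ----------
    data
        (n_samples, n_dims) real array.
    labels
        Group assignment per sample (any hashable labels, >= 2 groups).
    """
    _, inv, counts = _encode_labels(labels)
    data = _validate(np.asarray(data, dtype=float), counts)
    if data.shape[0] != len(inv):
        raise ValueError("labels length does not match number of samples")
    db2, dw2 = _db2_dw2(data, inv, len(counts))
    return _finish(db2, dw2, data.shape[0], len(counts), space_tag)


def dsc_naive(data, labels, space_tag: str = "overall") -> DSCResult:
    """DSC via explicit between/within scatter matrices (the oracle route).

    Builds S_w = sum_j pi_j Sigma_j and
    S_b = sum_j pi_j (mu_j - M_o)(mu_j - M_o)^T with pi_j = s_j/N, then takes
    D_b = sqrt(trace S_b), D_w = sqrt(trace S_w).
    """
    groups, inv, counts = _encode_labels(labels)
    data = _validate(np.asarray(data, dtype=float), counts)
    n, d = data.shape
    if n != len(inv):
        raise ValueError("labels length does not match number of samples")
    pi = counts / n
    mo = np.zeros(d)
    mus = []
    for j in range(len(groups)):
        mus.append(data[inv == j].mean(axis=0))
        mo += pi[j] * mus[j]
    s_w = np.zeros((d, d))
    s_b = np.zeros((d, d))
    for j in range(len(groups)):
        members = data[inv == j]
        sigma_j = np.zeros((d, d))
        for row in members:
            dev = row - mus[j]
            sigma_j += np.outer(dev, dev)
        sigma_j /= counts[j]
        s_w += pi[j] * sigma_j
        dev = mus[j] - mo
        s_b += pi[j] * np.outer(dev, dev)
    return _finish(float(np.trace(s_b)), float(np.trace(s_w)), n, len(groups), space_tag)


def interpret_dsc(dsc: float) -> str:
    """Qualitative reading of a DSC value: low / moderate / strong.

    The 0.3 and 0.6 boundaries themselves classify as "moderate".
    """
    if dsc < 0:
        raise ValueError(f"DSC must be non-negative, got {dsc}")
    if dsc < LOW_THRESHOLD:
        return "low"
    if dsc <= STRONG_THRESHOLD:
        return "moderate"
    return "strong"


def _null_dsc(data: np.ndarray, inv: np.ndarray, k: int) -> float:
    """DSC of one permuted labelling, with degenerate completions:
    dw=0 & db>0 -> +inf (extreme separation, counts toward the tail);
    dw=0 & db=0 -> 0.
    """
    db2, dw2 = _db2_dw2(data, inv, k)
    if dw2 == 0.0:
        return np.inf if db2 > 0.0 else 0.0
    return float(np.sqrt(db2 / dw2))


def permutation_test(
    data,
    labels,
    n_perm: int = 2000,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    smoothed: bool = False,
) -> PermutationResult:
    """One-tailed permutation test for the DSC.

    Labels are shuffled uniformly at random ``n_perm`` times (sampling the
    assignment space with replacement; group sizes preserved by
    construction). ``p = #{null >= observed} / n_perm``; ties count toward
    the null. ``smoothed=True`` uses (count+1)/(n_perm+1) instead.
    Reproducible given ``seed``; pass ``rng`` to share a generator stream
    across several tests.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = dsc_fast(data, labels)
    data = np.asarray(data, dtype=float)
    _, inv, counts = _encode_labels(labels)
    k = len(counts)
    if rng is None:
        rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for t in range(n_perm):
        null[t] = _null_dsc(data, rng.permutation(inv), k)
    count = int((null >= observed.dsc).sum())
    p = (count + 1) / (n_perm + 1) if smoothed else count / n_perm
    return PermutationResult(
        observed_dsc=observed.dsc,
        null_dsc=null,
        n_perm=n_perm,
        p_value=float(p),
        seed=seed,
    )


def dsc_report(
    m: FeatureMatrix,
    r: PCAResult,
    a: SampleAnnotation,
    variable: str,
    n_perm: int = 2000,
    seed: int | None = 0,
) -> dict[str, tuple[DSCResult, PermutationResult]]:
    """Paired DSC + permutation test in the full feature space ("overall")
    and on the plotted score columns ("pca-L"), sharing one seed stream.

    Echoes the dual convention of figure captions: an "overall" DSC on all
    retained features and a "DSC for PCA" on the L components shown.
    """
    aligned, labels = align_samples(m, a, variable)
    if aligned.sample_ids != r.sample_ids:
        raise ValueError("PCA scores and matrix samples are not aligned")
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[DSCResult, PermutationResult]] = {}
    spaces = {
        "overall": aligned.values.T,  # samples x features
        f"pca-{r.n_components}": r.scores,
    }
    for tag, data in spaces.items():
        res = dsc_fast(data, labels, space_tag=tag)
        perm = permutation_test(data, labels, n_perm=n_perm, seed=seed, rng=rng)
        out[tag] = (res, perm)
    return out


def report_frame(
    report: dict[str, tuple[DSCResult, PermutationResult]], variable: str
) -> pd.DataFrame:
    """Flatten a :func:`dsc_report` result into the report-table layout."""
    rows = []
    for tag, (res, perm) in report.items():
        rows.append(
            {
                "variable": variable,
                "space": tag,
                "n_samples": res.n_samples,
                "n_groups": res.n_groups,
                "Db": res.db,
                "Dw": res.dw,
                "DSC": res.dsc,
                "p_value": perm.p_value,
                "n_perm": perm.n_perm,
                "interpretation": res.interpretation,
            }
        )
    return pd.DataFrame(rows)
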