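"""Construction, vectorization, and comparison of representational
dissimilarity matrices (RDMs).

An RDM summarizes the geometry of a condition-by-unit response matrix as
the matrix of pairwise dissimilarities between condition patterns.  Two
systems (a brain region and a model layer, say) are compared by
correlating the off-diagonal vectorizations of their RDMs rather than by
mapping units onto each other.

Conventions
-----------
* z-normalization uses the sample standard deviation (``ddof=1``).  For
  rows normalized this way the identity
  ``d_euclidean(i, j)**2 == 2 * (V - 1) * (1 - r_ij)`` holds exactly,
  where ``r_ij`` is the Pearson correlation between the rows, so the
  ``euclidean_z`` and ``correlation_distance`` metrics are rank-equivalent
  in the absence of ties.
* Vectorization takes the upper triangle in row-major order
  (``i < j``, ``i`` ascending then ``j``), matching
  :func:`scipy.spatial.distance.squareform`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .errors import InvalidRdmError, UndefinedCorrelationError, ZeroVarianceError

__all__ = [
    "ResponseMatrix",
    "RDM",
    "METRICS",
    "znormalize_pattern",
    "znormalize_rows",
    "build_rdm",
    "vectorize_rdm",
    "rdm_from_vector",
    "compare_rdms",
    "fisher_z",
    "pair_labels",
]

METRICS = ("euclidean_z", "correlation_distance", "euclidean")

#: clamp applied to |r| >= 1 before the Fisher transform
_FISHER_CLAMP = 1.0 - 1e-12


@dataclass
class ResponseMatrix:
    """A conditions-by-units real matrix with condition labels.

    Represents the response pattern of one system: one ROI of one subject
    (voxels as units) or one model layer (activations as units).
    """

    values: np.ndarray
    condition_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.condition_labels = [str(c) for c in self.condition_labels]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D conditions x units matrix")
        k, v = self.values.shape
        if k < 3:
            raise ValueError(f"need at least 3 conditions, got {k}")
        if v < 2:
            raise ValueError(f"need at least 2 units, got {v}")
        if len(self.condition_labels) != k:
            raise ValueError("condition_labels length must match row count")
        if len(set(self.condition_labels)) != k:
            raise ValueError("condition labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain missing or non-finite entries")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    @property
    def unit_count(self) -> int:
        return self.values.shape[1]


@dataclass
class RDM:
    """A symmetric zero-diagonal dissimilarity matrix over conditions."""

    values: np.ndarray
    metric: str
    condition_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape != (k, k):
            raise InvalidRdmError("RDM must be square")
        if not self.condition_labels:
            self.condition_labels = [f"c{i + 1}" for i in range(k)]
        if len(self.condition_labels) != k:
            raise InvalidRdmError("condition_labels length must match size")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise InvalidRdmError("RDM must be symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise InvalidRdmError("RDM diagonal must be exactly zero")
        if np.any(self.values < -1e-12):
            raise InvalidRdmError("RDM entries must be nonnegative")
        if self.metric == "correlation_distance" and np.any(self.values > 2 + 1e-9):
            raise InvalidRdmError("correlation-distance entries must be <= 2")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]


def znormalize_pattern(pattern: np.ndarray) -> np.ndarray:
    """z-score a single response pattern to mean 0 and unit sample sd.

    Raises
    ------
    ZeroVarianceError
        If the pattern is constant.
    """
    pattern = np.asarray(pattern, dtype=float)
    if pattern.ndim != 1 or pattern.size < 2:
        raise ValueError("pattern must be a 1-D vector of length >= 2")
    sd = pattern.std(ddof=1)
    if sd == 0.0:
        raise ZeroVarianceError("constant pattern: z-normalization undefined")
    return (pattern - pattern.mean()) / sd


def znormalize_rows(matrix: np.ndarray, labels: Sequence[str] | None = None) -> np.ndarray:
    """Row-wise z-normalization; names the offending condition on failure."""
    matrix = np.asarray(matrix, dtype=float)
    sd = matrix.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        name = labels[bad[0]] if labels is not None else f"row {bad[0]}"
        raise ZeroVarianceError(f"constant pattern for condition {name!r}")
    return (matrix - matrix.mean(axis=1, keepdims=True)) / sd[:, None]


def build_rdm(patterns: ResponseMatrix, metric: str = "euclidean_z") -> RDM:
    """Build the pairwise-dissimilarity matrix of a response matrix.

    Parameters
    ----------
    patterns
        Conditions-by-units response matrix.
    metric
        ``euclidean_z`` — Euclidean distance between row-wise z-scored
        patterns; ``correlation_distance`` — ``1 - pearson_r`` between raw
        rows; ``euclidean`` — raw Euclidean distance (testing convenience).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    x = patterns.values
    labels = patterns.condition_labels
    if metric == "euclidean_z":
        x = znormalize_rows(x, labels)
        d = _pairwise_euclidean(x)
    elif metric == "euclidean":
        d = _pairwise_euclidean(x)
    else:  # correlation_distance
        sd = x.std(axis=1, ddof=1)
        bad = np.flatnonzero(sd == 0.0)
        if bad.size:
            raise ZeroVarianceError(
                f"constant pattern for condition {labels[bad[0]]!r}: "
                "correlation distance undefined"
            )
        z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        r = (z @ z.T) / (x.shape[1] - 1)
        d = 1.0 - np.clip(r, -1.0, 1.0)
        np.fill_diagonal(d, 0.0)
        d = np.maximum(d, 0.0)
    d = 0.5 * (d + d.T)  # enforce exact symmetry against rounding
    return RDM(values=d, metric=metric, condition_labels=list(labels))


def _pairwise_euclidean(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def vectorize_rdm(rdm: RDM) -> np.ndarray:
    """Extract the upper triangle in row-major order (length K(K-1)/2)."""
    return squareform(rdm.values, checks=True).astype(float)


def rdm_from_vector(vector: np.ndarray, metric: str = "euclidean_z",
                    condition_labels: Sequence[str] | None = None) -> RDM:
    """Inverse of :func:`vectorize_rdm`."""
    mat = squareform(np.asarray(vector, dtype=float))
    labels = list(condition_labels) if condition_labels is not None else []
    return RDM(values=mat, metric=metric, condition_labels=labels)


def pair_labels(condition_labels: Sequence[str]) -> list[str]:
    """Labels ``"condA|condB"`` for the vectorized upper triangle."""
    k = len(condition_labels)
    return [f"{condition_labels[i]}|{condition_labels[j]}"
            for i in range(k) for j in range(i + 1, k)]


def compare_rdms(a: np.ndarray, b: np.ndarray, method: str = "spearman") -> float:
    """Correlate two dissimilarity vectors.

    ``spearman`` is the Pearson correlation of mid-rank (tie-averaged)
    ranks; ``pearson`` is the standard product-moment correlation.

    Raises
    ------
    UndefinedCorrelationError
        If either vector has zero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 entries to correlate")
    if method == "spearman":
        a, b = rankdata(a), rankdata(b)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    if a.std() == 0.0 or b.std() == 0.0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    if np.array_equal(a, b):
        return 1.0  # self-correlation is exactly 1 by definition
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def fisher_z(r: float) -> float:
    """Variance-stabilizing arctanh transform of a correlation.

    Values with ``|r| >= 1`` are clamped to ``1 - 1e-12`` in magnitude
    (with a warning) rather than raising, so that degenerate noise-free
    inputs do not halt group analyses.
    """
    r = float(r)
    if abs(r) >= 1.0:
        warnings.warn(
            f"correlation {r} clamped to +/-{_FISHER_CLAMP} before Fisher transform",
            RuntimeWarning,
            stacklevel=2,
        )
        r = np.sign(r) * _FISHER_CLAMP
    return float(np.arctanh(r))
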