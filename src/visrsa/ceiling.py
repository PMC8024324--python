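"""Group noise-ceiling bounds for ROI dissimilarity structures.

The upper bound is the mean over subjects of the correlation between each
subject's dissimilarity vector and the element-wise group mean over ALL
subjects; the lower bound replaces the group mean with the leave-one-out
mean excluding that subject.  Averaging is over raw correlations by
default; a Fisher-z-averaged variant is available behind a flag for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedCorrelationError, VisRsaError
from .geometry import compare_rdms, fisher_z

__all__ = ["CeilingEstimate", "upper_bound", "lower_bound", "estimate_ceiling"]


@dataclass
class CeilingEstimate:
    lower: float
    upper: float
    n_subjects: int
    method: str
    roi_name: str = ""

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")


def _stack(subject_vectors) -> np.ndarray:
    mat = np.asarray([np.asarray(v, dtype=float) for v in subject_vectors])
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise VisRsaError("need >= 2 subject vectors of equal length")
    return mat


def _average(correlations: list[float], fisher_average: bool) -> float:
    if fisher_average:
        return float(np.tanh(np.mean([fisher_z(r) for r in correlations])))
    return float(np.mean(correlations))


def upper_bound(subject_vectors, method: str = "spearman",
                fisher_average: bool = False) -> float:
    """Mean subject-to-full-group-mean correlation."""
    mat = _stack(subject_vectors)
    group = mat.mean(axis=0)
    rs = []
    for i, vec in enumerate(mat):
        try:
            rs.append(compare_rdms(vec, group, method=method))
        except UndefinedCorrelationError as exc:
            raise UndefinedCorrelationError(
                f"subject {i}: {exc} (upper-bound computation)"
            ) from exc
    return _average(rs, fisher_average)


def lower_bound(subject_vectors, method: str = "spearman",
                fisher_average: bool = False) -> float:
    """Mean subject-to-leave-one-out-group-mean correlation."""
    mat = _stack(subject_vectors)
    n = mat.shape[0]
    total = mat.sum(axis=0)
    rs = []
    for i, vec in enumerate(mat):
        loo = (total - vec) / (n - 1)
        try:
            rs.append(compare_rdms(vec, loo, method=method))
        except UndefinedCorrelationError as exc:
            raise UndefinedCorrelationError(
                f"subject {i}: {exc} (lower-bound computation)"
            ) from exc
    return _average(rs, fisher_average)


def estimate_ceiling(subject_vectors, method: str = "spearman",
                     roi_name: str = "", fisher_average: bool = False) -> CeilingEstimate:
    mat = _stack(subject_vectors)
    return CeilingEstimate(
        lower=lower_bound(mat, method, fisher_average),
        upper=upper_bound(mat, method, fisher_average),
        n_subjects=mat.shape[0],
        method=method,
        roi_name=roi_name,
    )
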