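"""2-D embedding of RDMs by classical (Torgerson) multidimensional
scaling, with Procrustes alignment replacing manual rotation/flips."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, orthogonal_procrustes
from scipy.spatial.distance import pdist

from .geometry import RDM

__all__ = ["EmbeddingResult", "classical_mds", "procrustes_align"]

log = logging.getLogger(__name__)


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray       # K x dims, centered at the origin
    eigenvalues: np.ndarray       # top eigenvalues of the centered Gram matrix
    stress: float                 # relative distance-reconstruction residual
    condition_labels: list[str] = field(default_factory=list)
    aligned_to: str | None = None


def classical_mds(rdm: RDM, dims: int = 2) -> EmbeddingResult:
    """Torgerson scaling: double-center ``-0.5 * J D^2 J`` and embed on the
    top ``dims`` nonnegative eigenpairs.

    Negative eigenvalues (non-Euclidean input) are dropped with a logged
    diagnostic; their coordinates are set to zero.
    """
    k = rdm.n_conditions
    if k < 3:
        raise ValueError("need at least 3 conditions to embed")
    d2 = rdm.values ** 2
    j = np.eye(k) - np.ones((k, k)) / k
    b = -0.5 * j @ d2 @ j
    b = 0.5 * (b + b.T)
    evals, evecs = eigh(b, subset_by_index=(k - dims, k - 1))
    evals, evecs = evals[::-1], evecs[:, ::-1]  # descending
    neg = evals < 0
    if neg.any():
        log.info("dropping %d negative eigenvalue(s) (min %.3g): input is not "
                 "exactly Euclidean in %d dims", int(neg.sum()), evals.min(), dims)
    coords = evecs * np.sqrt(np.maximum(evals, 0.0))
    coords = coords - coords.mean(axis=0)
    d_hat = pdist(coords)
    d = rdm.values[np.triu_indices(k, 1)]
    denom = float(np.sqrt(np.sum(d ** 2)))
    stress = float(np.sqrt(np.sum((d_hat - d) ** 2)) / denom) if denom > 0 else 0.0
    return EmbeddingResult(
        coordinates=coords,
        eigenvalues=evals,
        stress=stress,
        condition_labels=list(rdm.condition_labels),
    )


def procrustes_align(coords: np.ndarray, reference: np.ndarray,
                     labels=None, reference_labels=None) -> np.ndarray:
    """Rotate/reflect and translate ``coords`` onto ``reference``.

    Scale is deliberately NOT fitted, so all inter-point distances are
    preserved exactly; only the orthogonal transform minimizing the summed
    squared deviation to the reference is applied.
    """
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if coords.shape != reference.shape:
        raise ValueError("coords and reference must have matching shapes")
    if labels is not None and reference_labels is not None and list(labels) != list(reference_labels):
        raise ValueError("label mismatch between coords and reference")
    c_mean = coords.mean(axis=0)
    r_mean = reference.mean(axis=0)
    rot, _ = orthogonal_procrustes(coords - c_mean, reference - r_mean)
    return (coords - c_mean) @ rot + r_mean
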