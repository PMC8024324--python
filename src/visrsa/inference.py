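"""Group-level statistics: the hierarchy-correspondence test and the
proportion-of-explainable-variance-captured test, plus shared utilities
(one-sample one-tailed t-tests and Benjamini-Hochberg FDR control).

The correspondence test asks, per subject, whether the model layer best
correlated with each region climbs with the region's position in the
visual hierarchy: the Spearman rho between region ranks and best-layer
indices is Fisher-transformed and the group of per-subject values is
tested above zero with a one-tailed one-sample t-test.

The capture test divides each subject's region-layer RDM correlation by
the region's lower noise-ceiling bound, squares the ratio, picks the
layer with the highest group-mean proportion, and tests the subject
proportions at that layer below 1 (one-tailed), BH-corrected across
regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from .errors import VisRsaError
from .geometry import fisher_z

__all__ = [
    "LayerAssignment",
    "CorrespondenceResult",
    "CaptureResult",
    "best_layer_per_region",
    "correspondence_statistic",
    "group_test_positive",
    "group_test_below",
    "variance_captured",
    "test_full_capture",
    "bh_fdr",
]


@dataclass
class LayerAssignment:
    """Per-subject best-layer index (1-based, within the sampled-layer
    list) for each region, regions ordered low to high."""

    best_layer: np.ndarray
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.best_layer = np.asarray(self.best_layer, dtype=int)
        if not self.region_names:
            self.region_names = [f"region{i + 1}" for i in range(self.best_layer.size)]
        if len(self.region_names) != self.best_layer.size:
            raise ValueError("region_names length must match best_layer")
        if np.any(self.best_layer < 1):
            raise ValueError("best-layer indices are 1-based")


@dataclass
class CorrespondenceResult:
    mean_fisher_z: float
    t_stat: float
    df: int
    p_one_tailed: float
    p_fdr: float
    n_subjects: int


@dataclass
class CaptureResult:
    region_names: list[str]
    mean_proportion: np.ndarray        # regions x layers group means
    best_layer_for_test: np.ndarray    # 1-based, per region
    best_mean_proportion: np.ndarray   # per region, at the tested layer
    t_vs_1: np.ndarray
    p_one_tailed: np.ndarray
    p_fdr: np.ndarray


def best_layer_per_region(correlations: np.ndarray,
                          region_names=None) -> LayerAssignment:
    """Argmax layer per region; ties resolved to the lowest layer index."""
    table = np.asarray(correlations, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("correlations must be regions x layers with >= 2 layers")
    if not np.all(np.isfinite(table)):
        raise VisRsaError("undefined correlation cell in region-layer table")
    best = table.argmax(axis=1) + 1  # argmax returns first max -> lowest index
    names = list(region_names) if region_names is not None else []
    return LayerAssignment(best_layer=best, region_names=names)


def correspondence_statistic(assignment: LayerAssignment) -> float:
    """Fisher-z of the Spearman rho between region ranks and best layers.

    If every region picked the same layer the rank correlation is
    undefined; it is defined here as 0 (no evidence of hierarchy), with a
    warning.
    """
    layers = assignment.best_layer
    n = layers.size
    if n < 2:
        raise ValueError("need at least 2 regions")
    if np.all(layers == layers[0]):
        warnings.warn("all regions picked the same layer; rho defined as 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    region_ranks = np.arange(1, n + 1, dtype=float)
    rho = float(np.corrcoef(region_ranks, rankdata(layers))[0, 1])
    return fisher_z(np.clip(rho, -1.0, 1.0))


def _one_tailed_t(values: np.ndarray, popmean: float, tail: str):
    """One-sample t with zero-variance fallback by sign of the mean."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values")
    mean = values.mean()
    sd = values.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        warnings.warn("zero variance in group test; p resolved by sign of mean",
                      RuntimeWarning, stacklevel=3)
        on_alt = mean > popmean if tail == "greater" else mean < popmean
        t = np.inf if mean > popmean else (-np.inf if mean < popmean else 0.0)
        return float(t), df, 0.0 if on_alt else 1.0
    t = (mean - popmean) / (sd / np.sqrt(n))
    p = stats.t.sf(t, df) if tail == "greater" else stats.t.cdf(t, df)
    return float(t), df, float(p)


def group_test_positive(z_values) -> tuple[float, int, float]:
    """One-tailed one-sample t-test of mean > 0."""
    return _one_tailed_t(np.asarray(z_values), 0.0, "greater")


def group_test_below(values, popmean: float = 1.0) -> tuple[float, int, float]:
    """One-tailed one-sample t-test of mean < ``popmean``."""
    return _one_tailed_t(np.asarray(values), popmean, "less")


def variance_captured(r_subject: float, lower_ceiling: float) -> float:
    """Proportion of explainable RDM variance: ``(r / lower_ceiling)**2``.

    Not clipped at 1 — the vs-1 test handles direction.
    """
    if lower_ceiling <= 0:
        raise VisRsaError(
            f"lower noise ceiling {lower_ceiling} <= 0: region uninterpretable"
        )
    return float((r_subject / lower_ceiling) ** 2)


def test_full_capture(proportions: np.ndarray, region_names=None,
                      q: float = 0.05, per_subject_max: bool = False) -> CaptureResult:
    """Per region, test the best layer's variance-captured proportions vs 1.

    ``proportions`` is regions x layers x subjects.  By default the tested
    layer is the one with the highest group-mean proportion and subject
    values at that layer are tested below 1; ``per_subject_max`` instead
    tests each subject's own maximum across layers (biased upward; off by
    default).  p-values are BH-adjusted across regions.
    """
    arr = np.asarray(proportions, dtype=float)
    if arr.ndim != 3:
        raise ValueError("proportions must be regions x layers x subjects")
    n_regions = arr.shape[0]
    names = list(region_names) if region_names is not None else [
        f"region{i + 1}" for i in range(n_regions)
    ]
    mean_prop = arr.mean(axis=2)  # regions x layers
    best = mean_prop.argmax(axis=1)
    ts = np.empty(n_regions)
    ps = np.empty(n_regions)
    best_means = np.empty(n_regions)
    for r in range(n_regions):
        vals = arr[r].max(axis=0) if per_subject_max else arr[r, best[r], :]
        best_means[r] = vals.mean()
        ts[r], _, ps[r] = group_test_below(vals, 1.0)
    _, p_adj = bh_fdr(ps, q)
    return CaptureResult(
        region_names=names,
        mean_proportion=mean_prop,
        best_layer_for_test=best + 1,
        best_mean_proportion=best_means,
        t_vs_1=ts,
        p_one_tailed=ps,
        p_fdr=p_adj,
    )


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns ``(rejected, adjusted)`` where ``adjusted[j] = min over
    ranks >= rank(j) of m * p / rank``, capped at 1, and
    ``rejected <=> adjusted <= q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted <= q, adjusted
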