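"""Voxel selection: split-half reliability ranking and category-selectivity
flagging on run-level beta series.

A :class:`RunBetaSeries` holds runs x conditions x voxels beta estimates
for one ROI of one subject.  Reliable voxels are ranked by correlating
each voxel's condition profile between the odd-run mean and the even-run
mean; category-selective voxels are flagged by across-run paired t-tests
of a category group against every complement category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import VisRsaError
from .geometry import ResponseMatrix

__all__ = [
    "RunBetaSeries",
    "SelectivitySpec",
    "split_half_reliability",
    "select_top_k",
    "flag_category_selective",
    "average_runs",
    "UNRELIABLE",
]

#: sentinel reliability for voxels whose half-profiles are constant;
#: compares below every finite correlation so they are never selected.
UNRELIABLE = -np.inf


@dataclass
class RunBetaSeries:
    """Runs x conditions x voxels beta weights for one ROI of one subject."""

    betas: np.ndarray
    run_ids: list[int] = field(default_factory=list)
    condition_labels: list[str] = field(default_factory=list)
    roi_name: str = ""

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 3:
            raise ValueError("betas must be runs x conditions x voxels")
        r, k, v = self.betas.shape
        if r < 1:
            raise ValueError("need at least 1 run")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas contain missing or non-finite cells")
        if not self.run_ids:
            self.run_ids = list(range(1, r + 1))
        if not self.condition_labels:
            self.condition_labels = [f"c{i + 1}" for i in range(k)]
        if len(self.run_ids) != r or len(self.condition_labels) != k:
            raise ValueError("run_ids / condition_labels lengths must match betas")

    @property
    def n_runs(self) -> int:
        return self.betas.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.betas.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[2]


@dataclass
class SelectivitySpec:
    """Which category groups define selectivity, and at what alpha.

    ``target_sets`` maps a group name (e.g. ``"face"``) to the set of base
    category labels whose run-wise mean forms the group response; every
    base category outside the group is a complement the group must beat.
    ``format_collapse`` maps condition-label variants (e.g. format
    variants of one category) to their base category; labels not in the
    map are their own base category.
    """

    target_sets: Mapping[str, frozenset[str]]
    alpha: float = 0.05
    format_collapse: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        self.target_sets = {k: frozenset(v) for k, v in self.target_sets.items()}


def split_half_reliability(series: RunBetaSeries) -> np.ndarray:
    """Odd/even split-half reliability per voxel.

    Runs are split by 1-based acquisition order (runs 1,3,5,... vs
    2,4,6,...), averaged within each half, and each voxel's K-condition
    profile is Pearson-correlated between halves.  Voxels with a constant
    profile in either half receive the ``UNRELIABLE`` sentinel.
    """
    if series.n_runs < 2:
        raise VisRsaError("need at least 2 runs to split into halves")
    if series.n_conditions < 3:
        raise VisRsaError("need at least 3 conditions for reliability")
    odd = series.betas[0::2].mean(axis=0)   # K x V
    even = series.betas[1::2].mean(axis=0)
    return _columnwise_pearson(odd, even)


def _columnwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    sa = np.sqrt(np.sum(ac * ac, axis=0))
    sb = np.sqrt(np.sum(bc * bc, axis=0))
    out = np.full(a.shape[1], UNRELIABLE)
    ok = (sa > 0) & (sb > 0)
    out[ok] = np.sum(ac[:, ok] * bc[:, ok], axis=0) / (sa[ok] * sb[ok])
    out[ok] = np.clip(out[ok], -1.0, 1.0)
    return out


def select_top_k(reliabilities: np.ndarray, k: int = 75) -> np.ndarray:
    """Indices of the ``k`` most reliable voxels, ties broken by lower index.

    Raises if fewer than ``k`` voxels are available — the pipeline never
    silently pads a selection.
    """
    reliabilities = np.asarray(reliabilities, dtype=float)
    v = reliabilities.size
    if v < k:
        raise VisRsaError(
            f"cannot select top {k} of {v} voxels; lower k or supply more voxels"
        )
    # stable sort on negated values keeps lowest index first among ties
    order = np.argsort(-reliabilities, kind="stable")
    return np.sort(order[:k])


def flag_category_selective(series: RunBetaSeries, spec: SelectivitySpec) -> np.ndarray:
    """Boolean mask of voxels selective for any group in ``spec``.

    A voxel is flagged for a group iff for EVERY complement base category
    the across-run paired comparison (group mean minus complement) has a
    positive mean and a one-tailed paired-t p-value below ``spec.alpha``.
    Zero-variance paired differences are treated as non-significant.
    """
    if series.n_runs < 2:
        raise VisRsaError("need at least 2 runs for paired selectivity tests")
    collapsed, base_labels = _collapse_formats(series, spec.format_collapse)
    r, _, v = collapsed.shape
    label_ix = {c: i for i, c in enumerate(base_labels)}
    mask = np.zeros(v, dtype=bool)
    for group, members in spec.target_sets.items():
        missing = members - set(base_labels)
        if missing:
            raise VisRsaError(f"group {group!r} references unknown categories {sorted(missing)}")
        complements = [c for c in base_labels if c not in members]
        if not complements:
            raise VisRsaError(f"group {group!r} covers all conditions; no complement to test")
        gix = [label_ix[c] for c in members]
        group_resp = collapsed[:, gix, :].mean(axis=1)  # R x V
        flagged = np.ones(v, dtype=bool)
        for comp in complements:
            d = group_resp - collapsed[:, label_ix[comp], :]  # R x V
            mean = d.mean(axis=0)
            sd = d.std(axis=0, ddof=1)
            p = np.ones(v)
            ok = sd > 0
            t = np.zeros(v)
            t[ok] = mean[ok] / (sd[ok] / np.sqrt(r))
            p[ok] = stats.t.sf(t[ok], df=r - 1)
            flagged &= (mean > 0) & (p < spec.alpha)
            if not flagged.any():
                break
        mask |= flagged
    return mask


def _collapse_formats(series: RunBetaSeries,
                      format_collapse: Mapping[str, str]) -> tuple[np.ndarray, list[str]]:
    """Average condition variants into base categories, per run."""
    bases: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, label in enumerate(series.condition_labels):
        base = format_collapse.get(label, label)
        if base not in groups:
            groups[base] = []
            bases.append(base)
        groups[base].append(i)
    out = np.stack(
        [series.betas[:, groups[b], :].mean(axis=1) for b in bases], axis=1
    )
    return out, bases


def average_runs(series: RunBetaSeries,
                 voxel_subset: Sequence[int] | None = None) -> ResponseMatrix:
    """Mean beta over runs, restricted to ``voxel_subset`` columns."""
    if voxel_subset is None:
        subset = np.arange(series.n_voxels)
    else:
        subset = np.asarray(sorted(voxel_subset), dtype=int)
    if subset.size == 0:
        raise VisRsaError(
            f"empty voxel subset for ROI {series.roi_name!r} "
            f"(of {series.n_voxels} voxels none remain)"
        )
    mean = series.betas.mean(axis=0)[:, subset]
    return ResponseMatrix(values=mean, condition_labels=list(series.condition_labels))
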