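"""Replicate studies: parameter-recovery and error-rate simulations used
to validate the pipeline (and to calibrate synthetic noise levels).

These compose the same stage functions as :func:`visrsa.pipeline.run_pipeline`
but skip report writing and embeddings, so thousands of replicates stay
cheap on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ceiling import lower_bound, upper_bound
from .pipeline import correlation_tables, correspondence_test, layer_rdvs, \
    subject_region_rdvs
from .simulate import SimulationConfig, generate_brain_data, \
    generate_ground_truth, generate_model_layers

__all__ = [
    "GroupRunResult",
    "lean_group_run",
    "hierarchy_recovery_study",
    "null_rejection_study",
    "ceiling_bounds_study",
    "study_config",
]


def study_config(**overrides) -> SimulationConfig:
    """Small-but-faithful default design for replicate studies.

    Six subjects, six regions, eight categories, sixteen runs, the planted
    mapping ``(1, 3, 5, 7, 9, 11)`` over eleven layers, and noise levels
    calibrated so the lower noise-ceiling bound lands in ~0.7-0.9.
    """
    base = dict(
        n_subjects=6, n_regions=6, n_categories=8, n_runs=16,
        n_voxels_per_region=120, n_model_layers=11,
        subject_loading_sd=0.8, run_noise_sd=2.5,
        n_latent_features=30, seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class GroupRunResult:
    p_correspondence: float
    mean_fisher_z: float
    lower_ceilings: np.ndarray
    upper_ceilings: np.ndarray
    best_layers: np.ndarray  # subjects x regions
    tables: np.ndarray       # subjects x regions x layers


def lean_group_run(config: SimulationConfig, mode: str = "planted",
                   metric: str = "euclidean_z", comparison: str = "spearman",
                   top_k: int = 75) -> GroupRunResult:
    """One simulated group through selection, RDMs, ceilings, and the
    correspondence test (no capture/MDS/report)."""
    truth = generate_ground_truth(config)
    dataset = generate_brain_data(truth)
    layers = generate_model_layers(truth, mode=mode)
    brain, _ = subject_region_rdvs(dataset, metric=metric, top_k=top_k)
    lmat = layer_rdvs(layers, metric=metric)
    tables = correlation_tables(brain, lmat, method=comparison)
    zs, best, result = correspondence_test(tables, dataset.region_names)
    lows = np.array([lower_bound(brain[:, r, :], comparison)
                     for r in range(brain.shape[1])])
    ups = np.array([upper_bound(brain[:, r, :], comparison)
                    for r in range(brain.shape[1])])
    return GroupRunResult(
        p_correspondence=result.p_one_tailed,
        mean_fisher_z=result.mean_fisher_z,
        lower_ceilings=lows, upper_ceilings=ups,
        best_layers=best, tables=tables)


def hierarchy_recovery_study(n_replicates: int = 200,
                             config: SimulationConfig | None = None,
                             seed: int = 0, alpha: float = 0.05):
    """Fraction of replicate groups whose correspondence test is
    significant, plus the distribution of lower-ceiling bounds."""
    base = config or study_config()
    rejections = 0
    lows = []
    for i in range(n_replicates):
        cfg = base.with_(seed=seed * 1_000_003 + i)
        res = lean_group_run(cfg, mode="planted")
        rejections += res.p_correspondence < alpha
        lows.append(res.lower_ceilings.mean())
    return rejections / n_replicates, np.asarray(lows)


def null_rejection_study(n_replicates: int = 2000,
                         config: SimulationConfig | None = None,
                         seed: int = 0, alpha: float = 0.05) -> float:
    """Type-I error of the correspondence test under the pure null.

    Model layers are independent of the brain AND the brain carries no
    shared geometry (signal-free voxels), so per-subject statistics are
    independent and exchangeable over regions — the setting in which the
    one-sample t-test's error rate is interpretable.
    """
    base = config or study_config(n_signal_voxels_per_region=0)
    if base.n_signal_voxels_per_region != 0:
        base = base.with_(n_signal_voxels_per_region=0)
    rejections = 0
    for i in range(n_replicates):
        cfg = base.with_(seed=seed * 1_000_003 + i)
        res = lean_group_run(cfg, mode="null")
        rejections += res.p_correspondence < alpha
    return rejections / n_replicates


def ceiling_bounds_study(n_groups: int = 1000, n_subjects: int = 6,
                         n_pairs: int = 28, noise_sd: float = 1.0,
                         seed: int = 0, method: str = "spearman"):
    """Vector-level Monte-Carlo of the ceiling bounds: shared signal plus
    independent subject noise.  Returns (lower, upper) arrays."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    lows = np.empty(n_groups)
    ups = np.empty(n_groups)
    for g in range(n_groups):
        signal = rng.normal(size=n_pairs)
        subjects = signal + noise_sd * rng.normal(size=(n_subjects, n_pairs))
        lows[g] = lower_bound(subjects, method)
        ups[g] = upper_bound(subjects, method)
    return lows, ups
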