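"""Synthetic multi-subject data with planted representational structure.

The generator plants (a) a smoothly drifting chain of latent category
geometries across hierarchy levels, (b) a region-to-layer correspondence
(each brain region reads out the geometry of one hierarchy level, model
layers realize the levels), (c) subject-level geometry perturbations and
run-level i.i.d. Gaussian noise, and (d) optional category-selective
voxels and pure-noise voxels — so that every pipeline stage (voxel
selection, RDM construction, noise ceilings, the hierarchy test, the
variance-captured test) is verifiable by parameter recovery.

Random streams are split hierarchically (truth / subject / model layers)
so adding subjects never perturbs existing subjects' data, and the whole
dataset is bit-reproducible from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .geometry import ResponseMatrix, build_rdm, vectorize_rdm
from .voxels import RunBetaSeries, SelectivitySpec

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "BrainDataset",
    "default_planted_mapping",
    "generate_ground_truth",
    "generate_brain_data",
    "generate_model_layers",
    "selectivity_spec",
]

DEFAULT_REGION_NAMES = ("V1", "V2", "V3", "V4", "LOT", "VOT")

# sub-stream domains under the top-level seed
_TRUTH, _BRAIN, _LAYERS, _REGION = 0, 1, 2, 3


def default_planted_mapping(n_regions: int, n_layers: int) -> tuple[int, ...]:
    """Evenly spaced, weakly increasing region-to-layer mapping (1-based).

    For 6 regions over 11 layers this is ``(1, 3, 5, 7, 9, 11)``.
    """
    return tuple(int(x) for x in np.round(np.linspace(1, n_layers, n_regions)))


@dataclass
class SimulationConfig:
    n_subjects: int = 6
    n_regions: int = 6
    n_categories: int = 8
    n_exemplars_per_category: int = 10
    n_runs: int = 16
    n_voxels_per_region: int = 150
    n_model_layers: int = 11
    planted_mapping: tuple[int, ...] | None = None
    subject_loading_sd: float = 0.25
    run_noise_sd: float = 1.0
    selective_voxel_fraction: float = 0.0
    selective_offset: float = 0.0
    #: voxels per region carrying signal; the rest are pure noise (None = all)
    n_signal_voxels_per_region: int | None = None
    n_latent_features: int = 30
    #: AR(1) mixing weight between consecutive hierarchy levels
    level_mixing: float = 0.8
    exemplar_sd: float = 0.5
    #: region index (0-based) whose geometry the "matched" layer copies
    matched_region: int = -1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_regions", "n_categories", "n_runs",
                     "n_voxels_per_region", "n_model_layers",
                     "n_exemplars_per_category", "n_latent_features"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_categories < 3:
            raise ValueError("need at least 3 categories")
        if self.planted_mapping is None:
            self.planted_mapping = default_planted_mapping(
                self.n_regions, self.n_model_layers)
        self.planted_mapping = tuple(int(m) for m in self.planted_mapping)
        if len(self.planted_mapping) != self.n_regions:
            raise ValueError("planted_mapping must have one layer per region")
        if any(not 1 <= m <= self.n_model_layers for m in self.planted_mapping):
            raise ValueError("planted_mapping entries must be 1-based layer indices")
        if not 0.0 <= self.level_mixing <= 1.0:
            raise ValueError("level_mixing must lie in [0, 1]")
        if self.n_signal_voxels_per_region is not None and (
                self.n_signal_voxels_per_region > self.n_voxels_per_region):
            raise ValueError("n_signal_voxels_per_region exceeds voxel count")

    @property
    def condition_labels(self) -> list[str]:
        return [f"cat{i + 1:02d}" for i in range(self.n_categories)]

    @property
    def region_names(self) -> list[str]:
        if self.n_regions == len(DEFAULT_REGION_NAMES):
            return list(DEFAULT_REGION_NAMES)
        return [f"region{i + 1}" for i in range(self.n_regions)]

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    config: SimulationConfig
    level_features: np.ndarray           # L x K x F exemplar-averaged geometries
    region_layer_mapping: np.ndarray     # 1-based best layer per region
    region_rdvs: np.ndarray              # n_regions x K(K-1)/2 true dissimilarities
    layer_rdvs: np.ndarray               # L x K(K-1)/2
    condition_labels: list[str]
    region_names: list[str]
    signal_voxels: list[np.ndarray]      # per region, indices carrying signal
    selective_voxels: list[dict[str, np.ndarray]]  # per region, group -> indices


@dataclass
class BrainDataset:
    truth: GroundTruth
    data: list[list[RunBetaSeries]]      # [subject][region]
    region_names: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.data)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def generate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Latent hierarchy-level geometries plus planted voxel sets.

    Level category means follow an AR(1) chain in feature space (each
    level a ``level_mixing`` blend of its predecessor plus fresh
    structure), so nearby levels have more similar RDMs than distant
    ones.  Category features are exemplar means, exercising the
    exemplar-averaging path.
    """
    cfg = config
    rng = _rng(cfg.seed, _TRUTH)
    L, K, F = cfg.n_model_layers, cfg.n_categories, cfg.n_latent_features
    w = cfg.level_mixing
    means = np.empty((L, K, F))
    means[0] = rng.normal(size=(K, F))
    for level in range(1, L):
        fresh = rng.normal(size=(K, F))
        means[level] = w * means[level - 1] + np.sqrt(1.0 - w * w) * fresh
    exemplars = means[:, :, None, :] + cfg.exemplar_sd * rng.normal(
        size=(L, K, cfg.n_exemplars_per_category, F))
    features = exemplars.mean(axis=2)

    labels = cfg.condition_labels
    layer_rdvs = np.stack([
        vectorize_rdm(build_rdm(ResponseMatrix(features[level], labels)))
        for level in range(L)
    ])
    mapping = np.asarray(cfg.planted_mapping, dtype=int)
    region_rdvs = layer_rdvs[mapping - 1]

    n_signal = cfg.n_signal_voxels_per_region
    v = cfg.n_voxels_per_region
    signal_voxels = []
    for _ in range(cfg.n_regions):
        if n_signal is None or n_signal >= v:
            signal_voxels.append(np.arange(v))
        else:
            signal_voxels.append(np.sort(rng.choice(v, size=n_signal, replace=False)))

    groups = _selectivity_groups(labels)
    selective_voxels: list[dict[str, np.ndarray]] = []
    n_sel = int(round(cfg.selective_voxel_fraction * v))
    for r in range(cfg.n_regions):
        chosen: dict[str, np.ndarray] = {}
        if n_sel > 0 and r in _selective_regions(cfg):
            pool = rng.permutation(signal_voxels[r])
            for i, group in enumerate(groups):
                chosen[group] = np.sort(pool[i * n_sel:(i + 1) * n_sel])
        selective_voxels.append(chosen)

    return GroundTruth(
        config=cfg,
        level_features=features,
        region_layer_mapping=mapping,
        region_rdvs=region_rdvs,
        layer_rdvs=layer_rdvs,
        condition_labels=labels,
        region_names=cfg.region_names,
        signal_voxels=signal_voxels,
        selective_voxels=selective_voxels,
    )


def _selective_regions(cfg: SimulationConfig) -> set[int]:
    """Higher-level object-selective analogs: the last two regions."""
    return {cfg.n_regions - 2, cfg.n_regions - 1} if cfg.n_regions >= 2 else {0}


def _selectivity_groups(labels: list[str]) -> dict[str, frozenset[str]]:
    """Default planted category groups over the synthetic labels."""
    if len(labels) < 6:
        return {"face": frozenset({labels[0]})}
    return {
        "face": frozenset({labels[0]}),
        "body": frozenset(labels[1:4]),
        "scene": frozenset({labels[4]}),
    }


def selectivity_spec(config: SimulationConfig, alpha: float = 0.05) -> SelectivitySpec:
    """The SelectivitySpec matching the generator's planted groups."""
    return SelectivitySpec(
        target_sets=_selectivity_groups(config.condition_labels), alpha=alpha)


def generate_brain_data(truth: GroundTruth,
                        config: SimulationConfig | None = None) -> BrainDataset:
    """Per-subject, per-region run-level beta series.

    Each signal voxel is a linear readout of its region's level geometry.
    Readout weights are shared across subjects per region, with a
    subject-specific perturbation of sd ``subject_loading_sd`` — so at
    ``subject_loading_sd = run_noise_sd = 0`` every subject's region RDM
    is identical.  Run betas add i.i.d. Gaussian noise; planted selective
    voxels get a constant offset on their group's conditions; non-signal
    voxels are pure noise.
    """
    cfg = config or truth.config
    K, F = cfg.n_categories, cfg.n_latent_features
    V, R = cfg.n_voxels_per_region, cfg.n_runs
    groups = _selectivity_groups(truth.condition_labels)
    cond_ix = {c: i for i, c in enumerate(truth.condition_labels)}

    base_readout = [
        _rng(cfg.seed, _REGION, r).normal(size=(F, V)) for r in range(cfg.n_regions)
    ]
    data: list[list[RunBetaSeries]] = []
    for s in range(cfg.n_subjects):
        subject_rows: list[RunBetaSeries] = []
        for r in range(cfg.n_regions):
            rng = _rng(cfg.seed, _BRAIN, s, r)
            g = truth.level_features[truth.region_layer_mapping[r] - 1]
            readout = base_readout[r] + cfg.subject_loading_sd * rng.normal(size=(F, V))
            means = g @ (readout / np.sqrt(F))
            mask = np.zeros(V, dtype=bool)
            mask[truth.signal_voxels[r]] = True
            means[:, ~mask] = 0.0
            for group, idxs in truth.selective_voxels[r].items():
                rows = [cond_ix[c] for c in groups[group]]
                means[np.ix_(rows, idxs)] += cfg.selective_offset
            noise = rng.normal(scale=cfg.run_noise_sd, size=(R, K, V)) \
                if cfg.run_noise_sd > 0 else np.zeros((R, K, V))
            subject_rows.append(RunBetaSeries(
                betas=means[None, :, :] + noise,
                condition_labels=list(truth.condition_labels),
                roi_name=truth.region_names[r],
            ))
        data.append(subject_rows)
    return BrainDataset(truth=truth, data=data, region_names=truth.region_names)


def generate_model_layers(
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    mode: Literal["planted", "matched", "null"] = "planted",
) -> list[ResponseMatrix]:
    """Model-layer activation matrices (categories x features).

    ``planted`` — layer ``l`` realizes hierarchy level ``l``, so the
    planted region-to-layer mapping is recoverable.  ``matched`` — all
    layers are random except the one mapped to ``config.matched_region``,
    which reproduces that region's exact noise-free voxel-space response
    pattern (its level geometry through the shared readout; for the
    variance-captured = 1 recovery test).  ``null`` — all layer
    geometries are independent of the truth (for type-I error tests).
    """
    cfg = config or truth.config
    K, F, L = cfg.n_categories, cfg.n_latent_features, cfg.n_model_layers
    labels = list(truth.condition_labels)
    if mode == "planted":
        return [ResponseMatrix(truth.level_features[l].copy(), labels)
                for l in range(L)]
    rng = _rng(cfg.seed, _LAYERS)
    layers = [ResponseMatrix(rng.normal(size=(K, F)), labels) for _ in range(L)]
    if mode == "null":
        return layers
    if mode == "matched":
        region = cfg.matched_region % cfg.n_regions
        layer_ix = int(truth.region_layer_mapping[region]) - 1
        g = truth.level_features[layer_ix]
        base_readout = _rng(cfg.seed, _REGION, region).normal(
            size=(F, cfg.n_voxels_per_region))
        layers[layer_ix] = ResponseMatrix(g @ (base_readout / np.sqrt(F)), labels)
        return layers
    raise ValueError(f"unknown mode {mode!r}")
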