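"""End-to-end orchestration: data -> voxel selection -> RDMs -> noise
ceilings -> hierarchy-correspondence test -> variance-captured test ->
2-D embeddings -> report tables.

All stages are exposed as plain functions over arrays so that replicate
studies can reuse them without touching the filesystem;
:func:`run_pipeline` composes them and writes the report bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import __version__
from .ceiling import estimate_ceiling
from .embedding import classical_mds, procrustes_align
from .errors import UndefinedCorrelationError, VisRsaError
from .geometry import ResponseMatrix, build_rdm, rdm_from_vector, vectorize_rdm
from .inference import (CaptureResult, CorrespondenceResult, bh_fdr,
                        best_layer_per_region, correspondence_statistic,
                        group_test_positive, test_full_capture,
                        variance_captured)
from .simulate import (BrainDataset, SimulationConfig, generate_brain_data,
                       generate_ground_truth, generate_model_layers,
                       selectivity_spec)
from .voxels import (RunBetaSeries, SelectivitySpec, flag_category_selective,
                     select_top_k, split_half_reliability)

__all__ = [
    "AnalysisConfig", "PipelineResult",
    "select_voxels", "subject_region_rdvs", "layer_rdvs",
    "batch_compare_rdvs", "correlation_tables",
    "correspondence_test", "capture_test",
    "run_pipeline", "compare_variants",
]


@dataclass
class AnalysisConfig:
    """One document driving a full run; persisted verbatim to the manifest."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    model_mode: str = "planted"
    metric: str = "euclidean_z"
    comparison: str = "spearman"
    top_k: int = 75
    exclude_selective: bool = False
    selectivity_alpha: float = 0.05
    fisher_average_ceiling: bool = False
    per_subject_max: bool = False
    q: float = 0.05
    condition: str = "main"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**{
                k: (tuple(v) if k == "planted_mapping" and v is not None else v)
                for k, v in self.simulation.items()
            })
        if self.metric not in ("euclidean_z", "correlation_distance"):
            raise ValueError(f"unsupported metric {self.metric!r}")
        if self.comparison not in ("spearman", "pearson"):
            raise ValueError(f"unsupported comparison {self.comparison!r}")
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class PipelineResult:
    config: AnalysisConfig
    brain_rdvs: np.ndarray            # subjects x regions x pairs
    layer_rdv_matrix: np.ndarray      # layers x pairs
    tables: np.ndarray                # subjects x regions x layers correlations
    ceilings: pd.DataFrame
    best_layers: pd.DataFrame
    correspondence: CorrespondenceResult
    subject_z: np.ndarray
    capture: CaptureResult
    proportions: np.ndarray           # regions x layers x subjects
    mds_regions: pd.DataFrame
    mds_layers: pd.DataFrame
    selection_log: pd.DataFrame
    region_names: list[str]


# ---------------------------------------------------------------------------
# stages

def select_voxels(series: RunBetaSeries, top_k: int,
                  spec: SelectivitySpec | None = None,
                  exclude: bool = False):
    """Reliability-rank voxels, optionally excluding selective ones first.

    Returns ``(kept_indices, reliabilities, flagged_mask)``.
    """
    rel = split_half_reliability(series)
    flagged = np.zeros(series.n_voxels, dtype=bool)
    if exclude:
        if spec is None:
            raise VisRsaError("exclusion requested without a SelectivitySpec")
        flagged = flag_category_selective(series, spec)
    eligible = np.flatnonzero(~flagged)
    if eligible.size < top_k:
        raise VisRsaError(
            f"ROI {series.roi_name!r}: only {eligible.size} voxels remain "
            f"after exclusion; cannot select top {top_k}")
    kept = eligible[select_top_k(rel[eligible], top_k)]
    return kept, rel, flagged


def subject_region_rdvs(dataset: BrainDataset, metric: str = "euclidean_z",
                        top_k: int = 75, exclude_selective: bool = False,
                        spec: SelectivitySpec | None = None,
                        selective_regions: set[int] | None = None):
    """Voxel-select, run-average, z-score, and vectorize every subject/region.

    Exclusion is applied only in ``selective_regions`` (default: the last
    two, the higher-level object-selective analogs), mirroring the use of
    selectivity exclusion for LOT/VOT only.
    """
    n_subj = dataset.n_subjects
    n_regions = len(dataset.data[0])
    if selective_regions is None:
        selective_regions = {n_regions - 2, n_regions - 1}
    rdvs = None
    rows = []
    for s in range(n_subj):
        for r, series in enumerate(dataset.data[s]):
            exclude = exclude_selective and r in selective_regions
            kept, rel, flagged = select_voxels(series, top_k, spec, exclude)
            mean = series.betas.mean(axis=0)[:, kept]
            rm = ResponseMatrix(values=mean,
                                condition_labels=list(series.condition_labels))
            vec = vectorize_rdm(build_rdm(rm, metric=metric))
            if rdvs is None:
                rdvs = np.empty((n_subj, n_regions, vec.size))
            rdvs[s, r] = vec
            rows.append({
                "subject": s + 1, "region": series.roi_name or f"region{r + 1}",
                "n_voxels": series.n_voxels, "n_kept": kept.size,
                "n_flagged": int(flagged.sum()),
                "median_reliability": float(np.median(rel[np.isfinite(rel)])),
            })
    return rdvs, pd.DataFrame(rows)


def layer_rdvs(layers: list[ResponseMatrix], metric: str = "euclidean_z") -> np.ndarray:
    return np.stack([vectorize_rdm(build_rdm(m, metric=metric)) for m in layers])


def batch_compare_rdvs(a: np.ndarray, b: np.ndarray,
                       method: str = "spearman") -> np.ndarray:
    """Correlation matrix between row vectors of ``a`` (n x P) and ``b`` (m x P).

    Vectorized equivalent of :func:`visrsa.geometry.compare_rdms` applied
    to every pair; mid-ranks are used for Spearman.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method == "spearman":
        a = rankdata(a, axis=1)
        b = rankdata(b, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt(np.sum(az * az, axis=1))
    sb = np.sqrt(np.sum(bz * bz, axis=1))
    if np.any(sa == 0) or np.any(sb == 0):
        raise UndefinedCorrelationError("zero-variance dissimilarity vector")
    return np.clip((az @ bz.T) / np.outer(sa, sb), -1.0, 1.0)


def correlation_tables(brain: np.ndarray, layers: np.ndarray,
                       method: str = "spearman") -> np.ndarray:
    """Subjects x regions x layers correlation tables."""
    n_subj, n_regions, _ = brain.shape
    out = np.empty((n_subj, n_regions, layers.shape[0]))
    for s in range(n_subj):
        out[s] = batch_compare_rdvs(brain[s], layers, method)
    return out


def correspondence_test(tables: np.ndarray, region_names=None,
                        n_fdr_family: int = 1):
    """Per-subject hierarchy statistic and its group test.

    Returns ``(subject_z, best_layer_matrix, CorrespondenceResult)``.
    ``n_fdr_family`` is the number of tests in the BH family this test
    belongs to (image conditions within an experiment); with a family of
    one the adjusted p equals the raw p.
    """
    n_subj = tables.shape[0]
    zs = np.empty(n_subj)
    best = np.empty((n_subj, tables.shape[1]), dtype=int)
    for s in range(n_subj):
        assignment = best_layer_per_region(tables[s], region_names)
        best[s] = assignment.best_layer
        zs[s] = correspondence_statistic(assignment)
    t, df, p = group_test_positive(zs)
    p_fdr = float(min(1.0, p * n_fdr_family))  # BH with a single rank-1 entry
    result = CorrespondenceResult(
        mean_fisher_z=float(zs.mean()), t_stat=t, df=df,
        p_one_tailed=p, p_fdr=p_fdr, n_subjects=n_subj)
    return zs, best, result


def capture_test(tables: np.ndarray, lower_ceilings: np.ndarray,
                 region_names=None, q: float = 0.05,
                 per_subject_max: bool = False):
    """Variance-captured proportions and the vs-1 test per region."""
    n_subj, n_regions, n_layers = tables.shape
    proportions = np.empty((n_regions, n_layers, n_subj))
    for r in range(n_regions):
        for l in range(n_layers):
            for s in range(n_subj):
                proportions[r, l, s] = variance_captured(
                    tables[s, r, l], lower_ceilings[r])
    result = test_full_capture(proportions, region_names, q=q,
                               per_subject_max=per_subject_max)
    return proportions, result


# ---------------------------------------------------------------------------
# orchestration

def run_pipeline(config: AnalysisConfig,
                 dataset: BrainDataset | None = None,
                 layers: list[ResponseMatrix] | None = None) -> PipelineResult:
    """Execute every stage; write the report bundle if an output dir is set.

    ``dataset``/``layers`` override the simulation (real-data mode: load
    them with :mod:`visrsa.io` and pass them in).
    """
    sim = config.simulation
    stage = "simulate"
    try:
        if dataset is None or layers is None:
            truth = generate_ground_truth(sim)
            dataset = dataset or generate_brain_data(truth)
            layers = layers or generate_model_layers(truth, mode=config.model_mode)
        region_names = dataset.region_names or [
            f"region{i + 1}" for i in range(len(dataset.data[0]))]

        stage = "voxel_selection/rdm"
        spec = selectivity_spec(sim, alpha=config.selectivity_alpha) \
            if config.exclude_selective else None
        brain, selection_log = subject_region_rdvs(
            dataset, metric=config.metric, top_k=config.top_k,
            exclude_selective=config.exclude_selective, spec=spec)

        stage = "noise_ceiling"
        ceilings = []
        for r, name in enumerate(region_names):
            est = estimate_ceiling(brain[:, r, :], method=config.comparison,
                                   roi_name=name,
                                   fisher_average=config.fisher_average_ceiling)
            ceilings.append({"region": name, "lower": est.lower,
                             "upper": est.upper, "n": est.n_subjects})
        ceilings = pd.DataFrame(ceilings)

        stage = "correlation"
        lmat = layer_rdvs(layers, metric=config.metric)
        tables = correlation_tables(brain, lmat, method=config.comparison)

        stage = "correspondence"
        subject_z, best, corr_result = correspondence_test(tables, region_names)
        best_layers = pd.DataFrame(
            best, columns=region_names,
            index=pd.Index(range(1, best.shape[0] + 1), name="subject"))

        stage = "capture"
        proportions, capture = capture_test(
            tables, ceilings["lower"].to_numpy(), region_names,
            q=config.q, per_subject_max=config.per_subject_max)

        stage = "mds"
        mds_regions, mds_layers = _embeddings(
            brain, lmat, region_names, config.metric)
    except VisRsaError as exc:
        raise VisRsaError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result = PipelineResult(
        config=config, brain_rdvs=brain, layer_rdv_matrix=lmat, tables=tables,
        ceilings=ceilings, best_layers=best_layers,
        correspondence=corr_result, subject_z=subject_z,
        capture=capture, proportions=proportions,
        mds_regions=mds_regions, mds_layers=mds_layers,
        selection_log=selection_log, region_names=region_names)
    if config.output_dir:
        write_report(result, config.output_dir)
    return result


def _embeddings(brain, lmat, region_names, metric):
    reference = None
    region_rows, layer_rows = [], []
    for r, name in enumerate(region_names):
        rdm = rdm_from_vector(brain[:, r, :].mean(axis=0), metric=metric)
        emb = classical_mds(rdm)
        coords = emb.coordinates
        if reference is None:
            reference = coords
            emb.aligned_to = None
        else:
            coords = procrustes_align(coords, reference)
        for label, (x, y) in zip(rdm.condition_labels, coords):
            region_rows.append({"panel": name, "label": label, "x": x, "y": y})
    for l in range(lmat.shape[0]):
        rdm = rdm_from_vector(lmat[l], metric=metric)
        coords = procrustes_align(classical_mds(rdm).coordinates, reference)
        for label, (x, y) in zip(rdm.condition_labels, coords):
            layer_rows.append({"panel": f"layer{l + 1}", "label": label,
                               "x": x, "y": y})
    return pd.DataFrame(region_rows), pd.DataFrame(layer_rows)


def write_report(result: PipelineResult, output_dir) -> dict:
    """Write the TSV/JSON report bundle and its manifest."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config

    result.ceilings.to_csv(out / "ceilings.tsv", sep="\t", index=False)
    result.best_layers.to_csv(out / "best_layers.tsv", sep="\t")
    result.selection_log.to_csv(out / "selection_log.tsv", sep="\t", index=False)

    c = result.correspondence
    pd.DataFrame([{
        "condition": cfg.condition, "mean_fisher_z": c.mean_fisher_z,
        "t": c.t_stat, "df": c.df, "p_one_tailed": c.p_one_tailed,
        "p_fdr": c.p_fdr, "n_subjects": c.n_subjects,
    }]).to_csv(out / "correspondence.tsv", sep="\t", index=False)

    cap = result.capture
    prop_rows = []
    for r, name in enumerate(cap.region_names):
        for l in range(result.proportions.shape[1]):
            prop_rows.append({
                "condition": cfg.condition, "region": name, "layer": l + 1,
                "mean_proportion": cap.mean_proportion[r, l]})
    pd.DataFrame(prop_rows).to_csv(out / "capture_proportions.tsv",
                                   sep="\t", index=False)
    pd.DataFrame({
        "region": cap.region_names,
        "best_layer": cap.best_layer_for_test,
        "mean_proportion": cap.best_mean_proportion,
        "t_vs_1": cap.t_vs_1,
        "p_one_tailed": cap.p_one_tailed,
        "p_fdr": cap.p_fdr,
    }).to_csv(out / "capture_tests.tsv", sep="\t", index=False)

    result.mds_regions.to_csv(out / "mds_regions.tsv", sep="\t", index=False)
    result.mds_layers.to_csv(out / "mds_layers.tsv", sep="\t", index=False)

    sub_rows = []
    for s in range(result.tables.shape[0]):
        for r, name in enumerate(result.region_names):
            for l in range(result.tables.shape[2]):
                sub_rows.append({"subject": s + 1, "region": name,
                                 "layer": l + 1, "r": result.tables[s, r, l]})
    pd.DataFrame(sub_rows).to_csv(out / "correlations.tsv", sep="\t", index=False)

    files = sorted(p.name for p in out.glob("*.tsv"))
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.simulation.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "outputs": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def compare_variants(config: AnalysisConfig,
                     variants=(("euclidean_z", "spearman"),
                               ("correlation_distance", "pearson"))) -> pd.DataFrame:
    """Run the pipeline under several metric/comparison variants on the
    same simulated data and summarize their agreement.

    Agreement columns: Spearman rank agreement of mean-best-layer
    profiles, exact per-subject best-layer match rate, and sign agreement
    of significance calls (correspondence plus per-region capture tests).
    """
    results = {}
    for metric, comparison in variants:
        cfg = dataclasses.replace(config, metric=metric, comparison=comparison,
                                  output_dir=None)
        results[(metric, comparison)] = run_pipeline(cfg)
    keys = list(results)
    rows = []
    for i, a in enumerate(keys):
        for b in keys[i:]:
            ra, rb = results[a], results[b]
            mean_a = ra.best_layers.to_numpy().mean(axis=0)
            mean_b = rb.best_layers.to_numpy().mean(axis=0)
            if np.std(mean_a) == 0 or np.std(mean_b) == 0:
                rank_agreement = float(np.allclose(mean_a, mean_b))
            else:
                rank_agreement = float(np.corrcoef(
                    rankdata(mean_a), rankdata(mean_b))[0, 1])
            match = float(np.mean(ra.best_layers.to_numpy()
                                  == rb.best_layers.to_numpy()))
            calls_a = _significance_calls(ra, config.q)
            calls_b = _significance_calls(rb, config.q)
            sig_agreement = float(np.mean(calls_a == calls_b))
            rows.append({
                "variant_a": "/".join(a), "variant_b": "/".join(b),
                "best_layer_rank_agreement": rank_agreement,
                "best_layer_match_rate": match,
                "significance_agreement": sig_agreement,
            })
    return pd.DataFrame(rows)


def _significance_calls(result: PipelineResult, q: float) -> np.ndarray:
    return np.concatenate([
        [result.correspondence.p_fdr < q],
        result.capture.p_fdr < q,
    ])
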