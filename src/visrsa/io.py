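"""Plain-text readers and writers for the pipeline's data structures.

ResponseMatrix: TSV with a header row of unit IDs and a first column of
condition labels.  RDM: square TSV with matching label row/column.
Dissimilarity vector: two-column TSV with pair labels ``condA|condB``.
RunBetaSeries: long TSV with columns (run, condition, voxel, beta).
Selection masks: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import RDM, ResponseMatrix, pair_labels
from .voxels import RunBetaSeries

__all__ = [
    "write_response_matrix", "read_response_matrix",
    "write_rdm", "read_rdm",
    "write_dissimilarity_vector", "read_dissimilarity_vector",
    "write_beta_series", "read_beta_series",
    "write_selection_mask", "read_selection_mask",
]


def write_response_matrix(path, matrix: ResponseMatrix) -> None:
    df = pd.DataFrame(
        matrix.values,
        index=pd.Index(matrix.condition_labels, name="condition"),
        columns=[f"u{i + 1}" for i in range(matrix.unit_count)],
    )
    df.to_csv(path, sep="\t")


def read_response_matrix(path) -> ResponseMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ResponseMatrix(values=df.to_numpy(dtype=float),
                          condition_labels=[str(c) for c in df.index])


def write_rdm(path, rdm: RDM) -> None:
    df = pd.DataFrame(rdm.values, index=rdm.condition_labels,
                      columns=rdm.condition_labels)
    df.index.name = rdm.metric
    df.to_csv(path, sep="\t")


def read_rdm(path, metric: str | None = None) -> RDM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    metric = metric or str(df.index.name or "euclidean_z")
    return RDM(values=df.to_numpy(dtype=float), metric=metric,
               condition_labels=[str(c) for c in df.index])


def write_dissimilarity_vector(path, vector: np.ndarray, condition_labels) -> None:
    df = pd.DataFrame({"pair": pair_labels(condition_labels),
                       "dissimilarity": np.asarray(vector, dtype=float)})
    df.to_csv(path, sep="\t", index=False)


def read_dissimilarity_vector(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["dissimilarity"].to_numpy(dtype=float)


def write_beta_series(path, series: RunBetaSeries) -> None:
    r, k, v = series.betas.shape
    runs = np.repeat(series.run_ids, k * v)
    conds = np.tile(np.repeat(series.condition_labels, v), r)
    voxels = np.tile(np.arange(v), r * k)
    pd.DataFrame({
        "run": runs, "condition": conds, "voxel": voxels,
        "beta": series.betas.ravel(),
    }).to_csv(path, sep="\t", index=False)


def read_beta_series(path, roi_name: str = "") -> RunBetaSeries:
    df = pd.read_csv(path, sep="\t")
    run_ids = sorted(df["run"].unique())
    conditions = list(dict.fromkeys(df["condition"]))  # first-appearance order
    voxels = sorted(df["voxel"].unique())
    cube = (
        df.set_index(["run", "condition", "voxel"])["beta"]
        .unstack("voxel")
        .reindex(columns=voxels)
    )
    betas = np.stack([
        cube.loc[r].reindex(conditions).to_numpy(dtype=float) for r in run_ids
    ])
    return RunBetaSeries(betas=betas, run_ids=[int(r) for r in run_ids],
                         condition_labels=[str(c) for c in conditions],
                         roi_name=roi_name)


def write_selection_mask(path, roi: str, kept_indices, flagged: dict) -> None:
    payload = {
        "roi": roi,
        "kept_indices": [int(i) for i in kept_indices],
        "flagged": {g: [int(i) for i in ix] for g, ix in flagged.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_selection_mask(path) -> dict:
    return json.loads(Path(path).read_text())
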