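"""Reference-projection classification of fibroblast activation states.

The labelled cell-line subgroups define a reference PCA space (fitted on
per-cell autoscaled data, so differences in global RNA content are removed)
with one centroid per differentiation state in the first ``n_pcs`` score
dimensions. Patient-derived cells — autoscaled per cell with their own
statistics — are projected into that space with the reference center, scale
and loadings (no refit) and assigned to the nearest centroid. Distance ties
break toward the earlier state on the pseudo-timeline (a conservative
activation call).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diffmodel import StateModel
from .panel import ExpressionMatrix
from .structure import PcaModel, SubgroupAssignment, fit_pca


@dataclass
class ReferenceSpace:
    """Reference PCA + per-state centroids on the pseudo-timeline."""

    pca: PcaModel
    centroids: pd.DataFrame  # states (timeline order) x PCs
    state_order: list  # state labels in timeline order
    n_pcs: int

    def __post_init__(self) -> None:
        if self.centroids.shape[1] != self.n_pcs:
            raise ValueError("centroid dimension must equal n_pcs")
        if list(self.centroids.index) != list(self.state_order):
            raise ValueError("centroids must be ordered along the timeline")


@dataclass
class ClassificationResult:
    """Per-cell state assignment with distances to every state centroid."""

    assignments: pd.DataFrame  # index cell_id: assigned_state, distance cols, PCs
    state_order: list

    def __post_init__(self) -> None:
        d = self.assignments[[f"dist_{s}" for s in self.state_order]].to_numpy()
        if len(d) and (d < 0).any():
            raise ValueError("distances must be non-negative")


def fit_reference(
    matrix: ExpressionMatrix,
    states: SubgroupAssignment,
    state_model: StateModel,
    n_pcs: int = 3,
) -> ReferenceSpace:
    """Fit the reference PCA and per-state centroids.

    ``matrix`` must be per-cell autoscaled and fully observed; every cell must
    carry a state via ``states`` whose labels are state ids of ``state_model``.
    """
    labels = states.labels.reindex(matrix.values.index)
    if labels.isna().any():
        raise ValueError("every reference cell must be labelled with a state")
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"states with fewer than 2 cells: {small.index.tolist()}")
    model, scores = fit_pca(matrix, n_components=n_pcs)
    order_ids = state_model.states  # already in timeline order after order_states
    order_labels = [state_model.labels[s] for s in order_ids]
    rows = []
    for sid in order_ids:
        members = labels.index[labels == sid]
        if len(members) == 0:
            raise ValueError(f"state {sid!r} has no cells in the reference")
        rows.append(scores.loc[members].mean(axis=0).to_numpy())
    centroids = pd.DataFrame(rows, index=order_labels, columns=scores.columns)
    return ReferenceSpace(pca=model, centroids=centroids, state_order=order_labels, n_pcs=n_pcs)


def classify_cells(space: ReferenceSpace, test: ExpressionMatrix) -> ClassificationResult:
    """Project test cells into the reference space; nearest-centroid assignment.

    The test matrix must be per-cell autoscaled on the shared gene panel.
    Projection uses only reference parameters, so permuting or subsetting test
    cells never changes an individual cell's assignment.
    """
    genes = list(space.pca.loadings.index)
    missing = [g for g in genes if g not in test.values.columns]
    if missing:
        raise ValueError(f"test matrix missing reference genes: {missing}")
    scores = space.pca.transform(test.values)
    c = space.centroids.to_numpy()  # states x pcs
    s = scores.to_numpy()  # cells x pcs
    d = np.sqrt(((s[:, None, :] - c[None, :, :]) ** 2).sum(axis=2))
    # ties (within floating tolerance) break to the earliest timeline state
    dmin = d.min(axis=1, keepdims=True)
    best = (d <= dmin + 1e-9 * (1.0 + dmin)).argmax(axis=1)
    out = scores.copy()
    for j, state in enumerate(space.state_order):
        out[f"dist_{state}"] = d[:, j]
    out["assigned_state"] = [space.state_order[i] for i in best]
    if "cell_class" in test.cells.columns:
        out["cell_class"] = test.cells["cell_class"].reindex(out.index)
    return ClassificationResult(assignments=out, state_order=list(space.state_order))


def cohort_report(result: ClassificationResult) -> pd.DataFrame:
    """Per cell-class state frequency table with per-state mean distance."""
    df = result.assignments
    if df.empty:
        raise ValueError("empty classification result")
    classes = df["cell_class"] if "cell_class" in df.columns else pd.Series(
        "all", index=df.index
    )
    rows = []
    for cls, sub in df.groupby(classes):
        n = len(sub)
        for state in result.state_order:
            members = sub[sub["assigned_state"] == state]
            rows.append(
                {
                    "cell_class": cls,
                    "state": state,
                    "n": len(members),
                    "frequency": len(members) / n,
                    "mean_distance": float(members[f"dist_{state}"].mean())
                    if len(members)
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


def save_reference(space: ReferenceSpace, path) -> None:
    """Serialize the reference space (loadings, center, scale, centroids, order)."""
    doc = {
        "n_pcs": space.n_pcs,
        "state_order": list(space.state_order),
        "genes": list(space.pca.loadings.index),
        "components": list(space.pca.loadings.columns),
        "loadings": space.pca.loadings.to_numpy().tolist(),
        "center": space.pca.center.to_numpy().tolist(),
        "scale": space.pca.scale.to_numpy().tolist(),
        "explained_variance_fraction": np.asarray(
            space.pca.explained_variance_fraction
        ).tolist(),
        "centroids": space.centroids.to_numpy().tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_reference(path) -> ReferenceSpace:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    loadings = pd.DataFrame(doc["loadings"], index=doc["genes"], columns=doc["components"])
    pca = PcaModel(
        loadings=loadings,
        explained_variance_fraction=np.asarray(doc["explained_variance_fraction"]),
        center=pd.Series(doc["center"], index=doc["genes"]),
        scale=pd.Series(doc["scale"], index=doc["genes"]),
        n_components=len(doc["components"]),
    )
    centroids = pd.DataFrame(
        doc["centroids"], index=doc["state_order"], columns=doc["components"]
    )
    return ReferenceSpace(
        pca=pca, centroids=centroids, state_order=list(doc["state_order"]), n_pcs=doc["n_pcs"]
    )
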