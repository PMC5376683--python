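"""Correlation structure, hierarchical subgrouping, PCA and SOM confirmation.

Subpopulation discovery works on the cell-to-cell Spearman correlation matrix:
each cell's row of correlations to every other cell is its feature vector, and
agglomerative clustering (Euclidean distance) of those rows cut at k groups
yields the manual subgrouping. A mixed subgroup containing both normal and
activated cells can subsequently be split by cell class. PCA provides the
score/loading views and a self-organizing map provides an independent
confirmation of the subgroups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from .panel import ExpressionMatrix

logger = logging.getLogger("scfib")

LINKAGES = ("average", "complete", "ward")


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman correlation matrix over genes or cells."""

    rho: pd.DataFrame
    axis: str  # "gene" or "cell"

    def __post_init__(self) -> None:
        a = self.rho.to_numpy(dtype=float)
        if a.shape[0] != a.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if len(a) and not np.allclose(np.diag(a), 1.0, atol=1e-12):
            raise ValueError("correlation diagonal must be 1")
        if len(a) and (np.nanmin(a) < -1 - 1e-12 or np.nanmax(a) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def labels(self) -> list:
        return list(self.rho.index)


@dataclass
class PcaModel:
    """Fitted PCA: per-gene center/scale, sign-fixed loadings, variance shares."""

    loadings: pd.DataFrame  # genes x components
    explained_variance_fraction: np.ndarray
    center: pd.Series  # per-gene offsets subtracted before projection
    scale: pd.Series  # per-gene divisors applied before projection
    n_components: int

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        """Project new data with the reference center/scale/loadings (no refit)."""
        missing = [g for g in self.loadings.index if g not in values.columns]
        if missing:
            raise ValueError(f"genes absent from data to project: {missing}")
        x = values[self.loadings.index].to_numpy(dtype=float)
        x = (x - self.center.to_numpy()) / self.scale.to_numpy()
        scores = x @ self.loadings.to_numpy()
        return pd.DataFrame(scores, index=values.index, columns=self.loadings.columns)


@dataclass
class SubgroupAssignment:
    """cell_id -> subgroup label, with the method that produced it."""

    labels: pd.Series  # index cell_id
    method: str  # hier_corr | som | manual_split | truth
    k: int

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n and not 1 <= self.k <= n:
            raise ValueError(f"k={self.k} outside [1, {n}]")

    def members(self, subgroup) -> list:
        return list(self.labels.index[self.labels == subgroup])


def spearman_matrix(matrix: ExpressionMatrix, axis: str = "cell") -> CorrelationMatrix:
    """Pairwise Spearman correlations between cells (rows) or genes (columns).

    Ranks use average tie handling, so imputed non-detects sharing a gene's
    floor value are tied deterministically.
    """
    if axis not in ("cell", "gene"):
        raise ValueError("axis must be 'cell' or 'gene'")
    a = matrix.values.to_numpy(dtype=float)
    if np.isnan(a).any():
        raise ValueError("spearman_matrix requires a fully observed (imputed) matrix")
    data = a if axis == "cell" else a.T
    labels = matrix.cell_ids if axis == "cell" else matrix.genes
    if data.shape[1] < 3:
        raise ValueError("need at least 3 observations per vector for Spearman")
    ranks = np.apply_along_axis(rankdata, 1, data)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    norms[norms == 0] = 1.0  # constant vectors: correlation defined as 0
    unit = ranks / norms[:, None]
    rho = unit @ unit.T
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2.0
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=labels, columns=labels), axis=axis
    )


def hier_cluster(
    corr: CorrelationMatrix,
    k: int,
    linkage_method: str = "average",
    min_cluster_size: int = 4,
) -> SubgroupAssignment:
    """Agglomerate the rows of the correlation matrix into exactly k subgroups.

    Rows of the correlation matrix are the feature vectors (a cell is described
    by its correlation profile to every cell), distances are Euclidean, and the
    tree is cut with ``maxclust``. Deterministic given its input.

    ``min_cluster_size`` emulates manual subgrouping from a dendrogram: a cut
    that isolates tiny outlier twigs (fewer cells than the minimum) is deepened
    until k substantive groups exist, and twig cells are folded into the
    nearest substantive group by mean feature distance. Set it to 1 for the
    plain cut (always used when k equals the number of items).
    """
    n = len(corr.rho)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of items ({n})")
    if linkage_method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    x = corr.rho.to_numpy(dtype=float)
    if k == n:
        flat = np.arange(1, n + 1)
    else:
        z = linkage(x, method=linkage_method, metric="euclidean")
        flat = fcluster(z, t=k, criterion="maxclust")
        if min_cluster_size > 1:
            flat = _absorb_twigs(x, z, k, min_cluster_size, flat)
    labels = pd.Series(flat, index=corr.rho.index, name="subgroup")
    return SubgroupAssignment(labels=labels, method="hier_corr", k=int(labels.nunique()))


def _absorb_twigs(
    x: np.ndarray, z: np.ndarray, k: int, min_size: int, flat: np.ndarray
) -> np.ndarray:
    """Deepen the cut until >= k clusters reach min_size; fold twigs into the
    nearest substantive cluster (closest mean feature vector)."""
    n = len(x)
    best = flat
    for kk in range(k, min(n, k + 10) + 1):
        cand = fcluster(z, t=kk, criterion="maxclust") if kk > k else flat
        ids, sizes = np.unique(cand, return_counts=True)
        large = ids[sizes >= min_size]
        if len(large) >= k:
            best = cand
            break
    else:
        return flat  # no cut yields k substantive groups; keep the plain cut
    ids, sizes = np.unique(best, return_counts=True)
    large = list(ids[sizes >= min_size])
    centroids = {c: x[best == c].mean(axis=0) for c in large}
    # merge closest substantive clusters until exactly k remain
    while len(large) > k:
        pairs = [
            (np.linalg.norm(centroids[a] - centroids[b]), a, b)
            for i, a in enumerate(large)
            for b in large[i + 1:]
        ]
        _, a, b = min(pairs)
        best[best == b] = a
        large.remove(b)
        centroids[a] = x[best == a].mean(axis=0)
        del centroids[b]
    for c in ids:
        if c not in large and np.any(best == c):
            members = np.where(best == c)[0]
            for i in members:
                nearest = min(large, key=lambda g: np.linalg.norm(x[i] - centroids[g]))
                best[i] = nearest
    return best


def split_mixed_cluster(
    assign: SubgroupAssignment, cells: pd.DataFrame, subgroup
) -> SubgroupAssignment:
    """Split one subgroup by cell_class (the manual division of a mixed cluster).

    Other labels are untouched; k grows by (classes present in the subgroup - 1).
    New labels are "<subgroup>/<cell_class>".
    """
    members = assign.members(subgroup)
    if not members:
        raise ValueError(f"subgroup {subgroup!r} absent or empty")
    classes = cells.loc[members, "cell_class"]
    labels = assign.labels.astype(object).copy()
    if classes.nunique() > 1:
        for cid in members:
            labels.loc[cid] = f"{subgroup}/{classes.loc[cid]}"
    return SubgroupAssignment(
        labels=labels, method="manual_split", k=int(labels.nunique())
    )


def fit_pca(
    matrix: ExpressionMatrix, n_components: int = 2
) -> tuple[PcaModel, pd.DataFrame]:
    """Fit PCA on a fully observed matrix; returns the model and cell scores.

    The caller chooses the scaling convention beforehand (autoscale per gene
    for the score/loading views; autoscale per cell for the global-normalized
    view). Loadings are sign-fixed so each component's largest-magnitude
    loading is positive, making score plots reproducible.
    """
    a = matrix.values.to_numpy(dtype=float)
    if np.isnan(a).any():
        raise ValueError("fit_pca requires a fully observed (imputed) matrix")
    if n_components > min(a.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_cells, n_genes)={min(a.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(a)
    loadings = pca.components_.T.copy()  # genes x components
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    model = PcaModel(
        loadings=pd.DataFrame(loadings, index=matrix.genes, columns=comp_names),
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        center=pd.Series(pca.mean_, index=matrix.genes),
        scale=pd.Series(1.0, index=matrix.genes),
        n_components=n_components,
    )
    score_df = pd.DataFrame(scores, index=matrix.cell_ids, columns=comp_names)
    return model, score_df


# ---------------------------------------------------------------------------
# self-organizing map
# ---------------------------------------------------------------------------

class SelfOrganizingMap:
    """Minimal Kohonen map: online training, Gaussian neighbourhood,
    linearly decaying learning rate and radius, deterministic for a fixed seed.

    Nearest-unit ties break toward the lowest unit index.
    """

    def __init__(self, rows: int, cols: int, n_features: int, seed: int = 0):
        self.rows, self.cols = rows, cols
        rng = np.random.default_rng(seed)
        self.weights = rng.normal(0.0, 0.1, size=(rows * cols, n_features))
        grid = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
        self._grid_d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(axis=2)
        self._rng = rng

    def train(self, data: np.ndarray, n_iter: int = 1000, lr0: float = 0.5,
              sigma0: float | None = None) -> None:
        n_units = self.rows * self.cols
        sigma0 = sigma0 if sigma0 is not None else max(self.rows, self.cols) / 2.0
        order = self._rng.integers(0, len(data), size=n_iter)
        for t, idx in enumerate(order):
            frac = t / n_iter
            lr = lr0 * (1.0 - frac)
            sigma = max(sigma0 * (1.0 - frac), 0.3)
            x = data[idx]
            bmu = self._bmu(x)
            h = np.exp(-self._grid_d2[bmu] / (2.0 * sigma**2))
            self.weights += lr * h[:, None] * (x - self.weights)

    def _bmu(self, x: np.ndarray) -> int:
        d2 = ((self.weights - x) ** 2).sum(axis=1)
        return int(np.argmin(d2))  # argmin takes the lowest index on ties

    def assign(self, data: np.ndarray) -> np.ndarray:
        d2 = ((data[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def fit_som(
    matrix: ExpressionMatrix,
    grid: tuple[int, int] = (3, 2),
    seed: int = 0,
    n_iter: int = 5000,
) -> SubgroupAssignment:
    """Assign cells to best-matching SOM units after a fixed training schedule.

    The default 3x2 grid matches the six differentiation states. Units may end
    up empty when the grid has more units than natural clusters (or cells); a
    warning is logged in the latter case.
    """
    a = matrix.values.to_numpy(dtype=float)
    if np.isnan(a).any():
        raise ValueError("fit_som requires a fully observed (imputed) matrix")
    rows, cols = grid
    if rows * cols > len(a):
        logger.warning("SOM grid has more units (%d) than cells (%d); empty units allowed",
                       rows * cols, len(a))
    som = SelfOrganizingMap(rows, cols, a.shape[1], seed=seed)
    som.train(a, n_iter=n_iter)
    units = som.assign(a)
    labels = pd.Series(units, index=matrix.cell_ids, name="som_unit")
    return SubgroupAssignment(labels=labels, method="som", k=int(labels.nunique()))
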