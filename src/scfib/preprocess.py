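"""Cq -> relative quantity conversion, QC gating and scaling conventions.

No normalization to a reference gene is performed: expression is reported per
cell as relative quantities RQ = 2^(cutoff - Cq), so the detection limit (Cq at
the cutoff) maps to RQ = 1 and every 1-cycle drop in Cq doubles RQ. GAPDH is
used only as a sort-efficiency / cell-quality gate, never as a normalizer.

Scaling conventions, each producing a new matrix with provenance recorded:

* ``to_log2``           log2 RQ, optionally imputing non-detects below the
                        per-gene detected floor (multivariate steps need a
                        fully observed matrix)
* ``autoscale_by_gene`` per-gene z-score (PCA convention)
* ``autoscale_by_cell`` per-cell z-score, a global normalization that removes
  per-cell differences in absolute RNA content
* ``mean_center_by_gene``  per-gene centering (heatmap convention)
* ``combine_mean_centered``  mean-center datasets independently, then stack —
  the cross-dataset combination used to co-embed cell-line and patient data
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import CqPlate, ExpressionMatrix, PanelError

logger = logging.getLogger("scfib")


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    cq_cutoff: off-scale Cq limit in cycles; Cq above it is treated as a
        non-detect and RQ is expressed relative to it. 28 cycles is a
        conventional post-preamplification bound for single-cell qPCR.
    min_gapdh_positivity: sort-efficiency bar — the fraction of cells that
        must be GAPDH-positive for a plate to pass QC (0.80).
    imputation_offset: log2 units below the per-gene minimum detected value
        at which non-detects are imputed for multivariate analyses.
    """

    cq_cutoff: float = 28.0
    min_gapdh_positivity: float = 0.80
    imputation_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.cq_cutoff <= 0:
            raise ValueError("cq_cutoff must be > 0")
        if not 0 < self.min_gapdh_positivity <= 1:
            raise ValueError("min_gapdh_positivity must be in (0, 1]")
        if self.imputation_offset < 0:
            raise ValueError("imputation_offset must be >= 0")


def cq_to_rq(plate: CqPlate, config: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Convert a Cq plate to linear relative quantities.

    Detected entries become RQ = 2^(cutoff - Cq); entries with Cq above the
    cutoff are off scale and flagged non-detect (RQ exactly 0), as are plate
    non-detects.
    """
    config = config or PreprocessConfig()
    cq = plate.cq.to_numpy(dtype=float)
    if np.any(cq[~np.isnan(cq)] <= 0):
        raise ValueError("Cq values must be positive")
    detected = ~np.isnan(cq) & (cq <= config.cq_cutoff)
    rq = np.zeros_like(cq)
    rq[detected] = 2.0 ** (config.cq_cutoff - cq[detected])
    values = pd.DataFrame(rq, index=plate.cq.index, columns=plate.cq.columns)
    mask = pd.DataFrame(detected, index=plate.cq.index, columns=plate.cq.columns)
    return ExpressionMatrix(
        values=values,
        detected=mask,
        cells=plate.cells.copy(),
        scale="linear_rq",
        provenance=[f"cq_to_rq(cutoff={config.cq_cutoff})"],
        panel=plate.panel,
    )


def qc_gapdh_gate(
    matrix: ExpressionMatrix, config: PreprocessConfig | None = None
) -> tuple[ExpressionMatrix, dict]:
    """Keep GAPDH-positive cells only; report per-sample positivity vs the bar.

    Returns the gated matrix and a QC report dict with overall and per-sample
    positivity fractions and a pass flag against ``min_gapdh_positivity``.
    """
    config = config or PreprocessConfig()
    if "GAPDH" not in matrix.values.columns:
        raise PanelError("GAPDH column absent; cannot apply QC gate")
    positive = matrix.detected["GAPDH"].to_numpy(dtype=bool)
    n_total = len(positive)
    positivity = float(positive.mean()) if n_total else 0.0
    per_sample = {}
    if n_total and "sample_id" in matrix.cells.columns:
        for sample, sub in matrix.detected["GAPDH"].groupby(matrix.cells["sample_id"]):
            per_sample[str(sample)] = float(sub.mean())
    report = {
        "n_total": n_total,
        "n_positive": int(positive.sum()),
        "positivity": positivity,
        "per_sample_positivity": per_sample,
        "min_required": config.min_gapdh_positivity,
        "passed": positivity > config.min_gapdh_positivity,
    }
    if not report["passed"]:
        logger.warning(
            "GAPDH positivity %.3f below the %.2f sort-efficiency bar",
            positivity, config.min_gapdh_positivity,
        )
    kept = matrix.values.index[positive]
    gated = matrix.subset_cells(kept)
    gated.provenance.append(f"qc_gapdh_gate(kept={len(kept)}/{n_total})")
    return gated, report


def to_log2(
    matrix: ExpressionMatrix, impute: bool = True, config: PreprocessConfig | None = None
) -> ExpressionMatrix:
    """log2-transform linear RQ values.

    With ``impute=True`` non-detects are filled one ``imputation_offset`` below
    the gene's minimum detected log2 value (0 for genes never detected),
    yielding a fully observed matrix for PCA/SOM/correlation while leaving the
    detection mask untouched. Without imputation non-detects stay NaN.
    """
    config = config or PreprocessConfig()
    if matrix.scale != "linear_rq":
        raise ValueError(f"to_log2 expects linear_rq input, got {matrix.scale!r}")
    det = matrix.detected.to_numpy(dtype=bool)
    vals = matrix.values.to_numpy(dtype=float)
    out = np.full_like(vals, np.nan)
    out[det] = np.log2(vals[det])
    if impute:
        for j in range(out.shape[1]):
            col_det = det[:, j]
            floor = out[col_det, j].min() - config.imputation_offset if col_det.any() else 0.0
            out[~col_det, j] = floor
        scale = "log2_rq_imputed"
        step = f"to_log2(impute=True, offset={config.imputation_offset})"
    else:
        scale = "log2_rq"
        step = "to_log2(impute=False)"
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    result = matrix.copy_with(values, scale, step)
    return result


def _zscore(a: np.ndarray, axis: int, what: str) -> np.ndarray:
    mean = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, ddof=1, keepdims=True) if a.shape[axis] > 1 else np.zeros_like(mean)
    out = a - mean
    const = (sd == 0) | ~np.isfinite(sd)
    if const.any():
        logger.warning("%d constant %s mapped to zeros during autoscaling", const.sum(), what)
    sd = np.where(const, 1.0, sd)
    out = out / sd
    out[np.broadcast_to(const, out.shape)] = 0.0
    return out


def autoscale_by_gene(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """z-score each gene across cells (sample SD); constant genes -> zeros."""
    _require_complete(matrix, "autoscale_by_gene")
    a = _zscore(matrix.values.to_numpy(dtype=float), axis=0, what="gene columns")
    values = pd.DataFrame(a, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.copy_with(values, "autoscaled_by_gene", "autoscale_by_gene")


def autoscale_by_cell(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """z-score each cell across genes — the global normalization that makes
    cells with different absolute RNA content comparable."""
    _require_complete(matrix, "autoscale_by_cell")
    a = _zscore(matrix.values.to_numpy(dtype=float), axis=1, what="cell rows")
    values = pd.DataFrame(a, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.copy_with(values, "autoscaled_by_cell", "autoscale_by_cell")


def mean_center_by_gene(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract the per-gene mean; variances untouched (heatmap convention)."""
    _require_complete(matrix, "mean_center_by_gene")
    a = matrix.values.to_numpy(dtype=float)
    a = a - a.mean(axis=0, keepdims=True)
    values = pd.DataFrame(a, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.copy_with(values, "mean_centered_by_gene", "mean_center_by_gene")


def combine_mean_centered(
    datasets: Sequence[ExpressionMatrix], genes: Sequence[str], names: Sequence[str] | None = None
) -> ExpressionMatrix:
    """Mean-center each dataset per gene independently, then stack rows.

    Restricting to a shared gene subset and centering per dataset removes
    dataset-level offsets so cell-line and patient cells can be co-embedded.
    The dataset of origin is kept in the cell metadata column ``dataset``.
    """
    if not datasets:
        raise ValueError("no datasets to combine")
    names = list(names) if names is not None else [f"dataset_{i}" for i in range(len(datasets))]
    blocks, cell_blocks = [], []
    for name, ds in zip(names, datasets):
        missing = [g for g in genes if g not in ds.values.columns]
        if missing:
            raise PanelError(f"dataset {name!r} missing genes: {missing}")
        sub = ds.subset_genes(genes)
        _require_complete(sub, "combine_mean_centered")
        centered = mean_center_by_gene(sub)
        blocks.append(centered.values)
        cells = centered.cells.copy()
        cells["dataset"] = name
        cell_blocks.append(cells)
    values = pd.concat(blocks, axis=0)
    detected = pd.concat([d.subset_genes(genes).detected for d in datasets], axis=0)
    cells = pd.concat(cell_blocks, axis=0)
    return ExpressionMatrix(
        values=values,
        detected=detected,
        cells=cells,
        scale="mean_centered_by_gene",
        provenance=[f"combine_mean_centered(n_datasets={len(datasets)}, genes={list(genes)})"],
        panel=datasets[0].panel,
    )


def _require_complete(matrix: ExpressionMatrix, op: str) -> None:
    if matrix.scale == "linear_rq":
        raise ValueError(f"{op} expects log-scale data, got linear_rq")
    if np.isnan(matrix.values.to_numpy(dtype=float)).any():
        raise ValueError(f"{op} requires a fully observed (imputed) matrix")
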