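"""Per-group frequency/level statistics, differential tests and bimodality.

Single-cell qPCR expression has two informative channels per gene and group:

* frequency — the fraction of QC-passed cells in which the gene is detected
  (the dropout/"number of positive cells" channel, which carries switch-like
  regulation), and
* level — the mean log2 relative quantity over the *detected* cells only
  (the transcript-abundance channel, which carries transitional regulation).

Bimodal expression within a group (the hallmark of a mixed low/high
population, e.g. ACTA2 in activated fibroblasts) is detected by fitting one-
and two-component Gaussian mixtures to the detected log2 values and selecting
by BIC; the posterior 0.5 crossing between the component means gives the
low/high stratification boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .panel import ExpressionMatrix
from .structure import SubgroupAssignment

logger = logging.getLogger("scfib")

SD_FLOOR = 1e-3
EM_RESTARTS = 10
EM_MAX_ITER = 500
EM_TOL = 1e-8


def _group_series(matrix: ExpressionMatrix, groups) -> pd.Series:
    """Resolve a grouping argument to a per-cell label series."""
    if isinstance(groups, SubgroupAssignment):
        s = groups.labels
    elif isinstance(groups, pd.Series):
        s = groups
    elif isinstance(groups, str):
        s = matrix.cells[groups]
    else:
        raise TypeError("groups must be a SubgroupAssignment, Series or metadata column name")
    return s.reindex(matrix.values.index)


def summarize_groups(matrix: ExpressionMatrix, groups) -> pd.DataFrame:
    """Frequency and detected-only expression level per (gene, group).

    Requires an unimputed log2-scale matrix so levels average real detected
    measurements. Returns a DataFrame indexed by (gene, group) with columns
    frequency, level, sem, n_pos, n_total; level and sem are NaN when no cell
    (or a single cell, for sem) is detected.
    """
    if matrix.scale not in ("log2_rq", "log2_rq_imputed"):
        raise ValueError("summarize_groups expects a log2-scale matrix")
    labels = _group_series(matrix, groups)
    if labels.isna().any():
        raise ValueError("every cell must carry a group label")
    det = matrix.detected
    vals = matrix.values
    records = []
    for group, idx in labels.groupby(labels).groups.items():
        if len(idx) == 0:
            raise ValueError(f"empty group {group!r}")
        d = det.loc[idx]
        v = vals.loc[idx]
        for gene in matrix.genes:
            mask = d[gene].to_numpy(dtype=bool)
            x = v[gene].to_numpy(dtype=float)[mask]
            n_pos, n_total = int(mask.sum()), len(mask)
            level = float(x.mean()) if n_pos else np.nan
            sem = float(x.std(ddof=1) / np.sqrt(n_pos)) if n_pos > 1 else np.nan
            records.append((gene, group, n_pos / n_total, level, sem, n_pos, n_total))
    out = pd.DataFrame(
        records, columns=["gene", "group", "frequency", "level", "sem", "n_pos", "n_total"]
    ).set_index(["gene", "group"])
    return out


def differential_expression(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    test: str = "student_t",
    alpha: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Two-sided per-gene comparison of detected log2 levels between two groups.

    Level tests use detected cells only and need >= 2 detected cells per side
    (p is NaN otherwise). ``test`` is one of student_t, anova, mann_whitney.
    ``adjust="bh"`` applies Benjamini-Hochberg before flagging significance
    (off by default, matching figure-legend per-gene alpha).
    """
    if test not in ("student_t", "anova", "mann_whitney"):
        raise ValueError(f"unknown test {test!r}")
    genes = matrix_a.genes
    if genes != matrix_b.genes:
        raise ValueError("gene panels differ between the two matrices")
    rows = []
    for gene in genes:
        xa = _detected_values(matrix_a, gene)
        xb = _detected_values(matrix_b, gene)
        freq_a = matrix_a.detected[gene].mean()
        freq_b = matrix_b.detected[gene].mean()
        delta_level = (xa.mean() if len(xa) else np.nan) - (xb.mean() if len(xb) else np.nan)
        if len(xa) >= 2 and len(xb) >= 2:
            if np.ptp(np.concatenate([xa, xb])) == 0:
                p = 1.0
            elif test == "student_t":
                p = float(sps.ttest_ind(xa, xb, equal_var=True).pvalue)
            elif test == "anova":
                p = float(sps.f_oneway(xa, xb).pvalue)
            else:
                p = float(sps.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        else:
            p = np.nan
        rows.append((gene, delta_level, float(freq_a - freq_b), p))
    out = pd.DataFrame(rows, columns=["gene", "delta_level", "delta_frequency", "p_value"])
    out = out.set_index("gene")
    pvals = out["p_value"].to_numpy()
    if adjust == "bh":
        ok = ~np.isnan(pvals)
        adj = np.full_like(pvals, np.nan)
        if ok.any():
            adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        out["p_adjusted"] = adj
        out["significant"] = adj < alpha
    elif adjust is None:
        out["significant"] = pvals < alpha
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def stratified_mean_scatter(
    reference: ExpressionMatrix,
    strata: dict[str, ExpressionMatrix],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean-vs-mean comparison of each stratum against a reference group.

    For every gene the record pairs the reference level with the stratum level
    and flags whether the gene lies *outside* the significance area — i.e.
    whether the per-gene two-sample Student t test on detected cells rejects
    at ``alpha``. Genes outside the area are the denoted discriminators.
    """
    frames = []
    for name, stratum in strata.items():
        if stratum.n_cells < 2:
            raise ValueError(f"stratum {name!r} has fewer than 2 cells")
        de = differential_expression(stratum, reference, test="student_t", alpha=alpha)
        ref_sum = summarize_groups(reference, pd.Series("ref", index=reference.values.index))
        str_sum = summarize_groups(stratum, pd.Series("s", index=stratum.values.index))
        df = pd.DataFrame(
            {
                "stratum": name,
                "reference_level": ref_sum.xs("ref", level="group")["level"],
                "stratum_level": str_sum.xs("s", level="group")["level"],
                "p_value": de["p_value"],
                "outside_significance_area": de["significant"].fillna(False),
            }
        )
        frames.append(df)
    return pd.concat(frames, axis=0)


def _detected_values(matrix: ExpressionMatrix, gene: str) -> np.ndarray:
    mask = matrix.detected[gene].to_numpy(dtype=bool)
    return matrix.values[gene].to_numpy(dtype=float)[mask]


@dataclass
class MixtureFit:
    """One- or two-component Gaussian fit to detected log2 expression values."""

    k: int
    weights: np.ndarray
    means: np.ndarray  # sorted ascending
    sds: np.ndarray
    bic: dict  # candidate k -> BIC
    boundary: float | None  # low/high split point (k=2 only)
    n: int

    def __post_init__(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.sds < SD_FLOOR - 1e-12):
            raise ValueError("component SDs below floor")
        if self.k == 2 and self.means[0] > self.means[1]:
            raise ValueError("means must be sorted ascending")


def fit_bimodal(values: np.ndarray, seed: int = 0, min_n: int = 10) -> MixtureFit:
    """Fit k=1 and k=2 Gaussians to one gene's detected log2 values; pick by BIC.

    k=1 is the closed-form normal fit; k=2 is EM with k-means-style restarts.
    For k=2 the low/high boundary is the point between the sorted means where
    the posterior responsibility of the high component crosses 0.5.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < min_n:
        raise ValueError(f"need at least {min_n} detected values, got {n}")

    # closed-form single Gaussian (MLE)
    mu1, sd1 = float(x.mean()), max(float(x.std(ddof=0)), SD_FLOOR)
    ll1 = float(sps.norm.logpdf(x, mu1, sd1).sum())
    bic1 = 2 * np.log(n) - 2 * ll1  # 2 free parameters

    if np.ptp(x) == 0:
        return MixtureFit(
            k=1, weights=np.array([1.0]), means=np.array([mu1]),
            sds=np.array([SD_FLOOR]), bic={1: bic1, 2: np.inf}, boundary=None, n=n,
        )

    gm = GaussianMixture(
        n_components=2,
        covariance_type="spherical",
        n_init=EM_RESTARTS,
        max_iter=EM_MAX_ITER,
        tol=EM_TOL,
        reg_covar=SD_FLOOR**2,
        init_params="k-means++",
        random_state=seed,
    ).fit(x[:, None])
    if not gm.converged_:
        logger.warning("EM did not converge within %d iterations; best fit kept", EM_MAX_ITER)
    order = np.argsort(gm.means_.ravel())
    means2 = gm.means_.ravel()[order]
    sds2 = np.maximum(np.sqrt(gm.covariances_.ravel()[order]), SD_FLOOR)
    w2 = gm.weights_[order]
    bic2 = float(gm.bic(x[:, None]))

    if bic2 < bic1:
        boundary = _posterior_boundary(w2, means2, sds2)
        return MixtureFit(
            k=2, weights=w2, means=means2, sds=sds2,
            bic={1: bic1, 2: bic2}, boundary=boundary, n=n,
        )
    return MixtureFit(
        k=1, weights=np.array([1.0]), means=np.array([mu1]),
        sds=np.array([max(sd1, SD_FLOOR)]), bic={1: bic1, 2: bic2}, boundary=None, n=n,
    )


def _posterior_boundary(w: np.ndarray, means: np.ndarray, sds: np.ndarray) -> float:
    """Point between the sorted means where P(high | x) = 0.5."""

    def diff(x: float) -> float:
        lo = w[0] * sps.norm.pdf(x, means[0], sds[0])
        hi = w[1] * sps.norm.pdf(x, means[1], sds[1])
        return hi - lo

    lo, hi = float(means[0]), float(means[1])
    if lo == hi:
        return lo
    flo, fhi = diff(lo), diff(hi)
    if flo * fhi > 0:  # no crossing inside (extreme weights): fall back to midpoint
        return (lo + hi) / 2.0
    return float(optimize.brentq(diff, lo, hi))


def stratify_by_gene(
    matrix: ExpressionMatrix, gene: str, fit: MixtureFit
) -> SubgroupAssignment:
    """Split cells into low/high by the fitted bimodal boundary of one gene.

    Detected cells at or above the boundary are "high", detected cells below
    it and all non-detect cells are "low".
    """
    if fit.k != 2:
        raise ValueError("no bimodal structure: fit has a single component")
    det = matrix.detected[gene].to_numpy(dtype=bool)
    vals = matrix.values[gene].to_numpy(dtype=float)
    high = det & (vals >= fit.boundary)
    labels = pd.Series(np.where(high, "high", "low"), index=matrix.values.index, name=gene)
    return SubgroupAssignment(labels=labels, method="manual_split", k=int(labels.nunique()))
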