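"""The drift test (Lande's model / β-test) on inter-landmark distances.

Under neutral divergence — mutation and genetic drift only — the
between-population variance B of a suite of traits is proportional to the
within-population variance W, direction by direction.  The test:

1. Reduce each specimen's landmark configuration to the chain of
   successive inter-landmark distances D_i (k landmarks give k - 1
   distances; 24 -> 23 for crania, 15 -> 14 for mandibles).
2. Estimate the within-population variance/covariance of D as the residual
   covariance of a two-factor additive linear model (locality + sex), i.e.
   the MANOVA error SSCP over its residual degrees of freedom, and
   eigendecompose it: the eigenvalues λ_j are W.
3. Project the per-locality mean D vectors onto the within-population
   eigenvectors; the variance (denominator g - 1) of the g projected
   means on each axis is B_j.
4. Keep the minimal leading set of PCs holding >= 95% of the within
   variance (trailing PCs are noise) and fit ln(B_j) = β0 + β ln(λ_j) by
   ordinary least squares.  A two-sided t-test of H0: β = 1 with
   df = n_pcs - 2 decides whether drift alone can explain the divergence;
   rejection implies selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import LandmarkConfiguration, LandmarkDataset, LandmarkError


def interlandmark_distances(config: LandmarkConfiguration | np.ndarray) -> np.ndarray:
    """Euclidean distances between successive landmarks, d[i] = |x_{i+1} - x_i|.

    The chain (1,2), (2,3), ..., (k-1,k) in stored landmark order; a
    k-landmark configuration yields exactly k - 1 distances.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if coords.shape[0] < 2:
        raise LandmarkError("need at least 2 landmarks for distances")
    return np.linalg.norm(np.diff(coords, axis=0), axis=1)


def distance_matrix(dataset: LandmarkDataset) -> np.ndarray:
    """(n, k-1) matrix of successive inter-landmark distances, specimen order preserved."""
    return np.vstack([interlandmark_distances(c) for c in dataset.configurations])


@dataclass
class VarianceDecomposition:
    """Within-population covariance of the distance traits and its spectrum.

    `eigenvalues` (descending) are the within-population variances W;
    `between_variance` (filled by :func:`between_variance`) holds B_j, the
    variance of the locality means projected on eigenvector j.
    """

    w_matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    residual_df: int
    retained: np.ndarray                      # indices of PCs kept for the regression
    group_means: pd.DataFrame | None = None   # locality x trait means
    between_variance: np.ndarray | None = None

    @property
    def n_traits(self) -> int:
        return self.w_matrix.shape[0]


def within_covariance(distances: np.ndarray, locality: np.ndarray,
                      sex: np.ndarray | None = None,
                      retention: float = 0.95) -> VarianceDecomposition:
    """Within-population V/CV matrix from two-factor model residuals.

    Fits the additive linear model D ~ locality + sex (sex optional) and
    returns the residual covariance (error SSCP / residual df), its
    eigendecomposition with deterministic eigenvector signs, and the
    minimal leading PC set whose eigenvalues sum to >= `retention` of the
    total; PCs with λ <= 1e-12·λ_max are always dropped.
    """
    d = np.asarray(distances, dtype=float)
    n, p = d.shape
    locality = np.asarray(locality)
    loc_levels = np.unique(locality)
    if len(loc_levels) < 2 and sex is not None:
        pass  # a single locality is allowed; the model reduces to sex only
    cols = [np.ones((n, 1))]
    cols.append(_dummies(locality))
    if sex is not None:
        sex = np.asarray(sex)
        if len(np.unique(sex)) > 1:
            cols.append(_dummies(sex))
            _check_cells(locality, sex)
    x = np.hstack(cols)
    rank = np.linalg.matrix_rank(x)
    if n <= rank:
        raise LandmarkError(f"need n > model rank ({rank}), got n = {n}")
    q, _ = np.linalg.qr(x)
    resid = d - q @ (q.T @ d)
    w = resid.T @ resid / (n - rank)
    if np.trace(w) <= 1e-24 * (float(np.mean(d ** 2)) + 1e-300):
        raise LandmarkError("within-population covariance is zero; cannot take logs")

    eigval, eigvec = np.linalg.eigh(w)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        col = eigvec[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            eigvec[:, j] = -col
    retained = _retain(eigval, retention)
    return VarianceDecomposition(w_matrix=w, eigenvalues=eigval, eigenvectors=eigvec,
                                 residual_df=n - rank, retained=retained)


def _dummies(labels: np.ndarray) -> np.ndarray:
    levels, codes = np.unique(labels, return_inverse=True)
    block = np.zeros((len(labels), max(len(levels) - 1, 0)))
    for c in range(1, len(levels)):
        block[codes == c, c - 1] = 1.0
    return block


def _check_cells(locality: np.ndarray, sex: np.ndarray) -> None:
    table = pd.crosstab(pd.Series(locality), pd.Series(sex))
    empty = [(str(r), str(c)) for r in table.index for c in table.columns if table.loc[r, c] == 0]
    if empty:
        x = np.hstack([np.ones((len(locality), 1)), _dummies(locality), _dummies(sex)])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise LandmarkError(f"additive locality+sex model unidentifiable; empty cells: {empty}")


def _retain(eigval: np.ndarray, retention: float) -> np.ndarray:
    positive = eigval > 1e-12 * max(eigval[0], 1e-300)
    total = eigval[positive].sum()
    if total <= 0:
        raise LandmarkError("within-population covariance is zero; cannot take logs")
    cum = np.cumsum(eigval) / total
    n_keep = int(np.searchsorted(cum, retention - 1e-12) + 1)
    n_keep = min(n_keep, int(positive.sum()))
    return np.arange(n_keep)


def between_variance(decomp: VarianceDecomposition, distances: np.ndarray,
                     locality: np.ndarray) -> VarianceDecomposition:
    """Between-population variances from eigenvector projection of locality means.

    The matrix of per-locality mean distance vectors is projected onto
    every within-population eigenvector; B_j is the variance (denominator
    g - 1) of the g projected means on axis j.  Fills `group_means` and
    `between_variance` on a copy of `decomp`.
    """
    d = np.asarray(distances, dtype=float)
    locality = np.asarray(locality)
    levels = np.unique(locality)
    g = len(levels)
    if g < 2:
        raise LandmarkError(f"between-population variance needs >= 2 localities, got {g}")
    means = np.vstack([d[locality == lev].mean(axis=0) for lev in levels])
    projected = means @ decomp.eigenvectors          # (g, p)
    b = projected.var(axis=0, ddof=1)
    return VarianceDecomposition(
        w_matrix=decomp.w_matrix, eigenvalues=decomp.eigenvalues,
        eigenvectors=decomp.eigenvectors, residual_df=decomp.residual_df,
        retained=decomp.retained,
        group_means=pd.DataFrame(means, index=pd.Index(levels, name="locality")),
        between_variance=b)


@dataclass
class BetaTestResult:
    """One fitted ln(B) = β0 + β ln(W) regression (a Table-1-shaped row)."""

    slope: float
    intercept: float
    se: float
    r2: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    n_pcs_used: int
    alpha: float
    drift_rejected: bool

    def as_row(self) -> dict:
        return {"R2": self.r2, "slope": self.slope, "intercept": self.intercept,
                "se": self.se, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "p_beta_ne_1": self.p, "n_pcs": self.n_pcs_used,
                "reject_drift": self.drift_rejected}


def beta_test(decomp: VarianceDecomposition, alpha: float = 0.05) -> BetaTestResult:
    """OLS of ln(B_j) on ln(λ_j) over the retained PCs, testing H0: β = 1.

    Uses a two-sided t-test with df = n_pcs - 2 and a t-based 95%
    confidence interval.  Retained PCs with non-positive λ or B are an
    error (the caller must drop them explicitly), as is n_pcs < 3.
    """
    if decomp.between_variance is None:
        raise LandmarkError("run between_variance before beta_test")
    idx = decomp.retained
    lam = decomp.eigenvalues[idx]
    b = decomp.between_variance[idx]
    bad = [int(j) + 1 for j, (w_j, b_j) in enumerate(zip(lam, b)) if w_j <= 0 or b_j <= 0]
    if bad:
        raise LandmarkError(f"non-positive W or B on retained PCs {bad}; cannot take logs")
    n = len(idx)
    if n < 3:
        raise LandmarkError(f"beta test needs >= 3 retained PCs, got {n}")
    x = np.log(lam)
    y = np.log(b)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise LandmarkError("all retained eigenvalues equal; slope undefined")
    slope = float(xc @ y) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    df = n - 2
    rss = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot > 0 and rss < 1e-24 * ss_tot:
        rss = 0.0  # numerically perfect log-linear fit
    mse = rss / df
    se = float(np.sqrt(mse / sxx))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 1.0
    if se > 0:
        t = (slope - 1.0) / se
        p = float(2 * sps.t.sf(abs(t), df))
    else:  # perfect fit: p -> 1 when the slope is exactly 1, else -> 0
        t = 0.0 if np.isclose(slope, 1.0) else np.inf * np.sign(slope - 1.0)
        p = 1.0 if np.isclose(slope, 1.0) else 0.0
    tq = sps.t.ppf(0.975, df)
    return BetaTestResult(slope=slope, intercept=intercept, se=se, r2=r2,
                          ci_low=slope - tq * se, ci_high=slope + tq * se,
                          t=float(t), p=p, n_pcs_used=n, alpha=alpha,
                          drift_rejected=bool(p < alpha))


def run_lande_pipeline(dataset: LandmarkDataset, use_sex: bool = True,
                       retention: float = 0.95, alpha: float = 0.05,
                       site_exclusion: bool = False,
                       ) -> tuple[BetaTestResult, VarianceDecomposition]:
    """Full drift test on a landmark dataset with locality (and sex) metadata."""
    if site_exclusion:
        # jackknife-by-locality needs more sites than these study designs
        # carry; the flag is reserved so configs stay forward-compatible
        raise LandmarkError("site-exclusion (jackknife-by-locality) analysis "
                            "is not implemented")
    locality = dataset.metadata_column("locality")
    if len(np.unique(locality)) < 2:
        raise LandmarkError("drift test needs >= 2 localities")
    sex = dataset.metadata_column("sex") if use_sex else None
    d = distance_matrix(dataset)
    decomp = within_covariance(d, locality, sex, retention=retention)
    decomp = between_variance(decomp, d, locality)
    result = beta_test(decomp, alpha=alpha)
    return result, decomp


def beta_test_from_distances(distances: np.ndarray, locality: np.ndarray,
                             sex: np.ndarray | None = None,
                             retention: float = 0.95,
                             alpha: float = 0.05) -> BetaTestResult:
    """Drift test straight from an (n, p) distance-trait matrix."""
    decomp = within_covariance(distances, locality, sex, retention=retention)
    decomp = between_variance(decomp, np.asarray(distances, float), locality)
    return beta_test(decomp, alpha=alpha)


def write_beta_table(results: dict[str, BetaTestResult], path: str | Path) -> None:
    """TSV with one row per analysis, mirroring the drift-test summary table."""
    table = pd.DataFrame({name: r.as_row() for name, r in results.items()}).T
    table.index.name = "analysis"
    table.to_csv(path, sep="\t")
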