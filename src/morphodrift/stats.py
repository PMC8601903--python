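"""Descriptive shape statistics: allometry, PCA, CVA, Procrustes ANOVA,
and shape-vs-geography regression.

All operations act on flattened shape coordinates (an n x 3k matrix) or on
an :class:`~morphodrift.align.AlignedDataset`.  For 3D shapes aligned by
full Procrustes superimposition the shape space has dimension
m = 3k - 7 (translation removes 3 degrees of freedom, rotation 3,
scale 1); Goodall-style ANOVA multiplies univariate degrees of freedom by
m, which is what produces F subscripts such as F_65;3510 for a 24-landmark
cranium with a 2-level factor and 56 specimens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .align import AlignedDataset
from .datatypes import LandmarkError


def shape_dimension(k: int, scaled: bool = True) -> int:
    """Dimension of the 3D shape space: 3k - 7 with scaling removed, 3k - 6 without."""
    return 3 * k - 7 if scaled else 3 * k - 6


# ---------------------------------------------------------------------------
# Allometry

@dataclass
class AllometryResult:
    coefficients: np.ndarray        # (3k,) slope of each coordinate on (log) size
    percent_predicted: float        # % of total shape variance explained by size
    p_parametric: float
    p_permutation: float | None
    residuals: np.ndarray           # (n, 3k) size-adjusted shapes (mean added back)
    use_log_size: bool
    significant: bool
    alpha: float


def allometry(aligned: AlignedDataset, use_log_size: bool = True,
              n_perm: int = 10000, seed: int | None = None,
              alpha: float = 0.05) -> AllometryResult:
    """Multivariate regression of shape on (log) centroid size.

    Percent predicted is SS_predicted / SS_total * 100 summed over all
    coordinates.  The permutation p-value shuffles centroid sizes across
    specimens (`n_perm=0` skips it); the parametric p is from Goodall's F
    with df (m, (n-2)m).  Residuals are returned with the mean shape added
    back, so they live in the original coordinate frame.
    """
    y = aligned.flat()
    n = y.shape[0]
    if n <= 3:
        raise LandmarkError("allometry needs n > 3 specimens")
    sizes = aligned.centroid_sizes.astype(float)
    if np.ptp(sizes) == 0:
        raise LandmarkError("no size variation: all centroid sizes equal")
    x = np.log(sizes) if use_log_size else sizes

    xc = x - x.mean()
    yc = y - y.mean(axis=0)
    beta = (xc @ yc) / (xc @ xc)          # (3k,)
    fitted = np.outer(xc, beta)
    ss_total = float((yc ** 2).sum())
    ss_pred = float((fitted ** 2).sum())
    percent = 100.0 * ss_pred / ss_total
    m = shape_dimension(aligned.k, aligned.scaled)
    f_obs = (ss_pred / m) / ((ss_total - ss_pred) / ((n - 2) * m))
    p_param = float(sps.f.sf(f_obs, m, (n - 2) * m))

    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            xp = rng.permutation(xc)
            ssp = float(((xp @ yc) ** 2).sum()) / (xp @ xp)
            if ssp >= ss_pred - 1e-12:
                exceed += 1
        p_perm = (1 + exceed) / (n_perm + 1)

    p_decision = p_perm if p_perm is not None else p_param
    residuals = yc - fitted + y.mean(axis=0)
    return AllometryResult(coefficients=beta, percent_predicted=percent,
                           p_parametric=p_param, p_permutation=p_perm,
                           residuals=residuals, use_log_size=use_log_size,
                           significant=p_decision < alpha, alpha=alpha)


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    eigenvalues: np.ndarray         # descending, >= 0
    eigenvectors: np.ndarray        # columns, orthonormal, deterministic signs
    scores: np.ndarray              # (n, n_components)
    percent_variance: np.ndarray
    mean: np.ndarray


def shape_pca(coords: np.ndarray) -> PCAResult:
    """Eigendecomposition of the sample covariance (denominator n-1).

    Components are ordered by descending eigenvalue; each eigenvector is
    signed so its largest-magnitude loading is positive.  Tiny negative
    eigenvalues from round-off are clipped to 0.
    """
    y = np.asarray(coords, dtype=float)
    if y.ndim != 2 or y.shape[0] < 3:
        raise LandmarkError("shape_pca needs an n x p matrix with n >= 3")
    if not np.all(np.isfinite(y)):
        raise LandmarkError("non-finite values in PCA input")
    mean = y.mean(axis=0)
    yc = y - mean
    cov = yc.T @ yc / (y.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    eigvec = _fix_signs(eigvec)
    total = eigval.sum()
    percent = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
    return PCAResult(eigenvalues=eigval, eigenvectors=eigvec,
                     scores=yc @ eigvec, percent_variance=percent, mean=mean)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    vectors = vectors.copy()
    for j in range(vectors.shape[1]):
        col = vectors[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            vectors[:, j] = -col
    return vectors


# ---------------------------------------------------------------------------
# CVA

@dataclass
class CVAResult:
    canonical_vectors: np.ndarray   # (p, n_cv) in the original coordinate basis
    eigenvalues: np.ndarray         # among/within variance ratios, descending
    percent_among: np.ndarray       # sums to 100 over the nonzero CVs
    scores: np.ndarray              # (n, n_cv)
    group_means: pd.DataFrame       # one row per group, columns CV1..
    groups: np.ndarray


def cva(coords: np.ndarray, groups: np.ndarray,
        max_rank: int | None = None) -> CVAResult:
    """Canonical variate analysis of grouped multivariate data.

    Shape coordinates are rank-deficient (p = 3k typically exceeds n), so
    the data are first projected onto the principal components carrying
    all non-negligible variance, capped at n - g dimensions so the pooled
    within-group covariance is invertible; the generalized among/within
    eigenproblem is solved there and the axes mapped back.  At most g - 1
    canonical variates have nonzero among-group variance.
    """
    y = np.asarray(coords, dtype=float)
    groups = np.asarray(groups)
    levels, codes = np.unique(groups, return_inverse=True)
    g = len(levels)
    if g < 2:
        raise LandmarkError("CVA needs at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        lonely = levels[counts < 2]
        raise LandmarkError(f"every group needs >= 2 specimens; too small: {list(lonely)}")
    n = y.shape[0]

    pca = shape_pca(y)
    lam = pca.eigenvalues
    nonzero = lam > 1e-12 * max(lam[0], 1e-300)
    cum = np.cumsum(lam) / lam.sum()
    enough = np.searchsorted(cum, 1.0 - 1e-12) + 1
    r = min(int(nonzero.sum()), int(enough), n - g)
    if max_rank is not None:
        r = min(r, max_rank)
    if r < 1:
        raise LandmarkError("no usable dimensions for CVA")
    z = pca.scores[:, :r]

    grand = z.mean(axis=0)
    within = np.zeros((r, r))
    among = np.zeros((r, r))
    for c in range(g):
        zg = z[codes == c]
        mu = zg.mean(axis=0)
        within += (zg - mu).T @ (zg - mu)
        among += counts[c] * np.outer(mu - grand, mu - grand)
    within /= (n - g)
    among /= (g - 1)

    from scipy.linalg import eigh as generalized_eigh
    eigval, eigvec = generalized_eigh(among, within)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    n_cv = min(g - 1, r)
    eigval = eigval[:n_cv]
    eigvec = eigvec[:, :n_cv]

    vectors = _fix_signs(pca.eigenvectors[:, :r] @ eigvec)
    scores = (y - y.mean(axis=0)) @ vectors
    total = eigval.sum()
    percent = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
    gm = pd.DataFrame(
        np.vstack([scores[codes == c].mean(axis=0) for c in range(g)]),
        index=pd.Index(levels, name="group"),
        columns=[f"CV{j + 1}" for j in range(n_cv)],
    )
    return CVAResult(canonical_vectors=vectors, eigenvalues=eigval,
                     percent_among=percent, scores=scores, group_means=gm,
                     groups=groups)


# ---------------------------------------------------------------------------
# Procrustes ANOVA

@dataclass
class ProcrustesAnovaResult:
    factor: str
    response: str
    ss_effect: float
    ss_error: float
    df_effect: int
    df_error: int
    f: float
    p_parametric: float
    p_permutation: float | None
    n_permutations: int


def procrustes_anova(aligned: AlignedDataset, response: str = "shape",
                     factors: list[str] | None = None,
                     metadata: pd.DataFrame | None = None,
                     factor_values: dict[str, np.ndarray] | None = None,
                     n_perm: int = 10000, seed: int | None = None) -> list[ProcrustesAnovaResult]:
    """Goodall-style ANOVA of shape (or centroid size) on categorical factors.

    Sequential (type-I) sums of squares are accumulated over all shape
    coordinates; degrees of freedom are the univariate ones multiplied by
    m = 3k - 7 for shape (m = 1 for size).  The permutation p-value uses
    residual randomization: for each term, residuals of the model reduced
    by that term are shuffled and the term's F recomputed.

    `factor_values` maps factor names to length-n label arrays; factors
    may instead be looked up in `metadata` (requires a ``specimen_id``
    column aligned through the dataset's specimen ids).
    """
    if response == "shape":
        y = aligned.flat()
        m = shape_dimension(aligned.k, aligned.scaled)
    elif response == "size":
        y = np.log(aligned.centroid_sizes)[:, None]
        m = 1
    else:
        raise LandmarkError(f"unknown response {response!r}")
    n = y.shape[0]
    if factors is None:
        factors = ["locality"]
    values = {}
    for f in factors:
        if factor_values is not None and f in factor_values:
            values[f] = np.asarray(factor_values[f])
        elif metadata is not None:
            table = metadata.set_index("specimen_id")
            values[f] = table.loc[aligned.specimen_ids, f].to_numpy()
        else:
            raise LandmarkError(f"no values supplied for factor {f!r}")

    # sequential design matrices: intercept, then dummy blocks per factor
    blocks = [np.ones((n, 1))]
    for f in factors:
        blocks.append(_dummy_block(values[f]))
    rank_prev = 1
    designs = []
    for j in range(1, len(blocks)):
        x = np.hstack(blocks[: j + 1])
        rank = np.linalg.matrix_rank(x)
        if rank <= rank_prev:
            raise LandmarkError(f"factor {factors[j - 1]!r} is aliased with preceding terms")
        designs.append((x, rank))
        rank_prev = rank

    full_x, full_rank = designs[-1]
    if full_rank >= n:
        raise LandmarkError("saturated design: no residual degrees of freedom")
    rss = [_rss(np.hstack(blocks[:1]), y)]
    for x, _ in designs:
        rss.append(_rss(x, y))
    df_err_uni = n - full_rank
    ss_err = rss[-1]

    rng = np.random.default_rng(seed)
    results = []
    for j, f in enumerate(factors):
        ss_eff = rss[j] - rss[j + 1]
        df_eff_uni = designs[j][1] - (designs[j - 1][1] if j > 0 else 1)
        df_eff = df_eff_uni * m
        df_err = df_err_uni * m
        f_obs = (ss_eff / df_eff) / (ss_err / df_err)
        p_param = float(sps.f.sf(f_obs, df_eff, df_err))
        p_perm = None
        if n_perm > 0:
            # residual randomization: shuffle residuals of the model
            # reduced by this term, recompute the term's F each time
            x_red = np.hstack(blocks[: j + 1])
            q_red, _ = np.linalg.qr(x_red)
            fitted_red = q_red @ (q_red.T @ y)
            resid_red = y - fitted_red
            q_cur, _ = np.linalg.qr(designs[j][0])
            q_full, _ = np.linalg.qr(full_x)
            exceed = 0
            for _ in range(n_perm):
                yp = fitted_red + resid_red[rng.permutation(n)]
                rss_red_p = float(((yp - q_red @ (q_red.T @ yp)) ** 2).sum())
                rss_cur_p = float(((yp - q_cur @ (q_cur.T @ yp)) ** 2).sum())
                rss_full_p = float(((yp - q_full @ (q_full.T @ yp)) ** 2).sum())
                f_p = ((rss_red_p - rss_cur_p) / df_eff) / (max(rss_full_p, 1e-300) / df_err)
                if f_p >= f_obs - 1e-12:
                    exceed += 1
            p_perm = (1 + exceed) / (n_perm + 1)
        results.append(ProcrustesAnovaResult(
            factor=f, response=response, ss_effect=float(ss_eff), ss_error=float(ss_err),
            df_effect=int(df_eff), df_error=int(df_err), f=float(f_obs),
            p_parametric=p_param, p_permutation=p_perm, n_permutations=n_perm))
    return results


def _dummy_block(labels: np.ndarray) -> np.ndarray:
    levels, codes = np.unique(labels, return_inverse=True)
    if len(levels) < 2:
        raise LandmarkError("factor needs >= 2 levels")
    block = np.zeros((len(labels), len(levels) - 1))
    for c in range(1, len(levels)):
        block[codes == c, c - 1] = 1.0
    return block


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    q, _ = np.linalg.qr(x)
    resid = y - q @ (q.T @ y)
    return float((resid ** 2).sum())


def anova_dfs(k: int, n: int, n_levels: int = 2, scaled: bool = True) -> tuple[int, int]:
    """Goodall degrees of freedom (effect, error) for a single categorical factor."""
    m = shape_dimension(k, scaled)
    return (n_levels - 1) * m, (n - n_levels) * m


# ---------------------------------------------------------------------------
# Sex balancing

def balance_sexes(dataset, seed: int, grouping: str = "locality"):
    """Subsample the more numerous sex within each group to equalize counts.

    Used when a Procrustes ANOVA finds a significant sex effect: instead
    of modelling sex, the larger sex is randomly thinned (recorded seed)
    so the sexes are balanced within every level of `grouping`; specimens
    of unknown sex are kept.  Returns a new dataset in original specimen
    order.
    """
    from .datatypes import LandmarkDataset

    rng = np.random.default_rng(seed)
    sex = np.asarray(dataset.metadata_column("sex"))
    group = np.asarray(dataset.metadata_column(grouping))
    keep = np.zeros(dataset.n, dtype=bool)
    keep[sex == "unknown"] = True
    for lev in pd.unique(group):
        in_group = group == lev
        males = np.flatnonzero(in_group & (sex == "M"))
        females = np.flatnonzero(in_group & (sex == "F"))
        n_keep = min(len(males), len(females))
        for idx in (males, females):
            chosen = rng.choice(idx, size=n_keep, replace=False) if len(idx) > n_keep else idx
            keep[chosen] = True
    if not keep.any():
        raise LandmarkError("sex balancing removed every specimen")
    configs = [c for c, k in zip(dataset.configurations, keep) if k]
    return LandmarkDataset(configs, dataset.metadata)


# ---------------------------------------------------------------------------
# Geography

@dataclass
class GeoRegressionResult:
    table: pd.DataFrame  # rows latitude/longitude; columns slope, intercept, r2, f, p


def geo_regression(pc1_scores: np.ndarray, metadata: pd.DataFrame | None = None,
                   latitude: np.ndarray | None = None,
                   longitude: np.ndarray | None = None) -> GeoRegressionResult:
    """Simple linear regressions of PC1 scores on latitude and on longitude."""
    y = np.asarray(pc1_scores, dtype=float)
    if metadata is not None:
        latitude = metadata["latitude"].to_numpy(dtype=float)
        longitude = metadata["longitude"].to_numpy(dtype=float)
    if latitude is None or longitude is None:
        raise LandmarkError("latitude and longitude required")
    if len(y) < 3:
        raise LandmarkError("geo regression needs n >= 3 (no residual df otherwise)")
    rows = {}
    for name, x in (("latitude", np.asarray(latitude, float)),
                    ("longitude", np.asarray(longitude, float))):
        if np.ptp(x) == 0:
            raise LandmarkError(f"constant {name}: regression undefined")
        res = sps.linregress(x, y)
        df = len(y) - 2
        f = res.rvalue ** 2 / max(1 - res.rvalue ** 2, 1e-300) * df
        rows[name] = dict(slope=res.slope, intercept=res.intercept,
                          r2=res.rvalue ** 2, f=f, p=res.pvalue)
    return GeoRegressionResult(table=pd.DataFrame(rows).T)
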