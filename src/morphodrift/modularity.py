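"""Covariance-ratio (CR) test of two-block modularity hypotheses.

The CR statistic compares the covariation between two a priori landmark
blocks with the covariation inside them:

    CR = sqrt( tr(S_AB' S_AB) / sqrt( tr(S*_AA S*_AA) tr(S*_BB S*_BB) ) )

where S is the sample covariance of the flattened coordinates partitioned
by module and S* zeroes the within-block diagonal.  At the population
level CR runs from 0 (independent blocks, strong modularity) to 1
(integrated); the sample statistic can exceed 1.  Significance comes from
permuting whole landmarks (the three coordinates of a landmark travel
together) across modules, preserving module sizes; the test is one-tailed
toward small CR.  Z_cr standardizes the observed CR against the
permutation distribution — the more negative, the stronger the
modularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import LandmarkError


@dataclass
class Partition:
    """Two-module assignment of k landmarks.

    `module_a` / `module_b` hold 1-based landmark indices, e.g. the
    cranium hypothesis rostrum = 1-5, 17-24 vs. basicranium = 6-16 and
    the mandible hypothesis ascending ramus = 1-5 vs. alveolar
    region = 6-15.
    """

    module_a: list[int]
    module_b: list[int]
    name_a: str = "A"
    name_b: str = "B"

    def __post_init__(self) -> None:
        a, b = set(self.module_a), set(self.module_b)
        if len(a) < 2 or len(b) < 2:
            raise LandmarkError("each module needs at least 2 landmarks")
        if a & b:
            raise LandmarkError(f"landmarks in both modules: {sorted(a & b)}")
        if min(a | b) < 1:
            raise LandmarkError("landmark indices are 1-based")

    @property
    def k(self) -> int:
        return len(self.module_a) + len(self.module_b)

    def labels(self, k: int) -> np.ndarray:
        """Length-k array of 'A'/'B' labels; errors if the partition doesn't cover 1..k."""
        if set(self.module_a) | set(self.module_b) != set(range(1, k + 1)):
            raise LandmarkError(
                f"partition ({sorted(self.module_a)} | {sorted(self.module_b)}) "
                f"does not cover landmarks 1..{k}")
        out = np.empty(k, dtype="<U1")
        out[np.asarray(self.module_a) - 1] = "A"
        out[np.asarray(self.module_b) - 1] = "B"
        return out


MANDIBLE_PARTITION = Partition(module_a=list(range(1, 6)), module_b=list(range(6, 16)),
                               name_a="ascending_ramus", name_b="alveolar_region")
CRANIUM_PARTITION = Partition(module_a=list(range(6, 17)),
                              module_b=list(range(1, 6)) + list(range(17, 25)),
                              name_a="basicranium", name_b="rostrum")


@dataclass
class ModularityResult:
    observed_cr: float
    permuted_cr: np.ndarray
    p: float
    z_cr: float
    n_perm: int
    seed: int | None
    partition: Partition = field(repr=False)


def _coordinate_columns(landmark_idx: np.ndarray) -> np.ndarray:
    """Column indices in the flattened n x 3k matrix for 1-based landmark indices."""
    base = (np.asarray(landmark_idx) - 1) * 3
    return np.concatenate([base + d for d in range(3)]).reshape(3, -1).T.ravel()


def _cr_from_cov(cov: np.ndarray, cols_a: np.ndarray, cols_b: np.ndarray) -> float:
    s_ab = cov[np.ix_(cols_a, cols_b)]
    s_aa = cov[np.ix_(cols_a, cols_a)].copy()
    s_bb = cov[np.ix_(cols_b, cols_b)].copy()
    np.fill_diagonal(s_aa, 0.0)
    np.fill_diagonal(s_bb, 0.0)
    denom = np.sqrt((s_aa ** 2).sum() * (s_bb ** 2).sum())
    if denom == 0:
        raise LandmarkError("zero within-block covariance: CR undefined")
    return float(np.sqrt((s_ab ** 2).sum() / np.sqrt((s_aa ** 2).sum() * (s_bb ** 2).sum())))


def covariance_ratio(coords: np.ndarray, partition: Partition) -> float:
    """CR statistic on an (n, 3k) or (n, k, 3) coordinate matrix."""
    y = np.asarray(coords, dtype=float)
    if y.ndim == 3:
        y = y.reshape(y.shape[0], -1)
    n, p = y.shape
    if n < 3:
        raise LandmarkError("CR needs n >= 3 specimens")
    k = p // 3
    if p != 3 * k or partition.k != k:
        raise LandmarkError(f"partition covers {partition.k} landmarks, data has {p // 3}")
    partition.labels(k)  # validates coverage
    yc = y - y.mean(axis=0)
    cov = yc.T @ yc / (n - 1)
    cols_a = _coordinate_columns(np.asarray(partition.module_a))
    cols_b = _coordinate_columns(np.asarray(partition.module_b))
    return _cr_from_cov(cov, cols_a, cols_b)


def cr_permutation_test(coords: np.ndarray, partition: Partition,
                        n_perm: int = 999, seed: int | None = None) -> ModularityResult:
    """Permutation test of modularity with the Z_cr effect size.

    Whole landmarks are reassigned to modules uniformly at random
    (preserving module sizes) `n_perm` times and CR recomputed from the
    same covariance matrix.  p = (1 + #{CR_perm <= CR_obs}) / (n_perm + 1)
    (one-tailed toward small CR); Z_cr = (CR_obs - mean_perm) / sd_perm.
    """
    if n_perm < 99:
        raise LandmarkError("n_perm must be >= 99 for a usable null distribution")
    y = np.asarray(coords, dtype=float)
    if y.ndim == 3:
        y = y.reshape(y.shape[0], -1)
    n, p = y.shape
    k = p // 3
    n_a = len(partition.module_a)
    observed = covariance_ratio(y, partition)
    yc = y - y.mean(axis=0)
    cov = yc.T @ yc / (n - 1)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    all_landmarks = np.arange(1, k + 1)
    for i in range(n_perm):
        shuffled = rng.permutation(all_landmarks)
        cols_a = _coordinate_columns(np.sort(shuffled[:n_a]))
        cols_b = _coordinate_columns(np.sort(shuffled[n_a:]))
        permuted[i] = _cr_from_cov(cov, cols_a, cols_b)
    p_val = (1 + int((permuted <= observed + 1e-12).sum())) / (n_perm + 1)
    sd = permuted.std(ddof=1)
    z = (observed - permuted.mean()) / sd if sd > 0 else 0.0
    return ModularityResult(observed_cr=observed, permuted_cr=permuted, p=p_val,
                            z_cr=float(z), n_perm=n_perm, seed=seed, partition=partition)
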