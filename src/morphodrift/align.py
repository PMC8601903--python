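"""Generalized Procrustes analysis (GPA) of 3D landmark configurations.

Superimposition removes nuisance variation — position, orientation and
(optionally) scale — leaving shape coordinates in the frame of the sample
consensus.  Rotations are proper (determinant +1): configurations here are
digitized on one anatomical side, so a reflection would map a right half
onto a left half and is anatomically meaningless.

The consensus orientation is made deterministic by rotating the converged
consensus so its principal axes coincide with the coordinate axes, each
axis signed so its largest-magnitude loading is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import LandmarkDataset, LandmarkError

DEFAULT_TOL = 1e-10
MAX_ITERATIONS = 200


@dataclass
class AlignedDataset:
    """Procrustes-superimposed shape coordinates.

    Attributes
    ----------
    shape_coords : (n, k, 3) ndarray
        Aligned configurations; each is centered at the origin and, when
        scaling was applied, has unit centroid size.
    centroid_sizes : (n,) ndarray
        Pre-scaling centroid sizes in input length units.
    consensus : (k, 3) ndarray
        Mean shape at convergence.
    """

    shape_coords: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    specimen_ids: list[str]
    n_iterations: int
    converged: bool
    scaled: bool

    @property
    def n(self) -> int:
        return self.shape_coords.shape[0]

    @property
    def k(self) -> int:
        return self.shape_coords.shape[1]

    def flat(self) -> np.ndarray:
        """Shape coordinates as an (n, 3k) matrix (x1 y1 z1 x2 ...)."""
        return self.shape_coords.reshape(self.n, -1)


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared distances of landmarks to their centroid.

    The standard geometric-morphometrics size measure, in input length
    units.  Coincident landmarks give 0 (with a warning).
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered ** 2).sum()))
    if cs == 0.0:
        warnings.warn("degenerate configuration: all landmarks coincident", stacklevel=2)
    return cs


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimizing ||source @ R - target||_F.

    Both inputs must already be centered.  Solved from the SVD of
    source^T target with the smallest singular value's sign flipped when
    the unconstrained optimum would be a reflection.
    """
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.ones(source.shape[1])
    flip[-1] = d if d != 0 else 1.0
    return (u * flip) @ vt


def gpa(dataset: LandmarkDataset | np.ndarray, scale: bool = True,
        tol: float = DEFAULT_TOL, max_iter: int = MAX_ITERATIONS) -> AlignedDataset:
    """Iterative generalized Procrustes superimposition.

    Each configuration is centered, scaled to unit centroid size (if
    `scale`), and rotated to the running consensus; the consensus is the
    arithmetic mean of aligned configurations, recomputed until it moves
    by less than `tol` in Procrustes distance.

    Returns an :class:`AlignedDataset`; `converged` is False (with a
    warning) if `max_iter` is exhausted.
    """
    if isinstance(dataset, LandmarkDataset):
        arr = dataset.coords_array()
        ids = dataset.specimen_ids
    else:
        arr = np.asarray(dataset, dtype=float)
        ids = [f"specimen_{i + 1}" for i in range(arr.shape[0])]
    n = arr.shape[0]
    if n < 2:
        raise LandmarkError("GPA needs at least 2 configurations")

    centered = arr - arr.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centered ** 2).sum(axis=(1, 2)))
    for i, s in enumerate(sizes):
        if s <= 0:
            raise LandmarkError(f"degenerate configuration (zero centroid size): specimen {ids[i]!r}")
    work = centered / sizes[:, None, None] if scale else centered.copy()

    consensus = work[0].copy()
    if scale:
        consensus /= np.linalg.norm(consensus)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        for i in range(n):
            work[i] = work[i] @ optimal_rotation(work[i], consensus)
        new_consensus = work.mean(axis=0)
        if scale:
            new_consensus /= np.linalg.norm(new_consensus)
        shift = np.linalg.norm(new_consensus - consensus)
        consensus = new_consensus
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"GPA did not converge in {max_iter} iterations", stacklevel=2)

    rot = _principal_axes_rotation(consensus)
    work = work @ rot
    consensus = work.mean(axis=0)  # arithmetic mean of the aligned shapes

    return AlignedDataset(shape_coords=work, centroid_sizes=sizes, consensus=consensus,
                          specimen_ids=list(ids), n_iterations=n_iter,
                          converged=converged, scaled=scale)


def _principal_axes_rotation(shape: np.ndarray) -> np.ndarray:
    """Proper rotation taking `shape`'s principal axes to the coordinate axes.

    Axis signs are fixed from the rotated shape itself (the landmark with
    the largest |coordinate| on each axis gets a positive value), which
    is invariant to the input frame since landmark order is intrinsic; if
    that choice yields a reflection, the smallest-variance axis is
    flipped back.
    """
    cov = shape.T @ shape
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigvec = eigvec[:, order]
    rotated = shape @ eigvec
    for j in range(3):
        if rotated[np.argmax(np.abs(rotated[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    if np.linalg.det(eigvec) < 0:
        eigvec[:, 2] = -eigvec[:, 2]
    return eigvec


def procrustes_distance(a: np.ndarray, b: np.ndarray, scale: bool = True) -> float:
    """Root-sum-of-squares between two shapes after optimal superimposition.

    Both shapes are centered (and unit-size scaled when `scale`), then `b`
    is rotated onto `a`.  Symmetric to numerical precision.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise LandmarkError(f"shape mismatch: {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    if scale:
        na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
        if na == 0 or nb == 0:
            raise LandmarkError("degenerate configuration in procrustes_distance")
        ac, bc = ac / na, bc / nb
    bc = bc @ optimal_rotation(bc, ac)
    return float(np.linalg.norm(ac - bc))


def flag_outliers(aligned: AlignedDataset, threshold: float = 3.0) -> list[str]:
    """Specimens unusually far from the consensus.

    Flags specimens whose Procrustes distance to the consensus exceeds
    Q3 + `threshold` * IQR of the sample distances (Tukey fence; the
    default 3.0 flags only extreme cases).
    """
    if aligned.n < 4:
        raise LandmarkError("outlier flagging needs at least 4 specimens")
    dists = np.array([
        procrustes_distance(aligned.consensus, aligned.shape_coords[i], scale=aligned.scaled)
        for i in range(aligned.n)
    ])
    q1, q3 = np.percentile(dists, [25, 75])
    fence = q3 + threshold * (q3 - q1)
    return [sid for sid, d in zip(aligned.specimen_ids, dists) if d > fence]
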