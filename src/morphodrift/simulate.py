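"""Synthetic landmark data with controlled evolutionary structure.

The generator emulates the statistical skeleton of a multi-locality
skull-morphometrics study: a fixed mean shape per structure (24-landmark
cranium, 15-landmark mandible), locality groups of 5-25 specimens whose
means diverge either neutrally (group means drawn with covariance c times
the within-group covariance, so B is proportional to W by construction),
under directional selection (divergence inflated along chosen
within-covariance eigenvectors only), or under stabilizing selection
(neutral divergence shrunk toward the grand mean); within-group
covariance that is isotropic, single-factor, or modular (two landmark
blocks with within-module correlation r_w and between-module correlation
r_b); optional allometry (a shape direction tied to log centroid size);
and replicate digitizing error for the precision analysis.

Two injection scales are provided.  Coordinate-scale noise perturbs the
3k landmark coordinates (realistic end-to-end input); distance-scale
noise (:func:`simulate_distance_data`) defines the covariance directly on
the k - 1 successive inter-landmark distances, which calibrates the
β-test exactly because no nonlinear distance transform intervenes.

Group means and within-group deviations are drawn from independent seed
streams, so enlarging a group never moves its mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import LandmarkConfiguration, LandmarkDataset, LandmarkError

#: localities span the study's latitudinal gradient, 16 S to 32 S
LATITUDE_RANGE = (-16.0, -32.0)
LONGITUDE_RANGE = (22.0, 32.0)


# ---------------------------------------------------------------------------
# Mean shapes

def make_mean_shape(k: int, kind: str = "helix", seed: int = 0,
                    structure: str = "cranium") -> LandmarkConfiguration:
    """Deterministic k-landmark template with centroid at origin and unit centroid size.

    ``helix`` places landmarks on a 3D helix (guaranteed distinct and
    non-coplanar); ``grid`` uses a jittered integer grid (jitter drawn
    from `seed`, so the same call always returns the same template).
    """
    if k < 4:
        raise LandmarkError(f"need k >= 4 landmarks, got {k}")
    if kind == "helix":
        t = np.linspace(0.0, 4.0 * np.pi, k)
        coords = np.column_stack([np.cos(t), np.sin(t), t / (2.0 * np.pi)])
    elif kind == "grid":
        rng = np.random.default_rng(seed)
        side = int(np.ceil(k ** (1.0 / 3.0)))
        pts = np.array([(i, j, l) for i in range(side) for j in range(side)
                        for l in range(side)], dtype=float)[:k]
        coords = pts + rng.uniform(-0.2, 0.2, size=(k, 3))
    else:
        raise LandmarkError(f"unknown mean-shape kind {kind!r}")
    coords -= coords.mean(axis=0)
    cs = np.sqrt((coords ** 2).sum())
    coords /= cs
    return LandmarkConfiguration(f"template_{kind}_{k}", structure, coords)


# ---------------------------------------------------------------------------
# Within-group covariance families (on the 3k coordinate scale)

def isotropic_cov(k: int, sigma: float) -> np.ndarray:
    return sigma ** 2 * np.eye(3 * k)


def factor_cov(k: int, sigma: float, loading: float, seed: int = 0) -> np.ndarray:
    """Single common factor plus isotropic noise: Sigma = loading^2 v v' + sigma^2 I."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(3 * k)
    v /= np.linalg.norm(v)
    return loading ** 2 * np.outer(v, v) + sigma ** 2 * np.eye(3 * k)


def modular_cov(k: int, module_a: list[int], sigma: float = 1.0,
                r_within: float = 0.7, r_between: float = 0.0) -> np.ndarray:
    """Two-block landmark covariance with correlations r_within / r_between.

    Same-axis coordinates of two landmarks correlate at r_within when the
    landmarks share a module and r_between otherwise; different axes are
    uncorrelated.  `module_a` holds 1-based landmark indices.
    """
    in_a = np.zeros(k, dtype=bool)
    in_a[np.asarray(module_a) - 1] = True
    same = in_a[:, None] == in_a[None, :]
    corr_lm = np.where(same, r_within, r_between)
    np.fill_diagonal(corr_lm, 1.0)
    cov = np.zeros((3 * k, 3 * k))
    for axis in range(3):
        idx = np.arange(k) * 3 + axis
        cov[np.ix_(idx, idx)] = sigma ** 2 * corr_lm
    _check_psd(cov)
    return cov


def random_psd(p: int, seed: int, condition: float = 20.0, scale: float = 1.0) -> np.ndarray:
    """Random PSD matrix with a smoothly decaying trait-variance spectrum.

    A geometric eigenvalue profile in a uniformly random orthogonal
    eigenbasis drawn from `seed`, scaled so the average per-trait variance
    is `scale`.  The default condition number (20) mimics the
    within-population spectra of inter-landmark distance traits, where a
    95% cumulative-variance cut retains most axes, while keeping adjacent
    eigenvalue gaps large relative to their sampling error at realistic
    sample sizes (a clustered spectrum makes every eigenvalue/eigenvector
    plug-in estimate unstable).
    """
    from scipy.stats import ortho_group

    rng = np.random.default_rng(seed)
    lam = np.geomspace(1.0, 1.0 / condition, p)
    lam *= p * scale / lam.sum()
    q = ortho_group.rvs(p, random_state=rng)
    return (q * lam) @ q.T


def _check_psd(cov: np.ndarray) -> None:
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if eigmin < -1e-8 * max(abs(cov).max(), 1.0):
        raise LandmarkError(f"covariance specification is not PSD (min eigenvalue {eigmin:.3g})")


# ---------------------------------------------------------------------------
# Group-mean divergence

def draw_group_means(cov: np.ndarray, g: int, mode: str, c: float, rng: np.random.Generator,
                     selection_axes: list[int] | None = None,
                     selection_inflation: float = 20.0,
                     stabilizing_shrink: float = 0.1) -> np.ndarray:
    """Draw g group-mean deviations under the requested evolutionary mode.

    drift: N(0, c * cov) — between-group covariance proportional to the
    within covariance.  directional: group means displaced only along the
    listed eigenvectors of `cov` (0-based ranks, largest first), with
    variance c * `selection_inflation` * eigenvalue on those axes and no
    divergence elsewhere — the sharpest break of the proportionality
    B propto W.  stabilizing: neutral draw shrunk toward zero by
    `stabilizing_shrink`.
    """
    if c < 0:
        raise LandmarkError("drift scale c must be >= 0")
    p = cov.shape[0]
    eigval, eigvec = np.linalg.eigh(cov)
    eigval = np.clip(eigval[::-1], 0.0, None)
    eigvec = eigvec[:, ::-1]
    if mode == "drift":
        z = rng.standard_normal((g, p))
        return (z * np.sqrt(c * eigval)) @ eigvec.T
    if mode == "directional":
        axes = list(selection_axes) if selection_axes is not None else [0, 1]
        z = rng.standard_normal((g, len(axes)))
        scales = np.sqrt(c * selection_inflation * eigval[axes])
        return (z * scales) @ eigvec[:, axes].T
    if mode == "stabilizing":
        z = rng.standard_normal((g, p))
        return stabilizing_shrink * (z * np.sqrt(c * eigval)) @ eigvec.T
    raise LandmarkError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Full coordinate-scale simulation

@dataclass
class SimulationConfig:
    """Study-shaped generator settings.

    Defaults mirror the study conditions: a 24-landmark cranium, 4
    locality groups (one lineage) with 5-25 specimens each, within-group
    coordinate noise small relative to the unit-size mean shape, and
    neutral (drift) divergence at scale c.
    """

    k: int = 24
    structure: str = "cranium"
    g: int = 4
    n_per_group: int | list[int] = field(default_factory=lambda: [25, 14, 12, 5])
    mean_shape: str = "helix"
    cov_kind: str = "isotropic"      # isotropic | factor | modular
    sigma: float = 0.01
    factor_loading: float = 0.03
    r_within: float = 0.7
    r_between: float = 0.0
    module_a: list[int] | None = None
    mode: str = "drift"              # drift | directional | stabilizing
    c: float = 0.5
    selection_axes: list[int] | None = None
    selection_inflation: float = 20.0
    stabilizing_shrink: float = 0.1
    allometry_strength: float = 0.0
    measurement_error_sd: float = 0.0
    lineage: str = "sim_lineage"
    seed: int = 0

    def within_cov(self) -> np.ndarray:
        if self.cov_kind == "isotropic":
            return isotropic_cov(self.k, self.sigma)
        if self.cov_kind == "factor":
            return factor_cov(self.k, self.sigma, self.factor_loading, self.seed)
        if self.cov_kind == "modular":
            module_a = self.module_a if self.module_a is not None else list(range(1, self.k // 2 + 1))
            return modular_cov(self.k, module_a, self.sigma, self.r_within, self.r_between)
        raise LandmarkError(f"unknown covariance kind {self.cov_kind!r}")

    def group_sizes(self) -> list[int]:
        if isinstance(self.n_per_group, int):
            return [self.n_per_group] * self.g
        if len(self.n_per_group) != self.g:
            raise LandmarkError(f"{len(self.n_per_group)} group sizes for g={self.g}")
        return list(self.n_per_group)


def simulate_dataset(config: SimulationConfig) -> LandmarkDataset:
    """Generate a landmark dataset (with metadata) under `config`.

    Specimens are the template shape plus a group-mean deviation (drawn
    once per locality from its own seed stream) plus individual
    within-group noise, optionally an allometric deformation proportional
    to log centroid size, and optionally isotropic digitizing error.
    Localities receive synthetic latitude/longitude on the study's 16 S -
    32 S gradient; sex alternates M/F within each locality.
    """
    template = make_mean_shape(config.k, config.mean_shape, seed=config.seed,
                               structure=config.structure)
    cov = config.within_cov()
    _check_psd(cov)
    chol = _psd_sqrt(cov)
    mean_stream, noise_stream, size_stream = (
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(3))

    sizes = config.group_sizes()
    group_dev = draw_group_means(cov, config.g, config.mode, config.c, mean_stream,
                                 config.selection_axes, config.selection_inflation,
                                 config.stabilizing_shrink)
    allo_dir = None
    if config.allometry_strength:
        v = np.random.default_rng(config.seed + 1).standard_normal(3 * config.k)
        allo_dir = v / np.linalg.norm(v)

    lat = np.linspace(*LATITUDE_RANGE, config.g)
    lon = np.linspace(*LONGITUDE_RANGE, config.g)
    configs, meta_rows = [], []
    counter = 0
    for gi in range(config.g):
        locality = f"P{gi + 1}"
        for si in range(sizes[gi]):
            counter += 1
            dev = chol @ noise_stream.standard_normal(3 * config.k)
            flat = template.coords.ravel() + group_dev[gi] + dev
            log_cs = 0.0
            if allo_dir is not None:
                log_cs = size_stream.normal(0.0, 0.1)
                flat = flat + config.allometry_strength * log_cs * allo_dir
            coords = flat.reshape(config.k, 3)
            if allo_dir is not None:
                coords = coords * np.exp(log_cs)
            if config.measurement_error_sd > 0:
                coords = coords + noise_stream.normal(0.0, config.measurement_error_sd,
                                                      size=coords.shape)
            sid = f"{config.lineage}_{locality}_{counter:03d}"
            configs.append(LandmarkConfiguration(sid, config.structure, coords))
            meta_rows.append(dict(specimen_id=sid, lineage=config.lineage,
                                  locality=locality, sex="M" if si % 2 == 0 else "F",
                                  latitude=lat[gi], longitude=lon[gi]))
    return LandmarkDataset(configs, pd.DataFrame(meta_rows))


def _psd_sqrt(cov: np.ndarray) -> np.ndarray:
    eigval, eigvec = np.linalg.eigh(cov)
    return eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None))) @ eigvec.T


# ---------------------------------------------------------------------------
# Distance-scale simulation (exact β-test calibration)

def simulate_distance_data(within_cov: np.ndarray, g: int, n_per_group: int,
                           mode: str = "drift", c: float = 0.5,
                           seed: int | np.random.Generator = 0,
                           selection_axes: list[int] | None = None,
                           selection_inflation: float = 20.0,
                           stabilizing_shrink: float = 0.1,
                           baseline: float = 10.0,
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate distance traits directly: D ~ N(baseline + mu_g, within_cov).

    Returns ``(distances, locality, sex)`` with shapes (g*n, p), (g*n,),
    (g*n,).  Group means are drawn with covariance c * within_cov in
    drift mode, so B is proportional to W at the population level by
    construction.
    """
    cov = np.asarray(within_cov, dtype=float)
    p = cov.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_rng = np.random.default_rng(rng.integers(2 ** 31))
    noise_rng = np.random.default_rng(rng.integers(2 ** 31))
    mu = draw_group_means(cov, g, mode, c, mean_rng, selection_axes,
                          selection_inflation, stabilizing_shrink)
    chol = _psd_sqrt(cov)
    d = np.vstack([
        baseline + mu[gi] + (chol @ noise_rng.standard_normal((p, n_per_group))).T
        for gi in range(g)
    ])
    locality = np.repeat([f"P{gi + 1}" for gi in range(g)], n_per_group)
    sex = np.tile(["M", "F"], (g * n_per_group + 1) // 2)[: g * n_per_group]
    return d, locality, sex


# ---------------------------------------------------------------------------
# Replicate digitizing error

def add_measurement_error(config: LandmarkConfiguration, sd: float | np.ndarray,
                          r: int, seed: int) -> LandmarkDataset:
    """r replicate digitizations of one specimen with per-landmark isotropic jitter."""
    if r < 2:
        raise LandmarkError(f"need r >= 2 replicates, got {r}")
    sd_vec = np.broadcast_to(np.asarray(sd, dtype=float), (config.k,))
    if np.any(sd_vec < 0):
        raise LandmarkError("jitter sd must be >= 0")
    rng = np.random.default_rng(seed)
    configs = []
    for i in range(r):
        jitter = rng.standard_normal((config.k, 3)) * sd_vec[:, None]
        configs.append(LandmarkConfiguration(
            f"{config.specimen_id}_rep{i + 1}", config.structure,
            config.coords + jitter, list(config.landmark_labels)))
    return LandmarkDataset(configs)
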