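"""Landmark repeatability analysis and the discard rule.

A voucher specimen digitized r times (typically 10) yields, per landmark,
a dispersion s.d., a standard error of the mean S.E. = s.d./sqrt(r), and a
coefficient of variation CV.  Because a 3D landmark has no natural scalar
mean, CV is defined here as the RMS dispersion of the replicate positions
divided by the landmark's mean distance from the configuration centroid —
a dimensionless noise-to-signal measure that ranks landmarks on a common
scale.  Replicates are superimposed without scaling (they are the same
physical object), so all dispersion statistics stay in input length units.

The discard rule then screens each landmark against the biological signal:
for every unordered pair of locality groups, the Euclidean norm of the
difference in group-mean landmark position is compared with that
landmark's S.E.; a landmark with more sub-S.E. pairs than the threshold
(default: strictly more than half of all pairs) carries mostly measurement
noise and is dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .align import gpa
from .datatypes import LandmarkDataset, LandmarkError


@dataclass
class PrecisionReport:
    """Per-landmark repeatability statistics.

    `table` columns: landmark_index (1-based), label, mean_x/y/z, sd, se,
    cv, rank and — after :func:`apply_discard_rule` — incidents and keep.
    """

    table: pd.DataFrame
    n_replicates: int
    n_pairs: int | None = None
    threshold: int | None = None

    @property
    def ranked_indices(self) -> np.ndarray:
        """Landmark indices ordered from most to least precise."""
        return self.table.sort_values("rank")["landmark_index"].to_numpy()

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def replicate_precision(replicates: LandmarkDataset) -> PrecisionReport:
    """Repeatability statistics from one specimen digitized r >= 2 times.

    Replicates are superimposed by GPA without scaling; for each landmark
    the dispersion s.d. is the root-mean-square deviation of replicate
    positions about the landmark's mean (denominator r - 1), S.E. is
    s.d./sqrt(r), and CV is s.d. over the mean distance of the landmark
    from the configuration centroid.  Landmarks are ranked ascending by
    (CV, S.E., index): rank 1 is the most precise.
    """
    r = replicates.n
    if r < 2:
        raise LandmarkError(f"need at least 2 replicates, got {r}")
    aligned = gpa(replicates, scale=False)
    coords = aligned.shape_coords  # (r, k, 3), centered at origin
    mean_pos = coords.mean(axis=0)  # (k, 3)
    dev = coords - mean_pos
    sd = np.sqrt((dev ** 2).sum(axis=(0, 2)) / (r - 1))
    # superimposition round-off on identical replicates is not dispersion
    sd[sd < 1e-12 * max(float(np.linalg.norm(mean_pos)), 1e-300)] = 0.0
    se = sd / np.sqrt(r)
    # aligned configurations are centered, so |position| = distance to centroid
    mean_radius = np.linalg.norm(coords, axis=2).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean_radius > 0, sd / np.where(mean_radius > 0, mean_radius, 1.0), 0.0)
    if np.any(mean_radius == 0):
        warnings.warn("landmark at configuration centroid: CV reported as 0", stacklevel=2)

    k = replicates.k
    order = np.lexsort((np.arange(k), se, cv))
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(1, k + 1)
    table = pd.DataFrame({
        "landmark_index": np.arange(1, k + 1),
        "label": replicates.landmark_labels,
        "mean_x": mean_pos[:, 0], "mean_y": mean_pos[:, 1], "mean_z": mean_pos[:, 2],
        "sd": sd, "se": se, "cv": cv, "rank": rank,
    })
    return PrecisionReport(table=table, n_replicates=r)


def count_incidents(report: PrecisionReport, dataset: LandmarkDataset,
                    grouping: str = "locality") -> np.ndarray:
    """Per-landmark count of locality pairs whose group-mean difference is below S.E.

    The dataset is superimposed by GPA without scaling (matching the units
    of the replicate S.E.), group-mean landmark positions are computed per
    level of `grouping`, and for each unordered pair of groups the
    Euclidean norm of the mean difference is compared with the landmark's
    S.E.
    """
    groups = np.asarray(dataset.metadata_column(grouping))
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise LandmarkError(f"grouping {grouping!r} needs >= 2 levels, got {len(levels)}")
    if len(report.table) != dataset.k:
        raise LandmarkError(
            f"precision report covers {len(report.table)} landmarks, dataset has {dataset.k}"
        )
    aligned = gpa(dataset, scale=False)
    se = report.table["se"].to_numpy()
    group_means = {lev: aligned.shape_coords[groups == lev].mean(axis=0) for lev in levels}
    incidents = np.zeros(dataset.k, dtype=int)
    for a, b in combinations(sorted(levels), 2):
        diff = np.linalg.norm(group_means[a] - group_means[b], axis=1)  # (k,)
        incidents += (diff < se).astype(int)
    return incidents


def apply_discard_rule(report: PrecisionReport, dataset: LandmarkDataset,
                       grouping: str = "locality",
                       threshold: int | None = None) -> tuple[PrecisionReport, LandmarkDataset]:
    """Flag unreliable landmarks and return the filtered dataset.

    A landmark is discarded when its incident count (see
    :func:`count_incidents`) is strictly greater than `threshold`
    (default: half of all group pairs, the majority rule).  Original
    1-based landmark indices are preserved in the filtered dataset's
    labels.
    """
    incidents = count_incidents(report, dataset, grouping)
    groups = pd.unique(np.asarray(dataset.metadata_column(grouping)))
    n_pairs = len(groups) * (len(groups) - 1) // 2
    if threshold is None:
        threshold = n_pairs // 2
    keep = incidents <= threshold
    if not keep.any():
        raise LandmarkError(
            "all landmarks discarded by the precision rule; inspect measurement error"
        )
    table = report.table.copy()
    table["incidents"] = incidents
    table["keep"] = keep
    out_report = PrecisionReport(table=table, n_replicates=report.n_replicates,
                                 n_pairs=n_pairs, threshold=threshold)
    filtered = dataset.subset_landmarks(keep)
    return out_report, filtered
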