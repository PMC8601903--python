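"""Core containers for 3D landmark data.

A *landmark configuration* is the set of k homologous points digitized on
one specimen, stored as a k x 3 coordinate matrix in the input length
units.  A *dataset* bundles the configurations of one skeletal structure
(all sharing landmark count and order) with a specimen metadata table
(lineage, locality, sex, latitude, longitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRUCTURES = ("cranium", "mandible")
SEXES = ("M", "F", "unknown")

METADATA_COLUMNS = ["specimen_id", "lineage", "locality", "sex", "latitude", "longitude"]


class LandmarkError(ValueError):
    """Raised for malformed landmark data or metadata."""


@dataclass
class LandmarkConfiguration:
    """One specimen's k x 3 landmark coordinates.

    Parameters
    ----------
    specimen_id : str
        Unique identifier of the specimen (voucher / museum number).
    structure : str
        Skeletal structure, ``"cranium"`` or ``"mandible"``.
    coords : (k, 3) ndarray
        Raw landmark coordinates in input length units.
    landmark_labels : list of str, optional
        Ordered landmark labels; defaults to ``"L1" .. "Lk"`` (1-based,
        matching field convention for naming landmarks).
    """

    specimen_id: str
    structure: str
    coords: np.ndarray
    landmark_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise LandmarkError(
                f"{self.specimen_id}: coordinates must be k x 3, got {self.coords.shape}"
            )
        if self.structure not in STRUCTURES:
            raise LandmarkError(f"unknown structure {self.structure!r}")
        if self.k < 4:
            raise LandmarkError(f"{self.specimen_id}: need at least 4 landmarks, got {self.k}")
        if not np.all(np.isfinite(self.coords)):
            raise LandmarkError(f"{self.specimen_id}: non-finite coordinate")
        if not self.landmark_labels:
            self.landmark_labels = [f"L{i}" for i in range(1, self.k + 1)]
        if len(self.landmark_labels) != self.k:
            raise LandmarkError(f"{self.specimen_id}: {len(self.landmark_labels)} labels for {self.k} landmarks")
        if len(set(self.landmark_labels)) != self.k:
            raise LandmarkError(f"{self.specimen_id}: duplicated landmark labels")

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass
class LandmarkDataset:
    """Configurations of one structure plus the specimen metadata table.

    All configurations share the landmark count and landmark order; the
    metadata table (if attached) has exactly one row per specimen with
    columns ``specimen_id, lineage, locality, sex, latitude, longitude``.
    """

    configurations: list[LandmarkConfiguration]
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.configurations:
            raise LandmarkError("no specimens found")
        k0 = self.configurations[0].k
        labels0 = self.configurations[0].landmark_labels
        struct0 = self.configurations[0].structure
        for c in self.configurations:
            if c.k != k0:
                raise LandmarkError(
                    f"ragged landmark counts: specimen {c.specimen_id!r} has {c.k}, expected {k0}"
                )
            if c.landmark_labels != labels0:
                raise LandmarkError(f"specimen {c.specimen_id!r} has a different landmark order")
            if c.structure != struct0:
                raise LandmarkError(f"specimen {c.specimen_id!r} has structure {c.structure!r}, expected {struct0!r}")
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            raise LandmarkError("duplicate specimen ids")
        if self.metadata is not None:
            self.metadata = _validate_metadata(self.metadata, ids)

    # -- convenience views -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def k(self) -> int:
        return self.configurations[0].k

    @property
    def structure(self) -> str:
        return self.configurations[0].structure

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def landmark_labels(self) -> list[str]:
        return self.configurations[0].landmark_labels

    def coords_array(self) -> np.ndarray:
        """Stack coordinates into an (n, k, 3) array (specimen order preserved)."""
        return np.stack([c.coords for c in self.configurations])

    def metadata_column(self, name: str) -> np.ndarray:
        """Metadata column aligned to specimen order."""
        if self.metadata is None:
            raise LandmarkError("dataset has no metadata attached")
        table = self.metadata.set_index("specimen_id")
        return table.loc[self.specimen_ids, name].to_numpy()

    def subset_landmarks(self, keep: np.ndarray) -> "LandmarkDataset":
        """New dataset restricted to the landmarks flagged in boolean mask `keep`."""
        keep = np.asarray(keep, dtype=bool)
        labels = [lab for lab, k in zip(self.landmark_labels, keep) if k]
        configs = [
            LandmarkConfiguration(c.specimen_id, c.structure, c.coords[keep], list(labels))
            for c in self.configurations
        ]
        return LandmarkDataset(configs, self.metadata)


def _validate_metadata(metadata: pd.DataFrame, ids: list[str]) -> pd.DataFrame:
    missing_cols = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing_cols:
        raise LandmarkError(f"metadata missing required columns: {missing_cols}")
    dup = metadata["specimen_id"][metadata["specimen_id"].duplicated()]
    if len(dup):
        raise LandmarkError(f"duplicate metadata rows for specimens: {sorted(set(dup))}")
    known = set(metadata["specimen_id"])
    unmatched = [i for i in ids if i not in known]
    if unmatched:
        raise LandmarkError(f"specimens missing from metadata: {unmatched}")
    bad_sex = set(metadata["sex"]) - set(SEXES)
    if bad_sex:
        raise LandmarkError(f"unknown sex codes: {sorted(bad_sex)} (expected {SEXES})")
    return metadata.reset_index(drop=True)
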