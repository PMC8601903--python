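"""Read and write landmark datasets and specimen metadata.

Two on-disk formats are supported:

* **TPS** with 3D blocks: ``LM3=<k>`` followed by k whitespace-separated
  ``x y z`` lines, an ``ID=<specimen>`` line, and an optional ``SCALE=``
  line (applied multiplicatively).  2D files (``LM=``) are rejected rather
  than zero-padded, so dimensional mistakes surface immediately.
* **Long CSV** with one row per landmark and columns
  ``specimen_id, structure, landmark_index, x, y, z`` (landmark_index is
  1-based).  This dialect is unambiguous for 3D data and diffs cleanly.

Metadata lives in a separate CSV with columns
``specimen_id, lineage, locality, sex, latitude, longitude``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import LandmarkConfiguration, LandmarkDataset, LandmarkError

CSV_COLUMNS = ["specimen_id", "structure", "landmark_index", "x", "y", "z"]


def read_landmarks(path: str | Path, format: str | None = None,
                   structure: str = "cranium") -> LandmarkDataset:
    """Read a landmark file into a :class:`LandmarkDataset`.

    Parameters
    ----------
    path : path
        Input file.
    format : {"tps", "csv"}, optional
        Inferred from the file suffix when omitted.
    structure : str
        Structure assigned to TPS specimens (the CSV dialect carries its
        own ``structure`` column and ignores this argument).
    """
    path = Path(path)
    if format is None:
        format = "tps" if path.suffix.lower() == ".tps" else "csv"
    if format == "tps":
        return _read_tps(path, structure)
    if format == "csv":
        return _read_csv(path)
    raise LandmarkError(f"unknown landmark format {format!r}")


def write_landmarks(dataset: LandmarkDataset, path: str | Path,
                    format: str | None = None, aligned: bool = False) -> None:
    """Write a dataset; round-trips bit-exactly through :func:`read_landmarks`."""
    path = Path(path)
    if format is None:
        format = "tps" if path.suffix.lower() == ".tps" else "csv"
    if format == "tps":
        _write_tps(dataset, path)
    elif format == "csv":
        _write_csv(dataset, path, aligned=aligned)
    else:
        raise LandmarkError(f"unknown landmark format {format!r}")


def attach_metadata(dataset: LandmarkDataset, metadata_path: str | Path) -> LandmarkDataset:
    """Link a metadata CSV to every configuration of `dataset`.

    Raises :class:`LandmarkError` listing specimen ids present in the
    coordinates but absent from the metadata, and on duplicated rows.
    """
    metadata = read_metadata(metadata_path)
    return LandmarkDataset(dataset.configurations, metadata)


def read_metadata(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"specimen_id": str, "lineage": str,
                                     "locality": str, "sex": str})
    return table


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CSV dialect

def _read_csv(path: Path) -> LandmarkDataset:
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    if not any(ln.strip() for ln in lines[1:] if ln.strip()):
        raise LandmarkError(f"{path}: no specimens found")
    try:
        table = pd.read_csv(_io.StringIO("\n".join(lines)), float_precision="round_trip",
                            dtype={"specimen_id": str, "structure": str})
    except pd.errors.EmptyDataError:
        raise LandmarkError(f"{path}: no specimens found") from None
    missing = [c for c in CSV_COLUMNS if c not in table.columns]
    if missing:
        raise LandmarkError(f"{path}: missing columns {missing}")
    for col in ("x", "y", "z"):
        bad = pd.to_numeric(table[col], errors="coerce").isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise LandmarkError(
                f"{path}: non-numeric {col} value {table[col].iloc[row]!r} on data line {row + 1}"
            )
        table[col] = pd.to_numeric(table[col])
    if table.empty:
        raise LandmarkError(f"{path}: no specimens found")

    configs = []
    # groupby(sort=False) preserves first-appearance specimen order
    for sid, block in table.groupby("specimen_id", sort=False):
        idx = block["landmark_index"].to_numpy()
        order = np.argsort(idx, kind="stable")
        block = block.iloc[order]
        k = len(block)
        expected = np.arange(1, k + 1)
        if not np.array_equal(block["landmark_index"].to_numpy(), expected):
            raise LandmarkError(
                f"{path}: specimen {sid!r} has landmark indices "
                f"{sorted(idx.tolist())}, expected 1..{k} without gaps"
            )
        coords = block[["x", "y", "z"]].to_numpy(dtype=float)
        configs.append(LandmarkConfiguration(str(sid), str(block["structure"].iloc[0]), coords))
    return LandmarkDataset(configs)


def _write_csv(dataset: LandmarkDataset, path: Path, aligned: bool = False) -> None:
    rows = []
    for c in dataset.configurations:
        for j in range(c.k):
            rows.append((c.specimen_id, c.structure, j + 1,
                         repr(float(c.coords[j, 0])), repr(float(c.coords[j, 1])),
                         repr(float(c.coords[j, 2]))))
    header = "# aligned=true\n" if aligned else ""
    body = ",".join(CSV_COLUMNS) + "\n" + "\n".join(",".join(map(str, r)) for r in rows) + "\n"
    Path(path).write_text(header + body)


# ---------------------------------------------------------------------------
# TPS

def _read_tps(path: Path, structure: str) -> LandmarkDataset:
    configs = []
    lines = Path(path).read_text().splitlines()
    i, n_lines = 0, len(lines)
    counter = 0
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            raise LandmarkError(
                f"{path}: 2D TPS block (LM=) at line {i + 1}; only 3D (LM3=) files are supported"
            )
        if not upper.startswith("LM3="):
            raise LandmarkError(f"{path}: expected LM3= at line {i + 1}, got {line!r}")
        k = int(line.split("=", 1)[1])
        coords = np.empty((k, 3))
        for j in range(k):
            i += 1
            parts = lines[i].split()
            if len(parts) != 3:
                raise LandmarkError(f"{path}: line {i + 1}: expected 3 coordinates, got {len(parts)}")
            try:
                coords[j] = [float(p) for p in parts]
            except ValueError:
                raise LandmarkError(f"{path}: non-numeric coordinate at line {i + 1}") from None
        counter += 1
        specimen_id = f"specimen_{counter}"
        scale = None
        i += 1
        while i < n_lines and "=" in lines[i] and not lines[i].strip().upper().startswith("LM3="):
            key, _, value = lines[i].strip().partition("=")
            key = key.strip().upper()
            if key == "ID":
                specimen_id = value.strip()
            elif key == "SCALE":
                scale = float(value)
            i += 1
        if scale is not None:
            coords = coords * scale
        configs.append(LandmarkConfiguration(specimen_id, structure, coords))
    if not configs:
        raise LandmarkError(f"{path}: no specimens found")
    return LandmarkDataset(configs)


def _write_tps(dataset: LandmarkDataset, path: Path) -> None:
    out = []
    for c in dataset.configurations:
        out.append(f"LM3={c.k}")
        for j in range(c.k):
            out.append(f"{float(c.coords[j, 0])!r} {float(c.coords[j, 1])!r} "
                       f"{float(c.coords[j, 2])!r}")
        out.append(f"ID={c.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")
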