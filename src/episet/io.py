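"""Readers and writers for label images, parameter tables and run metadata.

The minimal input is a fully-confluent label image: a single-channel integer
raster (TIFF or PNG) in which every pixel carries the label of its cell.
Labels are relabeled to contiguous 1..K on read, with the original mapping
preserved.  Per-cell AMAT parameters travel as a CSV with the header
``cell_id,mu1,mu2,alpha,s1,s2,a1,a2,p,is_border,mode``.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CellShapeParams

__all__ = [
    "read_label_image",
    "write_label_image",
    "params_to_frame",
    "frame_to_params",
    "write_params_csv",
    "read_params_csv",
    "read_classes_csv",
    "read_organelles_csv",
    "write_provenance",
]

PARAMS_COLUMNS = [
    "cell_id", "mu1", "mu2", "alpha", "s1", "s2", "a1", "a2", "p",
    "is_border", "mode",
]


def _load_raster(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


def read_label_image(path) -> tuple[np.ndarray, dict[int, int]]:
    """Read and validate a confluent label image.

    Returns ``(labels, mapping)`` with labels relabeled to 1..K and
    ``mapping`` original -> new.  Rejects float or multi-channel rasters and
    any zero-labeled pixel (the method requires 100% confluence; crop the
    image to a fully covered region instead).
    """
    path = Path(path)
    arr = _load_raster(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel label image, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: label image must be integer-typed, got {arr.dtype}")
    if np.any(arr == 0):
        raise ValueError(
            f"{path}: zero-labeled pixels found; the tessellation model requires "
            "every pixel to belong to a cell (full confluence)"
        )
    old = np.unique(arr)
    mapping = {int(o): i + 1 for i, o in enumerate(old)}
    lut = np.zeros(int(old.max()) + 1, dtype=np.int32)
    lut[old] = np.arange(1, len(old) + 1)
    return lut[arr], mapping


def write_label_image(path, labels: np.ndarray) -> None:
    path = Path(path)
    k = int(labels.max())
    dtype = np.uint16 if k <= np.iinfo(np.uint16).max else np.int32
    arr = labels.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


def params_to_frame(params: list[CellShapeParams]) -> pd.DataFrame:
    rows = [{c: getattr(p, c) for c in PARAMS_COLUMNS} for p in params]
    return pd.DataFrame(rows, columns=PARAMS_COLUMNS)


def frame_to_params(df: pd.DataFrame) -> list[CellShapeParams]:
    out = []
    for _, r in df.iterrows():
        out.append(
            CellShapeParams(
                cell_id=int(r.cell_id), mu1=float(r.mu1), mu2=float(r.mu2),
                alpha=float(r.alpha), s1=float(r.s1), s2=float(r.s2),
                a1=float(r.a1), a2=float(r.a2), p=float(r.p),
                is_border=bool(r.is_border), mode=str(r["mode"]),
            )
        )
    return out


def write_params_csv(path, params: list[CellShapeParams]) -> None:
    params_to_frame(params).to_csv(path, index=False, float_format="%.17g")


def read_params_csv(path) -> list[CellShapeParams]:
    return frame_to_params(pd.read_csv(path))


def read_classes_csv(path) -> dict[int, str]:
    df = pd.read_csv(path)
    return {int(r.cell_id): str(r["class"]) for _, r in df.iterrows()}


def read_organelles_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"cell_id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"organelles CSV missing columns {sorted(missing)}")
    return df


def write_provenance(path, config: dict, seeds) -> None:
    """Machine-readable record of a run: package/platform versions, seeds,
    and a hash of the configuration."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    rec = {
        "episet_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seeds": list(np.asarray(seeds).tolist()) if np.ndim(seeds) else [int(seeds)],
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    Path(path).write_text(json.dumps(rec, indent=2, default=str))
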