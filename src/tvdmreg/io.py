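"""File formats: TIFF and HDF5 images/stacks, YAML config, run reports.

All internal math is 64-bit float; files are written as 32-bit float TIFF
(or float HDF5 datasets), which round-trips bit-exactly for 32-bit data.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .imagemath import Image2D
from .search import SearchConfig

DEFAULT_H5_DATASET = "images"


def read_image(path: str | Path) -> Image2D:
    """Read a single grayscale image (first page of a TIFF)."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        arr = arr[0]
    return Image2D(np.asarray(arr, dtype=np.float64))


def write_image(path: str | Path, img: Image2D) -> None:
    tifffile.imwrite(str(path), img.pixels.astype(np.float32),
                     photometric="minisblack")


def read_stack(path: str | Path, dataset: str = DEFAULT_H5_DATASET) -> list[Image2D]:
    """Read an image series from a multi-page TIFF or an HDF5 [n, H, W] dataset."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5", ".hdf"):
        with h5py.File(path, "r") as fh:
            if dataset not in fh:
                raise KeyError(f"dataset {dataset!r} not found in {path}")
            arr = np.asarray(fh[dataset], dtype=np.float64)
    else:
        arr = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a [n, H, W] stack, got shape {arr.shape}")
    return [Image2D(frame) for frame in arr]


def write_stack(
    path: str | Path, images: list[Image2D], dataset: str = DEFAULT_H5_DATASET
) -> None:
    """Write a series as multi-page TIFF or HDF5, chosen by extension."""
    path = Path(path)
    arr = np.stack([img.pixels for img in images]).astype(np.float32)
    if path.suffix.lower() in (".h5", ".hdf5", ".hdf"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset(dataset, data=arr)
    else:
        tifffile.imwrite(str(path), arr, photometric="minisblack")


def load_config(path: str | Path | None) -> SearchConfig:
    """Load a SearchConfig from a YAML (or flat key: value) file.

    Keys mirror the SearchConfig field names exactly; unknown keys are
    errors, not warnings.
    """
    if path is None:
        return SearchConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return SearchConfig.from_dict(data)


def config_to_dict(cfg: SearchConfig) -> dict:
    return {
        name: (list(val) if isinstance(val, tuple) else val)
        for name, val in cfg.__dict__.items()
    }


def write_run_report(
    path: str | Path,
    cfg: SearchConfig,
    results: list[dict],
    extra: dict | None = None,
) -> None:
    """JSON run report: config echo, per-pair results, timing, versions.

    ``results`` entries typically carry the estimated transform, the TV of
    the difference map before/after alignment, iteration counts and, when
    ground truth is known, the recovery errors.
    """
    import tvdmreg

    report = {
        "package_version": tvdmreg.__version__,
        "numpy_version": np.__version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config_to_dict(cfg),
        "results": results,
    }
    if extra:
        report.update(extra)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
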