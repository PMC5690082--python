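"""Readers and writers for images, volumes, seed files and manifests.

2D grayscale images travel as PNG (integer label maps) or TIFF (float
maps); 3D volumes as NIfTI (.nii / .nii.gz).  Seeds are accepted as CSV
or JSON coordinate lists (0-based ``(row, col[, slice])`` voxel indices
with an integer ``label_id`` >= 1) or as an integer label-map image
where 0 means unlabeled.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .solver import SeedLabeling

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_LUMA = (0.2125, 0.7154, 0.0721)


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def read_image(path) -> np.ndarray:
    """Read a 2D image (PNG/TIFF) or 3D volume (NIfTI) as stored.

    Intensities are returned unscaled; RGB input collapses to luminance
    with a warning.  Singleton NIfTI axes are squeezed, so a one-slice
    volume comes back 2D.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        data = np.asarray(nib.load(str(path)).get_fdata())
        data = np.squeeze(data)
        if data.ndim not in (2, 3):
            raise ValueError(f"{path}: expected a 2D/3D volume, "
                             f"got shape {data.shape}")
        return data
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        warnings.warn(f"{path.name}: RGB(A) input converted to luminance",
                      stacklevel=2)
        arr = (arr[..., :3].astype(float) * _LUMA).sum(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D grayscale image, "
                         f"got shape {arr.shape}")
    return np.asarray(arr)


def write_image(path, array) -> None:
    """Write an image/volume, choosing the codec from the extension.

    PNG for 2D integer data (label maps, bit-exact up to 16 bits), TIFF
    for 2D float maps, NIfTI for anything 3D.
    """
    path = Path(path)
    arr = np.asarray(array)
    if _is_nifti(path):
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64
                                         if arr.dtype.kind == "f"
                                         else np.int32), np.eye(4))
        nib.save(img, str(path))
        return
    suffix = path.suffix.lower()
    if suffix == ".png":
        if arr.dtype.kind not in "ui":
            raise ValueError("PNG output requires integer data; "
                             "use TIFF for float maps")
        dtype = np.uint8 if arr.max() <= 255 else np.uint16
        iio.imwrite(path, arr.astype(dtype))
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        raise ValueError(f"unsupported output format {suffix!r}")


def _seed_columns(ndim: int) -> list:
    return ["row", "col", "slice"][:ndim]


def read_seeds(path, shape) -> SeedLabeling:
    """Read seeds from CSV/JSON coordinate lists or a label-map image."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        table = pd.read_csv(path)
        cols = _seed_columns(len(shape))
        missing = [c for c in ["label_id", *cols] if c not in table.columns]
        if missing:
            raise ValueError(f"{path}: missing seed columns {missing}")
        return SeedLabeling.from_points(
            shape, table["label_id"].to_numpy(),
            table[cols].to_numpy(dtype=int))
    if suffix == ".json":
        records = json.loads(path.read_text())
        if isinstance(records, dict):
            records = records["seeds"]
        labels = [r["label_id"] for r in records]
        coords = [r["coordinates"] for r in records]
        return SeedLabeling.from_points(shape, labels, coords)
    label_map = read_image(path)
    if label_map.shape != tuple(shape):
        raise ValueError(
            f"seed label map shape {label_map.shape} does not match the "
            f"image grid {tuple(shape)}"
        )
    return SeedLabeling(np.rint(label_map).astype(np.int32))


def write_seeds(path, seeds: SeedLabeling) -> None:
    """Write seeds as a CSV coordinate list (label_id, row, col[, slice])."""
    coords = np.argwhere(seeds.label_map > 0)
    labels = seeds.label_map[tuple(coords.T)]
    table = pd.DataFrame(coords, columns=_seed_columns(len(seeds.shape)))
    table.insert(0, "label_id", labels)
    table.to_csv(path, index=False)


def write_manifest(path, parameters: dict) -> None:
    """Write the run parameters as a JSON manifest next to the outputs."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(json.dumps(parameters, indent=2, default=_default)
                          + "\n")
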