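"""Segmentation quality metrics and the target homogeneity classifier.

Given a ground-truth region A and a computed region B (boolean masks on
the same grid):

* Dice coefficient  DC = 2|A∩B| / (|A| + |B|), 1 = perfect overlap;
* percent error     PE = (|A∪B| - |A∩B|) / |A|, 0 = perfect;
* Hausdorff distance HD = max(h(∂A, ∂B), h(∂B, ∂A)) with the directed
  distance h(X, Y) = max_x min_y ||x - y||, in voxel units unless a
  physical spacing is supplied.

A target is classified homogeneous when the standard deviation of its
min-max-normalized intensities falls below a threshold (default 0.1).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import directed_hausdorff

HOMOGENEITY_SD_THRESHOLD = 0.1


def _as_mask_pair(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"masks are on different grids: {a.shape} vs {b.shape}")
    return a, b


def dice(a, b) -> float:
    """Dice overlap coefficient in [0, 1]; two empty masks count as 1."""
    a, b = _as_mask_pair(a, b)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def percent_error(a, b) -> float:
    """Symmetric-difference error relative to the ground truth |A|."""
    a, b = _as_mask_pair(a, b)
    n_a = int(a.sum())
    if n_a == 0:
        raise ValueError("percent error is undefined for an empty ground truth")
    union = int((a | b).sum())
    inter = int((a & b).sum())
    return (union - inter) / n_a


def extract_boundary(mask, connectivity: int | None = None) -> np.ndarray:
    """Region voxels with a face neighbor outside (or on the image border).

    Returns an (P, ndim) array of integer voxel coordinates.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("empty region has no boundary", stacklevel=2)
        return np.empty((0, mask.ndim), dtype=int)
    structure = ndi.generate_binary_structure(mask.ndim, 1)
    interior = ndi.binary_erosion(mask, structure=structure, border_value=0)
    return np.argwhere(mask & ~interior)


def hausdorff(a_points, b_points, spacing=None) -> float:
    """Symmetric Hausdorff distance between two boundary point sets.

    Points are (P, ndim) voxel coordinates; with ``spacing`` given the
    coordinates are scaled per axis and the result is in physical units.
    """
    a = np.atleast_2d(np.asarray(a_points, dtype=float))
    b = np.atleast_2d(np.asarray(b_points, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("Hausdorff distance requires two nonempty point sets")
    if spacing is not None:
        spacing = np.asarray(spacing, dtype=float)
        a = a * spacing
        b = b * spacing
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


def classify_homogeneity(image, target, threshold: float = HOMOGENEITY_SD_THRESHOLD
                         ) -> tuple[str, float]:
    """Classify a target region by the spread of its own intensities.

    The target's voxel intensities are min-max normalized over the target
    itself; the population standard deviation is compared against
    ``threshold`` (strictly below means homogeneous).  Returns
    ``(category, sd)``.
    """
    image = np.asarray(image, dtype=float)
    target = np.asarray(target, dtype=bool)
    if image.shape != target.shape:
        raise ValueError("image and target mask are on different grids")
    values = image[target]
    if values.size == 0:
        raise ValueError("homogeneity is undefined for an empty target")
    lo, hi = values.min(), values.max()
    if hi == lo:
        sd = 0.0
    else:
        sd = float(np.std((values - lo) / (hi - lo)))
    return ("homogeneous" if sd < threshold else "inhomogeneous", sd)
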