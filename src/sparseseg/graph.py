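"""Lattice graph construction for random-walker segmentation.

An image is treated as a weighted graph: voxels are vertices and
face-adjacent voxel pairs are edges (4-connectivity in 2D, 6-connectivity
in 3D).  Each edge carries the exponential intensity affinity

    w_ij = exp(-beta * (I_i - I_j)**2)

where ``beta`` is the single free parameter of the walker model:  large
``beta`` makes intensity steps act as barriers, small ``beta`` makes the
walk purely geometric.  Intensities are expected on the [0, 1] scale so
that a given ``beta`` means the same thing across modalities; use
:func:`normalize_intensities` first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import prod

import numpy as np
from scipy import sparse

#: Lower clamp on edge weights.  Keeps the lattice connected and the
#: Dirichlet system nonsingular when exp(-beta * dI^2) underflows.
DEFAULT_WEIGHT_FLOOR = 1e-6


def _as_image(image) -> np.ndarray:
    a = np.asarray(image, dtype=float)
    if a.ndim not in (2, 3):
        raise ValueError(f"expected a 2D or 3D image, got ndim={a.ndim}")
    if a.size < 2:
        raise ValueError("image must contain at least 2 voxels")
    if not np.all(np.isfinite(a)):
        raise ValueError("image intensities must be finite")
    return a


def connectivity_for_shape(shape) -> int:
    """Face connectivity matching the dimensionality: 4 for 2D, 6 for 3D."""
    ndim = len(shape)
    if ndim == 2:
        return 4
    if ndim == 3:
        return 6
    raise ValueError(f"unsupported dimensionality {ndim}")


def normalize_intensities(image) -> np.ndarray:
    """Affinely map intensities onto [0, 1].

    A constant image has no contrast to preserve; it maps to all zeros
    and a warning is emitted.
    """
    a = _as_image(image)
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        warnings.warn(
            "constant image: degenerate contrast, normalizing to all zeros",
            stacklevel=2,
        )
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def lattice_edges(shape) -> np.ndarray:
    """All face-adjacent voxel pairs as flat (row-major) index pairs.

    Returns an (E, 2) int array; each unordered edge appears exactly once.
    """
    idx = np.arange(prod(shape)).reshape(shape)
    pairs = []
    for ax in range(len(shape)):
        if shape[ax] < 2:
            continue
        a = np.take(idx, np.arange(shape[ax] - 1), axis=ax).ravel()
        b = np.take(idx, np.arange(1, shape[ax]), axis=ax).ravel()
        pairs.append(np.stack([a, b], axis=1))
    return np.concatenate(pairs, axis=0)


def expected_edge_count(shape) -> int:
    """Closed-form number of lattice edges (e.g. r(c-1) + c(r-1) in 2D)."""
    total = 0
    for ax, extent in enumerate(shape):
        others = prod(shape) // extent
        total += (extent - 1) * others
    return total


@dataclass(frozen=True)
class GraphWeights:
    """Weighted face-adjacency lattice over an image grid.

    ``edges`` are flat voxel index pairs (row-major over the image shape);
    ``weights`` are the symmetric affinities in (0, 1], already clamped at
    ``epsilon_floor``.
    """

    shape: tuple
    connectivity: int
    edges: np.ndarray
    weights: np.ndarray
    beta: float
    epsilon_floor: float = DEFAULT_WEIGHT_FLOOR

    @property
    def n_vertices(self) -> int:
        return prod(self.shape)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


def build_graph(image, beta: float, connectivity: int | None = None,
                epsilon_floor: float = DEFAULT_WEIGHT_FLOOR) -> GraphWeights:
    """Build the weighted lattice graph of a [0, 1]-normalized image.

    Parameters
    ----------
    image : 2D or 3D array with values in [0, 1]
    beta : positive scalar; the edge-weight sharpness.
    connectivity : 4 (2D) or 6 (3D); inferred from dimensionality when None.
    epsilon_floor : lower clamp on weights.
    """
    a = _as_image(image)
    if a.min() < -1e-9 or a.max() > 1 + 1e-9:
        raise ValueError(
            "build_graph expects intensities in [0, 1]; "
            "call normalize_intensities first"
        )
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    expected = connectivity_for_shape(a.shape)
    if connectivity is None:
        connectivity = expected
    elif connectivity != expected:
        raise ValueError(
            f"connectivity {connectivity} does not match a {a.ndim}D image "
            f"(expected {expected})"
        )
    edges = lattice_edges(a.shape)
    flat = a.ravel()
    diff = flat[edges[:, 0]] - flat[edges[:, 1]]
    weights = np.maximum(np.exp(-beta * diff * diff), epsilon_floor)
    return GraphWeights(
        shape=a.shape,
        connectivity=connectivity,
        edges=edges,
        weights=weights,
        beta=float(beta),
        epsilon_floor=float(epsilon_floor),
    )


def build_laplacian(graph: GraphWeights) -> sparse.csr_matrix:
    """Graph Laplacian L = D - W (degrees on the diagonal, -w_ij off it).

    Constructed symmetrically from the edge list, so L is bit-exactly
    symmetric and each row sums to zero up to floating-point accumulation.
    """
    n = graph.n_vertices
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    w = graph.weights
    adj = sparse.coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    ).tocsr()
    degrees = np.asarray(adj.sum(axis=1)).ravel()
    lap = sparse.diags(degrees) - adj
    return lap.tocsr()
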