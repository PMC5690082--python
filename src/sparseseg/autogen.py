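"""Seed-point auto-generation: from scribbles to extended seed sets.

Starting from a handful of user seeds per label, each voxel's intensity
is scored against every label's seed intensities with a Gaussian-kernel
likelihood

    p(i | s_k) = (1/N_sk) * sum_c exp(-(I_i - t_c)^2 / sigma)

normalized over the quantized intensity alphabet (levels 0..m), and
converted to a posterior p(s_k | i) by dividing by the sum across labels.
Thresholded region growing then floods outward from the seeds over the
lattice, admitting a neighbor only while its posterior for that label
exceeds the growth threshold ``p_t``.  The grown, pairwise-disjoint
extended seed sets (ESPs) replace the user seeds in the final
random-walker solve, feeding it intensity evidence from regions the user
never touched.  If nothing grows, the pipeline degenerates exactly to
the plain random walker.

The kernel width follows sigma = 0.5 * D_I, where D_I is the mean
absolute difference between per-label mean seed intensities on the
quantized 0..255 scale; low-contrast label pairs thus get a stricter
similarity criterion automatically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple

import numpy as np
from scipy import ndimage as ndi

from .graph import _as_image, connectivity_for_shape, normalize_intensities
from .solver import (
    DEFAULT_BETA,
    DEFAULT_MAX_ITER,
    DEFAULT_REL_TOL,
    ProbabilityField,
    SeedLabeling,
    Segmentation,
    random_walks_segment,
)

logger = logging.getLogger(__name__)

DEFAULT_GROWTH_THRESHOLD = 0.8
QUANT_LEVELS = 255


def quantize_for_likelihood(image) -> tuple[np.ndarray, int]:
    """Map intensities onto the integer alphabet 0..255.

    The likelihood normalizer sums over integer intensity levels, so the
    image must live on an integer grid.  Values already in [0, 1] are
    scaled by 255 and rounded; anything else is min-max normalized first.
    The quantized minimum is anchored at level 0, and ``m`` is the
    maximum pairwise intensity difference (the top occupied level).

    Returns ``(quantized, m)``; a constant image yields ``m = 0``.
    """
    a = _as_image(image)
    if a.min() < -1e-9 or a.max() > 1 + 1e-9:
        a = normalize_intensities(a)
    q = np.rint(a * QUANT_LEVELS).astype(np.int64)
    q -= q.min()
    return q, int(q.max())


def estimate_sigma(quantized, seeds: SeedLabeling) -> float:
    """Kernel width from seed contrast: sigma = 0.5 * D_I.

    D_I is the mean over unordered label pairs of the absolute difference
    between the labels' mean seed intensities (quantized scale).  With
    two labels this is simply the inside/outside seed contrast.
    """
    q = np.asarray(quantized)
    if q.max() == q.min():
        raise ValueError(
            "constant image: seed contrast is undefined, supply sigma manually"
        )
    flat = q.ravel()
    means = [flat[seeds.indices(lab)].mean() for lab in seeds.labels]
    diffs = [abs(a - b) for a, b in combinations(means, 2)]
    d_i = float(np.mean(diffs))
    if d_i == 0:
        warnings.warn(
            "labels have identical mean seed intensities; falling back to "
            "sigma = 1",
            stacklevel=2,
        )
        return 1.0
    return 0.5 * d_i


@dataclass
class LikelihoodMaps:
    """Per-label intensity likelihood maps p(i | s_k) on the image grid."""

    values: np.ndarray            # (*shape, k)
    labels: np.ndarray
    sigma: float
    level_cap: int                # m: top quantized level
    normalizers: np.ndarray       # N_sk per label
    seed_intensities: dict        # label -> quantized seed intensities t_c


@dataclass
class PosteriorMaps:
    """Per-label posterior maps p(s_k | i); rows sum to one."""

    values: np.ndarray            # (*shape, k)
    labels: np.ndarray
    underflow_count: int = 0

    def label_map(self, label: int) -> np.ndarray:
        j = int(np.flatnonzero(self.labels == label)[0])
        return self.values[..., j]


def likelihood_maps(quantized, seeds: SeedLabeling, sigma: float) -> LikelihoodMaps:
    """Gaussian-kernel likelihood of each voxel under each label's seeds.

    For label s_k with seed intensities t_c on the quantized grid,

        p(i|s_k) = (1/N_sk) sum_c exp(-(I_i - t_c)^2 / sigma)
        N_sk     = sum_{l=0..m} sum_c exp(-(l - t_c)^2 / sigma)

    so that summing the kernel over the full intensity alphabet gives one.
    Listing a seed intensity twice leaves the map unchanged (the factor
    cancels against N_sk).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    q = np.asarray(quantized)
    if q.shape != seeds.shape:
        raise ValueError("quantized image and seeds are on different grids")
    m = int(q.max())
    levels = np.arange(m + 1, dtype=float)
    flat = q.ravel()
    labels = seeds.labels
    maps = np.empty(q.shape + (len(labels),), dtype=float)
    normalizers = np.empty(len(labels))
    seed_intensities = {}
    for j, lab in enumerate(labels):
        t = flat[seeds.indices(lab)].astype(float)
        seed_intensities[int(lab)] = t
        # kernel summed over seeds, tabulated per intensity level
        kernel = np.exp(-((levels[:, None] - t[None, :]) ** 2) / sigma).sum(axis=1)
        n_sk = kernel.sum()
        normalizers[j] = n_sk
        maps[..., j] = (kernel / n_sk)[q]
    return LikelihoodMaps(values=maps, labels=labels, sigma=float(sigma),
                          level_cap=m, normalizers=normalizers,
                          seed_intensities=seed_intensities)


def posterior_maps(likelihoods: LikelihoodMaps) -> PosteriorMaps:
    """Posterior label probabilities: own likelihood over the label sum.

    Voxels where every likelihood underflows to zero get the
    uninformative posterior 1/k (and are counted); they can never pass a
    growth threshold above 1/k.
    """
    lik = likelihoods.values
    k = lik.shape[-1]
    denom = lik.sum(axis=-1)
    zero = denom < np.finfo(float).tiny
    underflow = int(np.count_nonzero(zero))
    if underflow:
        logger.info("posterior_maps: %d voxels with underflowed denominator "
                    "set to uniform 1/%d", underflow, k)
    safe = np.where(zero, 1.0, denom)
    post = lik / safe[..., None]
    post[zero] = 1.0 / k
    return PosteriorMaps(values=post, labels=likelihoods.labels,
                         underflow_count=underflow)


@dataclass
class ExtendedSeedSet:
    """Grown per-label seed chains E_sk, pairwise disjoint.

    ``label_map`` assigns each ESP voxel its label (0 = none).  Initial
    seeds are always contained in their own chain.  ``conflict_voxels``
    are non-seed voxels grown by more than one label and excluded from
    every chain.
    """

    label_map: np.ndarray
    labels: np.ndarray
    threshold: float
    conflict_voxels: np.ndarray   # flat indices
    growth_counts: dict           # label -> |E_sk|
    grew: bool

    def as_seed_labeling(self) -> SeedLabeling:
        return SeedLabeling(self.label_map)

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.label_map.ravel() == label)


def grow_extended_seeds(posteriors: PosteriorMaps, seeds: SeedLabeling,
                        p_t: float = DEFAULT_GROWTH_THRESHOLD,
                        connectivity: int | None = None) -> ExtendedSeedSet:
    """Threshold-gated region growing of each label's seed chain.

    Breadth-first flood from the initial seeds over the face-adjacency
    lattice: a neighbor joins label s_k's chain iff its posterior for s_k
    strictly exceeds ``p_t`` and it is reachable through already-admitted
    voxels.  Initial seeds are always retained.  Voxels grown by more
    than one label are removed from all chains (initial seeds keep their
    own label); if no voxel grows at all the result equals the seed sets
    and the pipeline degenerates to the plain random walker.
    """
    if not 0 < p_t < 1:
        raise ValueError(f"growth threshold must be in (0, 1), got {p_t}")
    shape = seeds.shape
    if posteriors.values.shape[:-1] != shape:
        raise ValueError("posterior maps and seeds are on different grids")
    expected = connectivity_for_shape(shape)
    if connectivity is not None and connectivity != expected:
        raise ValueError(
            f"connectivity {connectivity} does not match a {len(shape)}D grid"
        )
    structure = ndi.generate_binary_structure(len(shape), 1)

    labels = seeds.labels
    grown = np.zeros((len(labels),) + shape, dtype=bool)
    for j, lab in enumerate(labels):
        seed_mask = seeds.label_map == lab
        admissible = posteriors.values[..., j] > p_t
        components, n_comp = ndi.label(admissible, structure=structure)
        if n_comp:
            # flood-reachable = components touching a seed or its neighbors
            frontier = ndi.binary_dilation(seed_mask, structure=structure)
            reached = np.unique(components[frontier & admissible])
            reached = reached[reached > 0]
            grown[j] = np.isin(components, reached)
        grown[j] |= seed_mask

    claimed = grown.sum(axis=0)
    conflict = (claimed > 1) & (seeds.label_map == 0)
    grown &= ~conflict
    # an initial seed grown by another label keeps only its own label
    for j, lab in enumerate(labels):
        grown[j] &= (seeds.label_map == 0) | (seeds.label_map == lab)

    label_map = np.zeros(shape, dtype=np.int32)
    growth_counts = {}
    for j, lab in enumerate(labels):
        label_map[grown[j]] = lab
        growth_counts[int(lab)] = int(grown[j].sum())
    grew = bool(np.any(label_map != seeds.label_map))
    if not grew:
        logger.info("no voxel passed the growth threshold p_t=%.3g: "
                    "SPARSE degenerates to the plain random walker", p_t)
    return ExtendedSeedSet(label_map=label_map, labels=labels,
                           threshold=float(p_t),
                           conflict_voxels=np.flatnonzero(conflict.ravel()),
                           growth_counts=growth_counts, grew=grew)


class SparseResult(NamedTuple):
    segmentation: Segmentation
    extended_seeds: ExtendedSeedSet
    posteriors: PosteriorMaps
    probabilities: ProbabilityField


def sparse_segment(image, seeds: SeedLabeling,
                   beta: float = DEFAULT_BETA,
                   p_t: float = DEFAULT_GROWTH_THRESHOLD,
                   sigma: float | None = None,
                   connectivity: int | None = None,
                   rel_tol: float = DEFAULT_REL_TOL,
                   max_iter: int = DEFAULT_MAX_ITER) -> SparseResult:
    """Full seed-expansion pipeline ending in a random-walker solve.

    quantize -> estimate sigma (unless given) -> likelihood maps ->
    posterior maps -> ESP growth -> random walker seeded with the ESPs.
    Deterministic given its inputs; when no voxel grows the output is
    voxel-for-voxel identical to ``random_walks_segment``.
    """
    a = np.asarray(image, dtype=float)
    if a.shape != seeds.shape:
        raise ValueError(
            f"image shape {a.shape} does not match seed grid {seeds.shape}"
        )
    quantized, m = quantize_for_likelihood(a)
    if sigma is None:
        sigma = estimate_sigma(quantized, seeds)
    lik = likelihood_maps(quantized, seeds, sigma)
    post = posterior_maps(lik)
    esp = grow_extended_seeds(post, seeds, p_t=p_t, connectivity=connectivity)
    segmentation, field = random_walks_segment(
        a, esp.as_seed_labeling(), beta=beta, connectivity=connectivity,
        rel_tol=rel_tol, max_iter=max_iter,
    )
    return SparseResult(segmentation=segmentation, extended_seeds=esp,
                        posteriors=post, probabilities=field)
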