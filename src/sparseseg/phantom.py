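"""Synthetic block phantom and seed-robustness experiment protocols.

The phantom emulates an inhomogeneous anatomical target: a square region
tiled by a grid of piecewise-constant blocks whose intensities span
25..255 over a zero-intensity background, with additive i.i.d. Gaussian
noise (variance 20 by default).  Seeding only a subset of the blocks
reproduces the regime where a plain random walker under-segments the
unseeded blocks while seed auto-expansion recovers them.

Experiment protocols:

* seed reduction — random down-sampling of the initial seeds in 5% steps
  (at 100% a single seed per label survives);
* seed displacement — each seed is shifted along a random direction by a
  fraction of its distance to the ground-truth boundary, so it never
  crosses to the other side;
* beta sweep — edge-weight sharpness from 10 to 1500;
* growth-threshold sweep — p_t from 0.1 to 0.95.

``run_sensitivity_sweep`` runs the plain random walker and the
seed-expanded pipeline over a grid of any of these variables and returns
a tidy per-run metrics table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .autogen import DEFAULT_GROWTH_THRESHOLD, sparse_segment
from .metrics import dice, extract_boundary, hausdorff, percent_error
from .solver import DEFAULT_BETA, SeedLabeling, random_walks_segment

#: Nine equally spaced block intensities spanning 25..255.
DEFAULT_BLOCK_INTENSITIES = (25, 54, 83, 111, 140, 169, 198, 226, 255)

#: Label ids: 1 is the designated background label, 2 the target.
BACKGROUND_LABEL = 1
FOREGROUND_LABEL = 2

#: Checkerboard subset (corner blocks + center) used for the
#: five-of-nine seeded-blocks scenario.
FIVE_BLOCK_PATTERN = (0, 2, 4, 6, 8)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise of the block phantom."""

    image_size: tuple = (256, 256)
    block_grid: tuple = (3, 3)
    block_intensities: tuple = DEFAULT_BLOCK_INTENSITIES
    background_intensity: float = 0.0
    noise_variance: float = 20.0
    rng_seed: int = 0
    target_offset: tuple | None = None
    block_size: tuple | None = None

    def __post_init__(self):
        if len(self.block_intensities) != int(np.prod(self.block_grid)):
            raise ValueError(
                f"{np.prod(self.block_grid)} block intensities required, "
                f"got {len(self.block_intensities)}"
            )
        if self.noise_variance < 0:
            raise ValueError("noise variance must be non-negative")
        size = self.resolved_block_size
        offset = self.resolved_offset
        for s, g, bs, off in zip(self.image_size, self.block_grid, size, offset):
            if off < 0 or off + g * bs > s:
                raise ValueError("target does not fit inside the image")

    @property
    def resolved_block_size(self) -> tuple:
        if self.block_size is not None:
            return tuple(self.block_size)
        # target occupies roughly half the image side
        return tuple(s // (2 * g) for s, g in zip(self.image_size,
                                                  self.block_grid))

    @property
    def resolved_offset(self) -> tuple:
        if self.target_offset is not None:
            return tuple(self.target_offset)
        size = self.resolved_block_size
        return tuple((s - g * bs) // 2 for s, g, bs in
                     zip(self.image_size, self.block_grid, size))

    def block_slices(self) -> list:
        """Per-block index slices, row-major over the block grid."""
        bs = self.resolved_block_size
        off = self.resolved_offset
        out = []
        for idx in np.ndindex(*self.block_grid):
            out.append(tuple(
                slice(o + i * b, o + (i + 1) * b)
                for o, i, b in zip(off, idx, bs)
            ))
        return out


def make_block_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the phantom image and its noiseless ground-truth mask.

    Deterministic given ``spec.rng_seed``.
    """
    if len(set(spec.block_intensities)) != len(spec.block_intensities):
        warnings.warn("block intensities are not distinct; blocks will "
                      "merge statistically", stacklevel=2)
    image = np.full(spec.image_size, float(spec.background_intensity))
    gt = np.zeros(spec.image_size, dtype=bool)
    for slc, intensity in zip(spec.block_slices(), spec.block_intensities):
        image[slc] = intensity
        gt[slc] = True
    if spec.noise_variance > 0:
        rng = np.random.default_rng(spec.rng_seed)
        image += rng.normal(0.0, np.sqrt(spec.noise_variance),
                            size=spec.image_size)
    return image, gt


def place_block_seeds(spec: PhantomSpec, blocks_seeded=None,
                      seeds_per_block: int = 1, background_seeds: int = 8,
                      rng_seed: int = 0) -> SeedLabeling:
    """Foreground seeds near chosen block centers, background seeds outside.

    Foreground seeds are jittered uniformly within the central half of
    each chosen block; background seeds are sampled uniformly from
    background voxels at least 3 voxels (Manhattan) away from the target.
    """
    slices = spec.block_slices()
    if blocks_seeded is None:
        blocks_seeded = tuple(range(len(slices)))
    if len(blocks_seeded) == 0:
        raise ValueError("at least one block must be seeded")
    bs = spec.resolved_block_size
    if seeds_per_block > int(np.prod(bs)):
        raise ValueError("more seeds per block than the block has voxels")
    rng = np.random.default_rng(rng_seed)

    lm = np.zeros(spec.image_size, dtype=np.int32)
    for b in blocks_seeded:
        slc = slices[b]
        placed = 0
        while placed < seeds_per_block:
            coord = tuple(
                (s.start + s.stop) // 2
                + rng.integers(-(s.stop - s.start) // 4,
                               (s.stop - s.start) // 4 + 1)
                for s in slc
            )
            if lm[coord] == 0:
                lm[coord] = FOREGROUND_LABEL
                placed += 1

    _, gt = make_block_phantom(
        PhantomSpec(image_size=spec.image_size, block_grid=spec.block_grid,
                    block_intensities=spec.block_intensities,
                    noise_variance=0.0, target_offset=spec.target_offset,
                    block_size=spec.block_size)
    )
    structure = ndi.generate_binary_structure(len(spec.image_size), 1)
    forbidden = ndi.binary_dilation(gt, structure=structure, iterations=3)
    candidates = np.flatnonzero(~forbidden.ravel())
    chosen = rng.choice(candidates, size=background_seeds, replace=False)
    bg_map = lm.ravel()
    bg_map[chosen] = BACKGROUND_LABEL
    return SeedLabeling(bg_map.reshape(spec.image_size))


def reduce_seeds(seeds: SeedLabeling, reduction_fraction: float,
                 rng_seed: int = 0) -> SeedLabeling:
    """Randomly down-sample seeds, keeping round((1-f)·n) per label.

    Never fewer than one seed per label; at f = 1 exactly one survives.
    """
    if not 0 <= reduction_fraction <= 1:
        raise ValueError("reduction fraction must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    lm = np.zeros_like(seeds.label_map)
    flat = lm.ravel()
    for lab in seeds.labels:
        idx = seeds.indices(lab)
        n = idx.size
        keep = max(1, int(np.floor((1 - reduction_fraction) * n + 0.5)))
        if reduction_fraction >= 1:
            keep = 1
        kept = rng.choice(idx, size=keep, replace=False)
        flat[kept] = lab
    return SeedLabeling(lm)


def perturb_seed_locations(seeds: SeedLabeling, gt_boundary: np.ndarray,
                           amplitude_fraction: float, rng_seed: int = 0,
                           region=None) -> SeedLabeling:
    """Shift each seed along a random direction by a boundary-scaled step.

    The step length is ``amplitude_fraction`` times the seed's minimum
    Euclidean distance to the ground-truth boundary points, so seeds stay
    on their original side.  When ``region`` (the ground-truth mask) is
    given, sidedness is re-checked after rounding to voxel centers and
    the step is halved until it holds.
    """
    if not 0 <= amplitude_fraction < 1:
        raise ValueError("amplitude fraction must be in [0, 1)")
    boundary = np.atleast_2d(np.asarray(gt_boundary, dtype=float))
    rng = np.random.default_rng(rng_seed)
    shape = np.asarray(seeds.shape)
    region_mask = None if region is None else np.asarray(region, dtype=bool)

    lm = np.zeros_like(seeds.label_map)
    for lab in seeds.labels:
        coords = np.argwhere(seeds.label_map == lab)
        for p in coords:
            d = np.sqrt(((boundary - p) ** 2).sum(axis=1)).min()
            direction = rng.normal(size=len(shape))
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 0 else direction * 0
            step = d * amplitude_fraction
            target = p
            while step >= 0.5:
                cand = np.rint(p + step * direction).astype(int)
                cand = np.clip(cand, 0, shape - 1)
                ok = lm[tuple(cand)] in (0, lab)
                if ok and region_mask is not None:
                    ok = region_mask[tuple(cand)] == region_mask[tuple(p)]
                if ok:
                    target = cand
                    break
                step /= 2
            lm[tuple(target)] = lab
    return SeedLabeling(lm)


DEFAULT_SWEEP_GRIDS = {
    "seed_reduction": tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2)),
    "seed_location": tuple(np.round(np.arange(0.0, 0.95, 0.1), 2)),
    "beta": tuple(range(10, 1411, 100)) + (1500,),
    "p_t": tuple(np.round(np.arange(0.1, 0.951, 0.05), 2)),
}


def run_sensitivity_sweep(image, gt, seeds: SeedLabeling, sweep: str,
                          grid=None, methods=("rw", "sparse"),
                          replicates: int = 1, rng_seed: int = 0,
                          beta: float = DEFAULT_BETA,
                          p_t: float = DEFAULT_GROWTH_THRESHOLD,
                          foreground_label: int = FOREGROUND_LABEL,
                          ) -> pd.DataFrame:
    """Run both methods over a parameter grid and tabulate the metrics.

    Returns a tidy DataFrame with one row per (method, value, replicate):
    columns method, sweep_variable, value, replicate, dc, pe, hd,
    rng_seed, status.  A segmentation failure yields a 'failed: ...'
    status row with NaN metrics rather than a crash.
    """
    if sweep not in DEFAULT_SWEEP_GRIDS:
        raise ValueError(f"unknown sweep variable {sweep!r}; choose from "
                         f"{sorted(DEFAULT_SWEEP_GRIDS)}")
    if grid is None:
        grid = DEFAULT_SWEEP_GRIDS[sweep]
    grid = list(grid)
    if not grid:
        raise ValueError("sweep grid must be nonempty")
    gt = np.asarray(gt, dtype=bool)
    gt_boundary = extract_boundary(gt)

    rows = []
    for vi, value in enumerate(grid):
        for rep in range(replicates):
            child = int(np.random.SeedSequence(
                [rng_seed, vi, rep]).generate_state(1)[0] % (2 ** 31))
            run_seeds = seeds
            run_beta, run_pt = beta, p_t
            if sweep == "seed_reduction":
                run_seeds = reduce_seeds(seeds, float(value), rng_seed=child)
            elif sweep == "seed_location":
                run_seeds = perturb_seed_locations(
                    seeds, gt_boundary, float(value), rng_seed=child,
                    region=gt)
            elif sweep == "beta":
                run_beta = float(value)
            elif sweep == "p_t":
                run_pt = float(value)
            for method in methods:
                row = {"method": method, "sweep_variable": sweep,
                       "value": value, "replicate": rep,
                       "dc": np.nan, "pe": np.nan, "hd": np.nan,
                       "rng_seed": child, "status": "ok"}
                try:
                    if method == "rw":
                        seg, _ = random_walks_segment(image, run_seeds,
                                                      beta=run_beta)
                    elif method == "sparse":
                        seg = sparse_segment(image, run_seeds, beta=run_beta,
                                             p_t=run_pt).segmentation
                    else:
                        raise ValueError(f"unknown method {method!r}")
                    mask = seg.label_map == foreground_label
                    row["dc"] = dice(gt, mask)
                    row["pe"] = percent_error(gt, mask)
                    if mask.any():
                        row["hd"] = hausdorff(gt_boundary,
                                              extract_boundary(mask))
                    else:
                        row["status"] = "failed: empty segmentation"
                except Exception as exc:  # record, don't crash the sweep
                    row["status"] = f"failed: {exc}"
                rows.append(row)
    return pd.DataFrame(rows)
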