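# sparseseg

Random-walker image segmentation with automatic seed-point expansion, for
2D grayscale images and 3D volumes (CT/MR and similar scalar modalities).

Interactive random-walker (RW) segmentation labels every voxel with the
probability that a random walker released there first reaches a seed of
each label. It works well when the user's scribbles cover all intensity
levels of the target — but *inhomogeneous* targets (a vertebra, an
applicator, a heterogeneous tumor) contain many intensity populations, and
seeding them all by hand is tedious, especially in 3D. With sparse seeds,
plain RW under-segments the populations the user never touched.

`sparseseg` closes that gap by growing **extended seed points (ESPs)**
from the user's scribbles before the walker runs:

1. **Likelihood.** Each voxel's intensity `I_i` (quantized to 0..255) is
   scored against each label's seed intensities `t_c`:
   `p(i|s_k) = (1/N_k) Σ_c exp(-(I_i - t_c)² / σ)`, where `N_k` sums the
   kernel over all intensity levels `l = 0..m`. The width is set from
   seed contrast: `σ = 0.5·D_I`, with `D_I` the mean difference between
   the labels' mean seed intensities.
2. **Posterior.** `p(s_k|i) = p(i|s_k) / Σ_s p(i|s)`.
3. **Growth.** Region growing floods from the seeds over the lattice,
   admitting a neighbor into label `s_k`'s chain iff `p(s_k|i) > P_T`
   (default 0.8). Voxels claimed by more than one label are dropped.
4. **Random walker.** The graph with edge weights
   `w_ij = exp(-β (I_i - I_j)²)` (β = 90, intensities normalized to
   [0, 1]) yields the Laplacian `L`; for each label the Dirichlet system
   `L_U x_U = -Bᵀ x_M` is solved by conjugate gradients (tolerance 1e-6,
   ≤1000 iterations) with the ESPs as boundary conditions, and each voxel
   takes the label of maximum probability.

If no voxel passes the threshold, the pipeline degenerates exactly to
plain RW. The package also ships the evaluation metrics (Dice, percent
error, Hausdorff distance), the SD-based homogeneous/inhomogeneous target
classifier, a nine-block synthetic phantom, and seed-robustness sweep
protocols.

## Worked example

```python
import sparseseg as ss

spec = ss.PhantomSpec(image_size=(128, 128), rng_seed=1)
image, truth = ss.make_block_phantom(spec)
seeds = ss.place_block_seeds(spec, blocks_seeded=ss.FIVE_BLOCK_PATTERN,
                             seeds_per_block=1, background_seeds=8, rng_seed=1)

rw_seg, _ = ss.random_walks_segment(image, seeds, beta=90)
result = ss.sparse_segment(image, seeds, beta=90, p_t=0.8)

for name, seg in [("RW", rw_seg), ("SPARSE", result.segmentation)]:
    mask = seg.label_map == ss.FOREGROUND_LABEL
    print(f"{name:6s} Dice={ss.dice(truth, mask):.4f} "
          f"PE={ss.percent_error(truth, mask):.4f}")
print("extended seeds per label:", result.extended_seeds.growth_counts)
category, sd = ss.classify_homogeneity(image, truth)
print(f"target SD={sd:.3f} -> {category}")
```

Output:

```
RW     Dice=0.9755 PE=0.0479
SPARSE Dice=1.0000 PE=0.0000
extended seeds per label: {1: 12409, 2: 3907}
target SD=0.289 -> inhomogeneous
```

The phantom's target is nine blocks with intensities 25..255, but only
five blocks carry a seed. Plain RW misses parts of the unseeded blocks;
seed expansion grows 3907 foreground ESPs covering every block (the
target is 63×63 = 3969 voxels) and recovers the full target. The target's
normalized intensity SD (0.289 ≥ 0.1) classifies it as inhomogeneous.

The same pipeline is available from the shell:

```bash
sparseseg phantom --size 128 --blocks five --out-image phantom.png \
    --out-mask mask.png --out-seeds seeds.csv
sparseseg segment-sparse --image phantom.png --seeds seeds.csv --out seg.png
sparseseg metrics --reference mask.png --segmentation seg.png --label 1
sparseseg sweep --variable beta --out beta_sweep.csv
```

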