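# Methods

## Model

An image is a lattice graph: voxels are vertices, face-adjacent pairs are
edges (4-connectivity in 2D, 6-connectivity in 3D), and each edge carries
the affinity `w_ij = exp(-β (I_i - I_j)²)` computed on intensities
min-max normalized to [0, 1]. The random-walker probability `x_i^s` —
that a walker from voxel *i* is first absorbed at a seed of label *s* —
is harmonic on the unseeded voxels, so with the Laplacian partitioned
into seeded (M) and unseeded (U) blocks it solves the sparse SPD system
`L_U x_U = -Bᵀ x_M`, with `x_M` the 0/1 label indicator on seeds. The
segmentation is the per-voxel argmax over labels.

Seed expansion converts a sparse scribble into dense boundary
conditions. Intensities are quantized to the integer alphabet 0..255
(anchored so the minimum maps to level 0; `m` is the top occupied
level). Each label's seed intensities `t_c` define a kernel likelihood
`p(i|s_k) = (1/N_k) Σ_c exp(-(I_i - t_c)²/σ)` with
`N_k = Σ_{l=0..m} Σ_c exp(-(l - t_c)²/σ)`, normalized into posteriors
across labels. Flood growth from the seeds admits a lattice neighbor
into label k's chain iff its posterior strictly exceeds `P_T`;
reachability matters, so a low-posterior barrier blocks growth even if
high-posterior voxels lie beyond it. The final walker runs with the
grown chains as seeds.

## Parameters

| parameter | default | meaning |
|---|---|---|
| β | 90 | edge-weight sharpness on [0,1] intensities; larger β makes intensity steps harder barriers |
| σ | 0.5·D_I | likelihood kernel width on the 0..255 quantized scale; D_I is the mean absolute difference between per-label mean seed intensities (mean over unordered label pairs when k > 2) |
| P_T | 0.8 | posterior threshold for growth, one value for all labels; useful range ≈ [0.6, 0.9] (warned outside) |
| CG tolerance / max iterations | 1e-6 / 1000 | conjugate-gradient stopping rule, no preconditioner; non-convergence raises rather than returning a degraded field |
| weight floor | 1e-6 | lower clamp on `w_ij`; keeps the lattice connected when the exponential underflows |

The σ rule is applied literally on the quantized scale even though it
places an intensity (not intensity²) quantity in the denominator of a
squared difference; it is the form that ties kernel strictness to
target/background contrast, and the pipeline's behavior is insensitive
to the distinction at the default settings.

## Numerical and design choices

- Voxel indexing is row-major over `(row, col[, slice])`, 0-based; only
  face adjacency is used. Voxel spacing does not enter the weights; it
  is available for physical-unit Hausdorff reporting.
- Only k−1 Dirichlet systems are solved; the last label's field is one
  minus the sum of the others (exact partition of unity).
- Argmax ties (within 1e-12) break toward the smallest label id and are
  counted. Label id 1 is the designated background: voxels in graph
  components containing no seed are assigned it with a warning.
- Boundary indicator convention for k > 2: each label's `x_M` is 1 on
  its own seeds and 0 on every other label's seeds.
- Growth uses strict `posterior > P_T`. Initial seeds always remain in
  their own chain, even below threshold — silently discarding user
  input is unacceptable. A voxel grown by more than one label is
  excluded from all chains (an initial seed only keeps its own label);
  with two labels and `P_T > 0.5` no conflicts can occur since
  posteriors sum to one.
- Posterior denominators that underflow to zero yield the uniform 1/k
  (counted and logged); such voxels cannot pass any threshold above 1/k.
- Degenerate inputs: a constant image normalizes to all zeros with a
  warning (the walk becomes purely geometric and β irrelevant); σ
  estimation on a constant image raises and asks for a manual σ;
  identical per-label seed means fall back to σ = 1 with a warning.

## Synthetic phantom

The benchmark image is a square target of 3×3 piecewise-constant blocks
with intensities {25, 54, 83, 111, 140, 169, 198, 226, 255} on a
zero-intensity background, plus i.i.d. Gaussian noise of variance 20 —
an idealized inhomogeneous structure with nine distinct intensity
populations. The canonical resolution is 256×256 with the target
occupying half the image side; the test suite and the acceptance script
use a 128×128 rendering (identical geometry proportions, 63×63 target,
same noise variance) to keep runs fast on one CPU. The stressed regime
seeds only five of the nine blocks (corners + center), one seed near
each block center, with eight background seeds at least 3 voxels from
the target.

What the phantom does *not* emulate: partial-volume and textured
boundaries (its edges are crisp step edges plus noise), intensity
gradients within a population, overlapping target/background intensity
distributions, and anisotropic voxels. Passing the phantom benchmarks
therefore demonstrates the mechanism — recovery of unseeded intensity
populations and robustness to seed perturbation and β — not clinical
accuracy on real CT/MR data.

## Experiment protocols

- **Seed reduction**: seeds randomly down-sampled per label in 5% steps;
  at 100% exactly one seed per label survives. Three replicates per
  level in the acceptance runs.
- **Seed displacement**: every seed moves along a random direction by
  `fraction × (its distance to the ground-truth boundary)`, so it stays
  on its original side; after rounding to voxel centers the side is
  re-checked against the mask and the step halved until it holds.
- **β sweep**: grid {10, 110, …, 1410, 1500} with fixed seeds.
- **P_T sweep**: grid 0.1..0.95.

Sweeps record Dice, percent error and Hausdorff distance per
(method, value, replicate) as a tidy table; failures become status rows,
not crashes. All randomness flows from explicit integer seeds; repeated
runs are bit-identical.

## Verification strategy

Each computational stage is checked against an independent oracle: the
CG solve against a dense direct solve of the same system (and, at the
labeling level, against scikit-image's random walker on a high-contrast
image), the kernel likelihoods against a brute-force double sum over
seeds and levels, ESP growth against a brute-force BFS flood, and the
Hausdorff distance against an exhaustive double loop. Metric identities
(Dice/PE consistency, symmetry), the partition of unity, the maximum
principle, degeneration-to-RW bit-identity, and the seeded-phantom
orderings (expansion ≥ plain walker under seed reduction; smaller Dice
spread across β) are asserted in the test suite. Closed-form checks at
tight tolerances (the linear harmonic profile on a path, 1e-10) run the
solver at a tighter CG tolerance (1e-12) than the production default,
since the default stopping rule certifies only ~1e-6 residuals.

## Known limitations

- Likelihoods are single-channel intensity only; no texture or
  multi-channel features.
- One global `P_T` for all labels; no adaptive per-label thresholds.
- Growth connectivity equals the graph connectivity (no diagonal
  growth).
- The CG solver is unpreconditioned by design fidelity; on severely
  ill-conditioned graphs (β ≫ 100 on noisy data) tighten `rel_tol` if
  probabilities near 0/1 must be resolved finely.
- 2D inputs are PNG/TIFF and 3D NIfTI; DICOM series are out of scope.
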