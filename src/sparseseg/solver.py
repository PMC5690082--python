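"""Random-walker segmentation: the combinatorial Dirichlet problem.

A walker released at voxel i is absorbed at the first seed it reaches;
x_i^s is the probability that this seed carries label s.  These
probabilities are harmonic on the unlabeled voxels, so they solve

    L_U x_U = -B^T x_M

where the graph Laplacian is partitioned into seeded (M) and unseeded (U)
blocks and x_M is the 0/1 label indicator on the seeds.  The final
segmentation assigns each voxel the label of maximum probability.

Only k-1 linear systems are solved for k labels; the last field follows
from the partition of unity (the per-voxel probabilities sum to one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import cg

from .graph import (
    build_graph,
    build_laplacian,
    connectivity_for_shape,
    normalize_intensities,
    DEFAULT_WEIGHT_FLOOR,
)

DEFAULT_BETA = 90.0
DEFAULT_REL_TOL = 1e-6
DEFAULT_MAX_ITER = 1000


@dataclass(frozen=True)
class SeedLabeling:
    """User-labeled seed voxels as a label map (0 = unlabeled).

    At least two label groups (e.g. foreground and background) are
    required; each labeled voxel carries exactly one positive integer
    label id.
    """

    label_map: np.ndarray

    def __post_init__(self):
        lm = np.asarray(self.label_map)
        if not np.issubdtype(lm.dtype, np.integer):
            raise TypeError("seed label map must be an integer array")
        if lm.min() < 0:
            raise ValueError("seed labels must be non-negative (0 = unlabeled)")
        if len(self.labels) < 2:
            raise ValueError(
                "at least two groups of labels (e.g. foreground and "
                "background seeds) must be supplied"
            )
        object.__setattr__(self, "label_map", lm)

    @property
    def shape(self) -> tuple:
        return self.label_map.shape

    @property
    def labels(self) -> np.ndarray:
        """Sorted positive label ids present in the map."""
        u = np.unique(self.label_map)
        return u[u > 0]

    @property
    def counts(self) -> dict:
        labels, counts = np.unique(self.label_map[self.label_map > 0],
                                   return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def indices(self, label: int) -> np.ndarray:
        """Flat (row-major) voxel indices carrying ``label``."""
        return np.flatnonzero(self.label_map.ravel() == label)

    @classmethod
    def from_points(cls, shape, labels, coordinates) -> "SeedLabeling":
        """Build from per-seed label ids and integer voxel coordinates."""
        lm = np.zeros(shape, dtype=np.int32)
        coords = np.atleast_2d(np.asarray(coordinates, dtype=int))
        labels = np.asarray(labels, dtype=int)
        if coords.shape[0] != labels.shape[0]:
            raise ValueError("one label id per coordinate is required")
        if coords.shape[1] != len(shape):
            raise ValueError(
                f"coordinates have {coords.shape[1]} components for a "
                f"{len(shape)}D grid"
            )
        for row, (lab, c) in enumerate(zip(labels, coords)):
            if np.any(c < 0) or np.any(c >= np.asarray(shape)):
                raise ValueError(f"seed row {row}: coordinate {tuple(c)} is "
                                 f"outside the {shape} grid")
            existing = lm[tuple(c)]
            if existing and existing != lab:
                raise ValueError(
                    f"seed row {row}: voxel {tuple(c)} already carries "
                    f"label {existing}, conflicting with {lab}"
                )
            lm[tuple(c)] = lab
        return cls(lm)


@dataclass(frozen=True)
class DirichletSystem:
    """Partitioned Laplacian system for the walker probabilities.

    ``x_M`` holds one 0/1 indicator column per label on the labeled
    voxels.  ``seedless`` lists voxels in connected components that no
    seed reaches; they are excluded from the linear system and handled
    by the caller (assigned the first/background label).
    """

    labels: np.ndarray
    labeled: np.ndarray
    unlabeled: np.ndarray
    seedless: np.ndarray
    L_U: sparse.csr_matrix
    B: sparse.csr_matrix  # |M| x |U| coupling block
    x_M: np.ndarray       # |M| x k indicators
    n_vertices: int
    shape: tuple


@dataclass
class ProbabilityField:
    """Per-voxel, per-label walker probabilities x_i^s."""

    values: np.ndarray        # (n_vertices, k)
    labels: np.ndarray
    shape: tuple
    solver_report: dict = field(default_factory=dict)

    def label_probabilities(self, label: int) -> np.ndarray:
        j = int(np.flatnonzero(self.labels == label)[0])
        return self.values[:, j].reshape(self.shape)


@dataclass(frozen=True)
class Segmentation:
    """Argmax labeling; ``tie_count`` voxels were decided by tie-break."""

    label_map: np.ndarray
    tie_count: int


def partition_system(laplacian: sparse.spmatrix,
                     seeds: SeedLabeling) -> DirichletSystem:
    """Split L into seeded/unseeded blocks and build boundary indicators.

    Connected components of the graph containing no seed of any label are
    flagged in ``seedless`` rather than entering L_U (which would be
    singular there).
    """
    lap = sparse.csr_matrix(laplacian)
    n = lap.shape[0]
    lm = seeds.label_map.ravel()
    if lm.size != n:
        raise ValueError(
            f"seed grid has {lm.size} voxels but the Laplacian is {n}x{n}"
        )
    labeled = np.flatnonzero(lm > 0)

    adjacency = lap - sparse.diags(lap.diagonal())
    _, comp = csgraph.connected_components(adjacency, directed=False)
    seeded_components = np.unique(comp[labeled])
    seedless_mask = ~np.isin(comp, seeded_components)
    seedless = np.flatnonzero(seedless_mask)
    unlabeled = np.flatnonzero((lm == 0) & ~seedless_mask)

    labels = seeds.labels
    x_M = (lm[labeled][:, None] == labels[None, :]).astype(float)
    L_U = lap[unlabeled][:, unlabeled]
    B = lap[labeled][:, unlabeled]
    return DirichletSystem(
        labels=labels, labeled=labeled, unlabeled=unlabeled,
        seedless=seedless, L_U=L_U.tocsr(), B=B.tocsr(), x_M=x_M,
        n_vertices=n, shape=seeds.shape,
    )


def solve_probabilities(system: DirichletSystem,
                        rel_tol: float = DEFAULT_REL_TOL,
                        max_iter: int = DEFAULT_MAX_ITER) -> "ProbabilityField":
    """Solve L_U x_U = -B^T x_M per label with conjugate gradients.

    The first k-1 label systems are solved; the last field is one minus
    the sum of the others.  Seeds keep their exact indicator values.
    Raises ``RuntimeError`` if CG does not reach ``rel_tol`` within
    ``max_iter`` iterations.
    """
    k = len(system.labels)
    values = np.zeros((system.n_vertices, k))
    values[system.labeled, :] = system.x_M
    if system.seedless.size:
        values[system.seedless, 0] = 1.0

    report = {}
    n_u = system.unlabeled.size
    if n_u:
        rhs = -(system.B.T @ system.x_M)  # (|U|, k)
        for j in range(k - 1):
            b = rhs[:, j]
            iterations = 0

            def _count(_xk):
                nonlocal iterations
                iterations += 1

            x, info = cg(system.L_U, b, rtol=rel_tol, maxiter=max_iter,
                         callback=_count)
            b_norm = np.linalg.norm(b)
            residual = (np.linalg.norm(b - system.L_U @ x) / b_norm
                        if b_norm > 0 else 0.0)
            label = int(system.labels[j])
            report[label] = {"iterations": iterations, "residual": residual}
            if info != 0 and residual > rel_tol:
                raise RuntimeError(
                    f"conjugate gradient failed for label {label}: "
                    f"residual {residual:.3e} > {rel_tol:.1e} after "
                    f"{iterations} iterations"
                )
            values[system.unlabeled, j] = x
        values[system.unlabeled, k - 1] = (
            1.0 - values[system.unlabeled, : k - 1].sum(axis=1)
        )
    return ProbabilityField(values=values, labels=system.labels,
                            shape=system.shape, solver_report=report)


def assign_labels(field: ProbabilityField, tie_tol: float = 1e-12) -> Segmentation:
    """Per-voxel argmax labeling; ties go to the smallest label id."""
    vals = field.values
    best = vals.max(axis=1)
    # argmax returns the first (= smallest-id, labels are sorted) maximum
    winner = np.argmax(vals, axis=1)
    tie_count = int(np.count_nonzero(
        (vals >= best[:, None] - tie_tol).sum(axis=1) > 1
    ))
    label_map = field.labels[winner].reshape(field.shape)
    return Segmentation(label_map=label_map.astype(np.int32),
                        tie_count=tie_count)


def random_walks_segment(image, seeds: SeedLabeling,
                         beta: float = DEFAULT_BETA,
                         connectivity: int | None = None,
                         rel_tol: float = DEFAULT_REL_TOL,
                         max_iter: int = DEFAULT_MAX_ITER,
                         epsilon_floor: float = DEFAULT_WEIGHT_FLOOR,
                         ) -> tuple[Segmentation, ProbabilityField]:
    """End-to-end random-walker segmentation of an image given seeds.

    Normalizes intensities, builds the lattice graph and Laplacian,
    solves the Dirichlet problem and returns the argmax segmentation
    together with the probability field.  Deterministic given its inputs.
    """
    a = np.asarray(image, dtype=float)
    if a.shape != seeds.shape:
        raise ValueError(
            f"image shape {a.shape} does not match seed grid {seeds.shape}"
        )
    normalized = normalize_intensities(a)
    graph = build_graph(normalized, beta=beta, connectivity=connectivity,
                        epsilon_floor=epsilon_floor)
    laplacian = build_laplacian(graph)
    system = partition_system(laplacian, seeds)
    if system.seedless.size:
        warnings.warn(
            f"{system.seedless.size} voxels lie in components with no seed; "
            f"assigned background label {int(system.labels[0])}",
            stacklevel=2,
        )
    field = solve_probabilities(system, rel_tol=rel_tol, max_iter=max_iter)
    return assign_labels(field), field
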