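import numpy as np
import pytest
from hypothesis import settings

import sparseseg as ss

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def phantom128():
    """128x128 nine-block phantom (noise variance 20, fixed seed) with
    ground truth and seeds placed in five of the nine blocks."""
    spec = ss.PhantomSpec(image_size=(128, 128), rng_seed=1)
    image, gt = ss.make_block_phantom(spec)
    seeds = ss.place_block_seeds(spec, blocks_seeded=ss.FIVE_BLOCK_PATTERN,
                                 seeds_per_block=1, background_seeds=8,
                                 rng_seed=1)
    return spec, image, gt, seeds


@pytest.fixture(scope="session")
def phantom128_dense_seeds(phantom128):
    """Same phantom with three seeds per seeded block (for reduction sweeps)."""
    spec, image, gt, _ = phantom128
    seeds = ss.place_block_seeds(spec, blocks_seeded=ss.FIVE_BLOCK_PATTERN,
                                 seeds_per_block=3, background_seeds=15,
                                 rng_seed=1)
    return spec, image, gt, seeds


def random_lattice_case(rng, max_side=10, max_labels=4):
    """A random small image plus a valid random seeding (2..k labels)."""
    shape = (int(rng.integers(2, max_side + 1)),
             int(rng.integers(2, max_side + 1)))
    image = rng.random(shape)
    k = int(rng.integers(2, max_labels + 1))
    n = shape[0] * shape[1]
    n_seeds = int(rng.integers(k, min(n, k + 6) + 1))
    voxels = rng.choice(n, size=n_seeds, replace=False)
    labels = np.concatenate([np.arange(1, k + 1),
                             rng.integers(1, k + 1, size=n_seeds - k)])
    label_map = np.zeros(n, dtype=np.int32)
    label_map[voxels] = labels
    return image, ss.SeedLabeling(label_map.reshape(shape))


def dense_walker_probabilities(image, seeds, beta=90.0):
    """Dense direct solve of the Dirichlet system (independent oracle)."""
    normalized = ss.normalize_intensities(image)
    graph = ss.build_graph(normalized, beta=beta)
    lap = ss.build_laplacian(graph).toarray()
    lm = seeds.label_map.ravel()
    labeled = np.flatnonzero(lm > 0)
    unlabeled = np.flatnonzero(lm == 0)
    labels = seeds.labels
    x_m = (lm[labeled][:, None] == labels[None, :]).astype(float)
    values = np.zeros((lm.size, len(labels)))
    values[labeled] = x_m
    if unlabeled.size:
        l_u = lap[np.ix_(unlabeled, unlabeled)]
        b = lap[np.ix_(labeled, unlabeled)]
        values[unlabeled] = np.linalg.solve(l_u, -b.T @ x_m)
    return values
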