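"""Seed auto-generation: likelihoods, posteriors, ESP growth."""

from collections import deque

import numpy as np
import pytest

import sparseseg as ss
from sparseseg.autogen import likelihood_maps, posterior_maps


def brute_force_likelihood(quantized, seed_intensities, sigma):
    """Double-loop oracle for the kernel likelihood of one label."""
    m = int(quantized.max())
    normalizer = 0.0
    for level in range(m + 1):
        for t in seed_intensities:
            normalizer += np.exp(-((level - t) ** 2) / sigma)
    out = np.zeros(quantized.shape)
    for idx in np.ndindex(quantized.shape):
        acc = 0.0
        for t in seed_intensities:
            acc += np.exp(-((quantized[idx] - t) ** 2) / sigma)
        out[idx] = acc / normalizer
    return out


def bfs_grow(posterior, seed_mask, p_t):
    """Brute-force BFS flood oracle for one label's ESP chain."""
    shape = posterior.shape
    grown = np.zeros(shape, dtype=bool)
    queue = deque(map(tuple, np.argwhere(seed_mask)))
    for s in queue:
        grown[s] = True
    while queue:
        p = queue.popleft()
        for ax in range(len(shape)):
            for step in (-1, 1):
                q = list(p)
                q[ax] += step
                q = tuple(q)
                if not (0 <= q[ax] < shape[ax]) or grown[q]:
                    continue
                if posterior[q] > p_t:
                    grown[q] = True
                    queue.append(q)
    return grown


class TestQuantize:
    def test_full_range(self):
        q, m = ss.quantize_for_likelihood(np.array([[0.0, 0.5, 1.0]]))
        assert q.tolist() == [[0, 128, 255]]
        assert m == 255

    def test_partial_range_is_not_stretched(self):
        q, m = ss.quantize_for_likelihood(np.array([[0.0, 0.5]]))
        assert q.tolist() == [[0, 128]]
        assert m == 128

    def test_raw_intensities_are_normalized_first(self):
        q, m = ss.quantize_for_likelihood(np.array([[25.0, 140.0, 255.0]]))
        assert q.tolist() == [[0, 128, 255]]

    def test_constant_image(self):
        with pytest.warns(UserWarning, match="constant"):
            q, m = ss.quantize_for_likelihood(np.full((2, 2), 3.0))
        assert m == 0


class TestSigma:
    def _seeds(self, shape, fg, bg):
        lm = np.zeros(shape, dtype=np.int32)
        for c in bg:
            lm[c] = 1
        for c in fg:
            lm[c] = 2
        return ss.SeedLabeling(lm)

    def test_two_label_contrast(self):
        q = np.array([[100, 50], [0, 255]])
        seeds = self._seeds((2, 2), fg=[(0, 0)], bg=[(0, 1)])
        assert ss.estimate_sigma(q, seeds) == pytest.approx(25.0)

    def test_means_then_half_difference(self):
        q = np.array([[90, 110, 0], [40, 60, 255]])
        seeds = self._seeds((2, 3), fg=[(0, 0), (0, 1)],
                            bg=[(1, 0), (1, 1)])
        assert ss.estimate_sigma(q, seeds) == pytest.approx(25.0)

    def test_identical_means_fall_back_to_one(self):
        q = np.array([[80, 80], [0, 255]])
        seeds = self._seeds((2, 2), fg=[(0, 0)], bg=[(0, 1)])
        with pytest.warns(UserWarning, match="identical"):
            assert ss.estimate_sigma(q, seeds) == 1.0

    def test_constant_image_errors(self):
        seeds = self._seeds((2, 2), fg=[(0, 0)], bg=[(0, 1)])
        with pytest.raises(ValueError, match="sigma manually"):
            ss.estimate_sigma(np.full((2, 2), 7), seeds)


class TestLikelihood:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        q = rng.integers(0, 256, size=(6, 6))
        q.flat[0], q.flat[1] = 0, 255  # pin the alphabet to 0..255
        lm = np.zeros((6, 6), dtype=np.int32)
        seed_idx = rng.choice(36, size=7, replace=False)
        lm.flat[seed_idx[:4]] = 1
        lm.flat[seed_idx[4:]] = 2
        seeds = ss.SeedLabeling(lm)
        lik = likelihood_maps(q, seeds, sigma=25.0)
        for j, lab in enumerate(seeds.labels):
            t = q.ravel()[seeds.indices(lab)]
            oracle = brute_force_likelihood(q, t, 25.0)
            assert np.max(np.abs(lik.values[..., j] - oracle)) < 1e-10

    def test_kernel_sums_to_one_over_levels(self):
        q = np.array([[0, 128], [255, 64]])
        lm = np.array([[2, 0], [1, 0]], dtype=np.int32)
        lik = likelihood_maps(q, ss.SeedLabeling(lm), sigma=25.0)
        # by construction of the normalizer, the per-level kernel sums to 1
        for j, lab in enumerate(lik.labels):
            t = lik.seed_intensities[int(lab)]
            levels = np.arange(lik.level_cap + 1)
            total = np.exp(-(levels[:, None] - t) ** 2 / lik.sigma).sum()
            assert total / lik.normalizers[j] == pytest.approx(1.0, abs=1e-6)

    def test_seed_at_own_intensity(self):
        q = np.array([[128, 0], [255, 40]])
        lm = np.array([[2, 1], [0, 0]], dtype=np.int32)
        lik = likelihood_maps(q, ss.SeedLabeling(lm), sigma=25.0)
        # voxel whose intensity equals the single seed's: kernel term is 1
        assert lik.values[0, 0, 1] == pytest.approx(1.0 / lik.normalizers[1])

    def test_duplicated_seed_intensities_cancel(self):
        q = np.array([[128, 128, 0, 255, 60, 200]])
        one = ss.SeedLabeling(np.array([[2, 0, 1, 0, 0, 0]], dtype=np.int32))
        two = ss.SeedLabeling(np.array([[2, 2, 1, 0, 0, 0]], dtype=np.int32))
        a = likelihood_maps(q, one, sigma=30.0)
        b = likelihood_maps(q, two, sigma=30.0)
        assert np.allclose(a.values, b.values, atol=1e-12)


class TestPosterior:
    def _lik(self, values):
        values = np.asarray(values, dtype=float)
        return ss.LikelihoodMaps(values=values, labels=np.array([1, 2]),
                                 sigma=1.0, level_cap=255,
                                 normalizers=np.ones(2), seed_intensities={})

    def test_equal_likelihoods_split_evenly(self):
        post = posterior_maps(self._lik([[[0.2, 0.2]]]))
        assert np.allclose(post.values, 0.5)

    def test_direct_ratio(self):
        post = posterior_maps(self._lik([[[0.03, 0.01]]]))
        assert np.allclose(post.values[0, 0], [0.75, 0.25])

    def test_partition_of_unity(self):
        rng = np.random.default_rng(1)
        lik = self._lik(rng.random((5, 5, 2)) + 1e-12)
        post = posterior_maps(lik)
        assert np.allclose(post.values.sum(axis=-1), 1.0, atol=1e-6)

    def test_underflow_gives_uniform(self):
        post = posterior_maps(self._lik([[[0.0, 0.0], [0.4, 0.0]]]))
        assert post.underflow_count == 1
        assert np.allclose(post.values[0, 0], [0.5, 0.5])
        assert np.allclose(post.values[0, 1], [1.0, 0.0])


def _two_label_posteriors(fg_map):
    fg = np.asarray(fg_map, dtype=float)
    values = np.stack([1.0 - fg, fg], axis=-1)
    return ss.PosteriorMaps(values=values, labels=np.array([1, 2]))


class TestGrowth:
    def test_barrier_blocks_the_flood(self):
        post = _two_label_posteriors([[1.0, 0.9, 0.7, 0.9, 1.0]])
        lm = np.array([[2, 0, 1, 0, 0]], dtype=np.int32)
        esp = ss.grow_extended_seeds(post, ss.SeedLabeling(lm), p_t=0.8)
        # indices 3-4 pass the threshold but are unreachable past the 0.7
        assert esp.members(2).tolist() == [0, 1]
        assert esp.members(1).tolist() == [2]

    def test_unobstructed_flood_fills_component(self):
        post = _two_label_posteriors(np.ones((4, 4)))
        lm = np.zeros((4, 4), dtype=np.int32)
        lm[0, 0] = 2
        lm[3, 3] = 1  # its own posterior is 0 everywhere: stays a seed
        esp = ss.grow_extended_seeds(post, ss.SeedLabeling(lm), p_t=0.8)
        assert esp.members(2).size == 15  # everything except the rival seed
        assert esp.members(1).tolist() == [15]

    def test_nothing_admitted_above_max_posterior(self):
        post = _two_label_posteriors(np.full((3, 3), 0.6))
        lm = np.zeros((3, 3), dtype=np.int32)
        lm[0, 0], lm[2, 2] = 2, 1
        esp = ss.grow_extended_seeds(post, ss.SeedLabeling(lm), p_t=0.7)
        assert not esp.grew
        assert np.array_equal(esp.label_map, lm)

    def test_matches_bfs_oracle_and_is_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            fg = rng.random((12, 12))
            lm = np.zeros((12, 12), dtype=np.int32)
            seed_idx = rng.choice(144, size=6, replace=False)
            lm.flat[seed_idx[:3]] = 1
            lm.flat[seed_idx[3:]] = 2
            seeds = ss.SeedLabeling(lm)
            post = _two_label_posteriors(fg)
            previous = None
            for p_t in (0.55, 0.7, 0.85):
                esp = ss.grow_extended_seeds(post, seeds, p_t=p_t)
                for j, lab in enumerate([1, 2]):
                    oracle = bfs_grow(post.values[..., j], lm == lab, p_t)
                    # a rival label's seed keeps its own label even when
                    # the flood passes through it
                    oracle &= (lm == 0) | (lm == lab)
                    assert np.array_equal(esp.label_map == lab, oracle)
                members = set(esp.members(2).tolist())
                if previous is not None:
                    assert members <= previous  # higher p_t grows less
                previous = members

    def test_conflicting_growth_is_excluded_but_seeds_survive(self):
        # both labels admissible everywhere: every non-seed voxel conflicts
        values = np.full((3, 3, 2), 0.5)
        post = ss.PosteriorMaps(values=values + [[[0.1, -0.1]]],
                                labels=np.array([1, 2]))
        lm = np.zeros((3, 3), dtype=np.int32)
        lm[0, 0], lm[2, 2] = 1, 2
        esp = ss.grow_extended_seeds(post, ss.SeedLabeling(lm), p_t=0.3)
        assert esp.conflict_voxels.size == 7
        assert esp.members(1).tolist() == [0]
        assert esp.members(2).tolist() == [8]

    def test_two_labels_high_threshold_never_conflict(self):
        rng = np.random.default_rng(9)
        post = _two_label_posteriors(rng.random((10, 10)))
        lm = np.zeros((10, 10), dtype=np.int32)
        lm[1, 1], lm[8, 8] = 2, 1
        esp = ss.grow_extended_seeds(post, ss.SeedLabeling(lm), p_t=0.6)
        assert esp.conflict_voxels.size == 0


class TestSparsePipeline:
    def test_no_growth_degenerates_to_plain_walker(self):
        spec = ss.PhantomSpec(image_size=(32, 32), rng_seed=3)
        image, _ = ss.make_block_phantom(spec)
        seeds = ss.place_block_seeds(spec, seeds_per_block=1,
                                     background_seeds=4, rng_seed=3)
        # a huge kernel width flattens the posteriors near 1/k, so the
        # growth threshold admits nothing
        result = ss.sparse_segment(image, seeds, sigma=1e9, p_t=0.9)
        assert not result.extended_seeds.grew
        seg, field = ss.random_walks_segment(image, seeds)
        assert np.array_equal(result.segmentation.label_map, seg.label_map)
        assert np.array_equal(result.probabilities.values, field.values)

    def test_expansion_covers_unseeded_blocks(self):
        spec = ss.PhantomSpec(image_size=(64, 64), rng_seed=5)
        image, gt = ss.make_block_phantom(spec)
        seeds = ss.place_block_seeds(spec,
                                     blocks_seeded=ss.FIVE_BLOCK_PATTERN,
                                     seeds_per_block=1, background_seeds=6,
                                     rng_seed=5)
        result = ss.sparse_segment(image, seeds)
        esp_fg = result.extended_seeds.label_map == ss.FOREGROUND_LABEL
        # the grown chain reaches into blocks that carry no user seed
        seeded_voxels = seeds.label_map == ss.FOREGROUND_LABEL
        assert esp_fg.sum() > 50 * seeded_voxels.sum()
        fg = result.segmentation.label_map == ss.FOREGROUND_LABEL
        assert ss.dice(gt, fg) > 0.95

    def test_seed_containment_and_disjointness(self):
        spec = ss.PhantomSpec(image_size=(48, 48), rng_seed=2)
        image, _ = ss.make_block_phantom(spec)
        seeds = ss.place_block_seeds(spec, seeds_per_block=2,
                                     background_seeds=6, rng_seed=2)
        esp = ss.sparse_segment(image, seeds).extended_seeds
        for lab in seeds.labels:
            assert set(seeds.indices(lab)) <= set(esp.members(lab))
        assert not (set(esp.members(1)) & set(esp.members(2)))
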