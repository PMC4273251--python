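"""Block matching: distances, adaptive thresholds, grouping contracts."""

import numpy as np
import pytest

from pgbm3d import (
    BlockSpec,
    MatchThreshold,
    block_distance,
    find_similar_blocks,
    find_similar_blocks_pilot,
    th_bm_level1,
    th_bm_level2,
)
from pgbm3d.block_matching import axis_lattice


class TestBlockSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"block_size": 1},
            {"step": 0},
            {"step": 9},
            {"max_group": 3},
            {"max_group": 0},
            {"search_radius": -1},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BlockSpec(**kwargs)


class TestDistance:
    def test_identical_blocks(self):
        b = np.arange(16.0).reshape(4, 4)
        assert block_distance(b, b) == 0.0

    def test_constant_offset(self):
        b = np.zeros((2, 2))
        assert block_distance(b, b + 3.0) == 9.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            block_distance(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_pure_noise_distance_is_twice_the_variance(self, rng):
        """Bienayme: two independent noise blocks differ by 2*sigma^2/pixel."""
        sigma = 1.5
        dists = [
            block_distance(rng.normal(0, sigma, (8, 8)), rng.normal(0, sigma, (8, 8)))
            for _ in range(2000)
        ]
        assert np.mean(dists) == pytest.approx(2 * sigma**2, rel=0.05)


class TestThresholds:
    def test_level1_values(self):
        assert th_bm_level1(0.0, 900.0) == 900.0
        assert th_bm_level1(50.0, 900.0) == 1000.0
        assert th_bm_level1(1.0, 0.0) == 2.0

    def test_level2_values(self):
        assert th_bm_level2(0.0, 900.0) == 900.0
        assert th_bm_level2(100.0, 900.0, 0.3) == 960.0

    def test_reduction_one_reproduces_level1(self):
        assert th_bm_level2(37.0, 11.0, 1.0) == th_bm_level1(37.0, 11.0)

    @pytest.mark.parametrize("args", [(-1.0, 0.0), (0.0, -1.0)])
    def test_negative_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            th_bm_level1(*args)
        with pytest.raises(ValueError):
            th_bm_level2(*args)

    def test_match_threshold_object_dispatches_by_level(self):
        assert MatchThreshold(50.0, 900.0, level=1).value() == 1000.0
        assert MatchThreshold(100.0, 900.0, level=2).value() == 960.0
        assert MatchThreshold(fixed_value=123.0).value() == 123.0


class TestLattice:
    def test_last_position_always_included(self):
        ps = axis_lattice(64, 8, 3)
        assert ps[0] == 0 and ps[-1] == 56
        ps = axis_lattice(65, 8, 3)
        assert ps[-1] == 57 and ps[-2] == 54


def _brute_force_group(image, ref, spec, threshold):
    """Exhaustive oracle with the same candidate-lattice definition."""
    h, w = image.shape
    b = spec.block_size
    th = threshold.value()
    rows = [p for p in axis_lattice(h, b, spec.step) if abs(p - ref[0]) <= spec.search_radius]
    cols = [p for p in axis_lattice(w, b, spec.step) if abs(p - ref[1]) <= spec.search_radius]
    refblk = image[ref[0] : ref[0] + b, ref[1] : ref[1] + b]
    cands = []
    for r in rows:
        for c in cols:
            if (r, c) == tuple(ref):
                continue
            d = np.mean((image[r : r + b, c : c + b] - refblk) ** 2)
            if d <= th:
                cands.append((d, r * w + c, r, c))
    cands.sort()
    n = 1 << int(np.log2(min(1 + len(cands), spec.max_group)))
    coords = [tuple(ref)] + [(r, c) for _, _, r, c in cands[: n - 1]]
    dists = [0.0] + [d for d, _, _, _ in cands[: n - 1]]
    return coords, dists


class TestGrouping:
    def test_constant_image_groups_fill_up_with_reference_first(self):
        img = np.ones((32, 32))
        spec = BlockSpec(block_size=8, step=3, search_radius=10, max_group=8)
        g = find_similar_blocks(img, (9, 9), spec, MatchThreshold(0.0, 10.0))
        assert g.n_blocks == 8
        assert tuple(g.coords[0]) == (9, 9)
        assert g.distances[0] == 0.0

    def test_two_identical_patches_found_exactly(self, rng):
        """Noise-free image with two identical textured patches on a distinct
        background: at zero offset only those two positions group."""
        img = np.zeros((40, 40))
        patch = rng.uniform(50, 100, (8, 8))
        img[4:12, 4:12] = patch
        img[4:12, 28:36] = patch
        img[24:32, 8:16] = rng.uniform(150, 200, (8, 8))
        spec = BlockSpec(block_size=8, step=4, search_radius=30, max_group=16)
        g = find_similar_blocks(img, (4, 4), spec, MatchThreshold(0.0, 0.0))
        assert {tuple(c) for c in g.coords} == {(4, 4), (4, 28)}

    def test_reference_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            find_similar_blocks(np.zeros((16, 16)), (10, 0), BlockSpec(), MatchThreshold())

    def test_equals_brute_force_on_small_image(self, rng):
        img = rng.uniform(0, 100, (32, 32)).round(1)
        spec = BlockSpec(block_size=8, step=3, search_radius=12, max_group=16)
        th = MatchThreshold(sigma_eta_sq=100.0, th_offset=900.0, level=1)
        for ref in [(0, 0), (9, 6), (24, 24), (3, 21)]:
            g = find_similar_blocks(img, ref, spec, th)
            coords, dists = _brute_force_group(img, ref, spec, th)
            assert [tuple(c) for c in g.coords] == coords
            np.testing.assert_allclose(g.distances, dists, atol=1e-12)

    def test_group_size_is_power_of_two_and_distances_sorted(self, rng):
        img = rng.uniform(0, 50, (48, 48))
        spec = BlockSpec(block_size=8, step=3, search_radius=19, max_group=16)
        for ref in [(0, 0), (12, 30), (40, 40)]:
            g = find_similar_blocks(img, ref, spec, MatchThreshold(200.0, 900.0))
            assert g.n_blocks & (g.n_blocks - 1) == 0
            assert np.all(np.diff(g.distances) >= 0)

    def test_raising_offset_never_shrinks_group(self, rng):
        img = rng.uniform(0, 60, (32, 32))
        spec = BlockSpec(block_size=8, step=3, search_radius=10, max_group=16)
        sizes = [
            find_similar_blocks(img, (12, 12), spec, MatchThreshold(0.0, off)).n_blocks
            for off in (0.0, 50.0, 500.0, 5000.0)
        ]
        assert sizes == sorted(sizes)

    def test_zero_noise_zero_offset_matches_only_exact_replicas(self):
        img = np.zeros((24, 24))
        img[0:8, 0:8] = img[0:8, 12:20] = np.arange(64.0).reshape(8, 8)
        img[12:20, 0:8] = 7.0
        spec = BlockSpec(block_size=8, step=4, search_radius=20, max_group=16)
        g = find_similar_blocks(img, (0, 0), spec, MatchThreshold(0.0, 0.0))
        assert {tuple(c) for c in g.coords} == {(0, 0), (0, 12)}


class TestPilotMatching:
    def test_pilot_equals_noisy_reduces_to_single_image_matching(self, rng):
        img = rng.uniform(0, 80, (32, 32))
        spec = BlockSpec(block_size=8, step=3, search_radius=10, max_group=8)
        th = MatchThreshold(20.0, 900.0, level=2)
        gn, gp = find_similar_blocks_pilot(img, img, (6, 6), spec, th)
        g = find_similar_blocks(img, (6, 6), spec, th)
        assert [tuple(c) for c in gn.coords] == [tuple(c) for c in g.coords]

    def test_both_stacks_share_coordinates(self, rng):
        noisy = rng.uniform(0, 80, (32, 32))
        pilot = noisy + rng.normal(0, 1, noisy.shape)
        spec = BlockSpec(block_size=8, step=3, search_radius=10, max_group=8)
        gn, gp = find_similar_blocks_pilot(noisy, pilot, (6, 6), spec, MatchThreshold(1.0, 900.0, level=2))
        np.testing.assert_array_equal(gn.coords, gp.coords)
        # and each stack really comes from its own image
        r, c = gn.coords[1]
        np.testing.assert_array_equal(gn.stack[:, :, 1], noisy[r : r + 8, c : c + 8])
        np.testing.assert_array_equal(gp.stack[:, :, 1], pilot[r : r + 8, c : c + 8])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            find_similar_blocks_pilot(
                np.zeros((16, 16)), np.zeros((16, 17)), (0, 0), BlockSpec(), MatchThreshold()
            )

    def test_cleaner_pilot_finds_at_least_as_many_true_replicates(self, rng):
        """Matching on a low-noise pilot recovers replicate positions that
        noise obscures at level 1."""
        base = rng.uniform(20, 40, (8, 8))
        truth = np.zeros((24, 48))
        positions = [(8, j) for j in range(0, 48 - 8 + 1, 8)]
        for r, c in positions:
            truth[r : r + 8, c : c + 8] = base
        noise = rng.normal(0, 6.0, truth.shape)
        noisy = truth + noise
        pilot = truth + 0.1 * noise
        spec = BlockSpec(block_size=8, step=8, search_radius=48, max_group=8)
        th1 = MatchThreshold(36.0, 40.0, level=1)
        th2 = MatchThreshold(36.0, 40.0, level=2, reduction=0.01)
        g1 = find_similar_blocks(noisy, (8, 0), spec, th1)
        g2, _ = find_similar_blocks_pilot(noisy, pilot, (8, 0), spec, th2)
        true_set = set(positions)
        hits1 = sum(tuple(c) in true_set for c in g1.coords)
        hits2 = sum(tuple(c) in true_set for c in g2.coords)
        assert hits2 >= hits1
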