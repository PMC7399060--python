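import numpy as np
import pytest
from scipy import ndimage

from neurimine.mining import (IterationConfig, MiningConfig, adaptive_threshold,
                              dice, grow_region, prune_skeleton_branches,
                              refine_labels, run_iterations, seed_region,
                              skeletonize)
from neurimine.pseudolabel import LabelConfig, build_labels, rasterize_cylinders
from neurimine.segnet import NetworkConfig, TrainConfig
from neurimine.stackio import LabelMask, ProbabilityMap


def _prob(arr):
    return ProbabilityMap(values=np.asarray(arr, dtype=np.float32))


def _mask(arr):
    return LabelMask(values=np.asarray(arr, dtype=bool))


def _axial_tube_mask(shape, length, width=1):
    m = np.zeros(shape, dtype=bool)
    m[shape[0] // 2 : shape[0] // 2 + width,
      shape[1] // 2 : shape[1] // 2 + width, :length] = True
    return m


class TestSeedRegion:
    def test_uniform_low_map_gives_empty_seed(self):
        assert seed_region(_prob(np.full((8, 8, 8), 0.4))).count() == 0

    def test_small_object_filter_boundary_at_200_voxels(self):
        shape = (8, 8, 256)
        for n, expect in ((199, 0), (200, 200)):
            p = np.full(shape, 0.1, dtype=np.float32)
            p[_axial_tube_mask(shape, n)] = 0.9
            assert seed_region(_prob(p)).count() == expect

    def test_only_large_component_survives(self):
        shape = (12, 12, 600)
        p = np.full(shape, 0.1, dtype=np.float32)
        p[2, 2, :500] = 0.9  # 500-voxel tube
        p[8, 8, :150] = 0.9  # 150-voxel tube, separated
        seeds = seed_region(_prob(p))
        lab, n = ndimage.label(seeds.values, structure=np.ones((3, 3, 3)))
        assert n == 1 and seeds.count() == 500

    def test_zero_min_object_equals_plain_argmax(self, rng):
        p = rng.random((10, 10, 10)).astype(np.float32)
        seeds = seed_region(_prob(p), MiningConfig(min_object_voxels=0))
        assert np.array_equal(seeds.values, p > 0.5)


class TestAdaptiveThreshold:
    def test_constant_neighborhood_returns_it(self):
        p = np.full((9, 9, 9), 0.3, dtype=np.float32)
        seed = np.zeros((9, 9, 9), dtype=bool)
        seed[4, 4, 4] = True
        p[4, 4, 4] = 0.99
        assert adaptive_threshold(_mask(seed), _prob(p)) == pytest.approx(0.3)

    def test_shell_neighborhood_has_124_offsets(self):
        assert MiningConfig().thre_neighborhood.shape == (124, 3)

    def test_matches_brute_force_shell_enumeration(self, rng):
        p = rng.random((7, 7, 7)).astype(np.float32)
        seed = np.zeros((7, 7, 7), dtype=bool)
        seed[3, 3, 3] = seed[3, 3, 4] = True
        shell = set()
        for v in np.argwhere(seed):
            for off in MiningConfig().thre_neighborhood:
                q = tuple(v + off)
                if all(0 <= q[i] < 7 for i in range(3)) and not seed[q]:
                    shell.add(q)
        expected = np.mean([p[q] for q in shell])
        got = adaptive_threshold(_mask(seed), _prob(p))
        assert got == pytest.approx(expected, abs=1e-6)

    def test_empty_seed_rejected(self):
        with pytest.raises(ValueError, match="empty seed"):
            adaptive_threshold(_mask(np.zeros((5, 5, 5))), _prob(np.zeros((5, 5, 5))))


def _flood_fill_oracle(seed, prob, thre, struct):
    """Independent brute-force BFS over {s(v) > thre} starting from the seed."""
    offsets = np.argwhere(struct) - 1
    offsets = [tuple(o) for o in offsets if tuple(o) != (0, 0, 0)]
    region = seed.copy()
    frontier = [tuple(v) for v in np.argwhere(seed)]
    shape = seed.shape
    while frontier:
        v = frontier.pop()
        for o in offsets:
            q = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
            if not all(0 <= q[i] < shape[i] for i in range(3)):
                continue
            if not region[q] and prob[q] > thre:
                region[q] = True
                frontier.append(q)
    return region


class TestGrowRegion:
    def test_thre_one_returns_seed_unchanged(self, rng):
        seed = rng.random((8, 8, 8)) < 0.05
        p = rng.random((8, 8, 8)).astype(np.float32)
        grown = grow_region(_mask(seed), _prob(p), 1.0)
        assert np.array_equal(grown.values, seed)

    def test_full_probability_map_floods_entire_volume(self):
        seed = np.zeros((6, 6, 6), dtype=bool)
        seed[0, 0, 0] = True
        grown = grow_region(_mask(seed), _prob(np.ones((6, 6, 6))), 0.5)
        assert grown.values.all()

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        from neurimine.mining import _growth_structure
        struct = _growth_structure(connectivity)
        rng = np.random.default_rng(connectivity)
        for trial in range(20):
            p = rng.random((16, 16, 16)).astype(np.float32)
            seed = rng.random((16, 16, 16)) < 0.01
            thre = float(rng.uniform(0.2, 0.9))
            got = grow_region(_mask(seed), _prob(p), thre,
                              MiningConfig(grow_neighborhood=connectivity))
            want = _flood_fill_oracle(seed, p, thre, struct)
            assert np.array_equal(got.values, want)

    def test_growth_contains_seed_and_is_monotone_in_thre(self, rng):
        p = rng.random((12, 12, 12)).astype(np.float32)
        seed = rng.random((12, 12, 12)) < 0.02
        low = grow_region(_mask(seed), _prob(p), 0.3)
        high = grow_region(_mask(seed), _prob(p), 0.7)
        assert np.all(low.values[seed]) and np.all(high.values[seed])
        assert np.all(low.values[high.values])  # lower threshold grows a superset


class TestSkeletonize:
    def test_empty_mask_gives_empty_skeleton(self):
        assert len(skeletonize(_mask(np.zeros((6, 6, 6))))) == 0

    def test_thin_axial_line_unchanged(self):
        m = np.zeros((5, 5, 20), dtype=bool)
        m[2, 2, 2:18] = True
        pts = skeletonize(_mask(m))
        assert {tuple(p) for p in pts} == {tuple(p) for p in np.argwhere(m)}

    def test_tube_skeleton_stays_near_centerline(self, straight_tube):
        pts = skeletonize(straight_tube.mask)
        lab, n = ndimage.label(straight_tube.mask.values, np.ones((3, 3, 3)))
        assert n == 1 and len(pts) > 0
        center = straight_tube.centerlines[0]
        d = np.sqrt((((pts[:, None, :] - center[None, :, :]) ** 2).sum(2)).min(1))
        assert d.max() <= 2.0


class TestPruneBranches:
    def test_straight_line_without_junction_unchanged(self):
        pts = np.array([[2, 2, x] for x in range(12)])
        out = prune_skeleton_branches(pts, MiningConfig(min_branch_nodes=5))
        assert len(out) == 12

    def test_short_stub_on_t_junction_removed(self):
        # long bar so its end-to-junction paths exceed the prune length;
        # in 26-adjacency the stub's base voxel is itself a junction and stays
        bar = [[2, 2, x] for x in range(21)]
        stub = [[2, 3, 10], [2, 4, 10], [2, 5, 10]]
        out = {tuple(p) for p in prune_skeleton_branches(
            np.array(bar + stub), MiningConfig(min_branch_nodes=5))}
        assert {tuple(p) for p in bar} <= out
        assert (2, 4, 10) not in out and (2, 5, 10) not in out

    def test_idempotent(self, rng):
        pts = np.unique(rng.integers(0, 6, size=(40, 3)), axis=0)
        cfg = MiningConfig(min_branch_nodes=4)
        once = prune_skeleton_branches(pts, cfg)
        twice = prune_skeleton_branches(once, cfg)
        assert np.array_equal(np.sort(once, axis=0), np.sort(twice, axis=0))


class TestRefineLabels:
    def test_all_background_map_gives_empty_labels(self):
        assert refine_labels(_prob(np.full((16, 16, 16), 0.1))).count() == 0

    def test_confident_tube_relabels_most_of_centerline(self):
        shape = (16, 16, 64)
        line = np.array([[8, 8, x] for x in range(4, 60)])
        tube = rasterize_cylinders(line, 2, shape)
        p = np.where(tube.values, 0.9, 0.1).astype(np.float32)
        labels = refine_labels(_prob(p))
        covered = np.mean([labels.values[z, y, x] for z, y, x in line])
        assert covered >= 0.95

    def test_growth_bridges_dim_gap_between_seed_halves(self):
        shape = (16, 16, 64)
        line = np.array([[8, 8, x] for x in range(2, 62)])
        tube = rasterize_cylinders(line, 2, shape).values
        gap = np.zeros(shape, dtype=bool)
        gap[:, :, 28:36] = True
        p = np.full(shape, 0.05, dtype=np.float32)
        p[tube & ~gap] = 0.9
        p[tube & gap] = 0.4  # dim stretch: below argmax, above local background
        seeds = seed_region(_prob(p))
        _, n_seed = ndimage.label(seeds.values, np.ones((3, 3, 3)))
        labels = refine_labels(_prob(p))
        _, n_final = ndimage.label(labels.values, np.ones((3, 3, 3)))
        assert n_seed == 2 and n_final == 1


class TestDice:
    def test_identical_masks_give_one_and_disjoint_zero(self, rng):
        a = rng.random((8, 8, 8)) < 0.3
        assert dice(_mask(a), _mask(a)) == 1.0
        assert dice(_mask(a), _mask(~a)) == 0.0
        assert dice(_mask(np.zeros((8, 8, 8))), _mask(np.zeros((8, 8, 8)))) == 1.0


def _micro_setup(small_phantom):
    labels0 = build_labels(small_phantom.traced, small_phantom.image.shape,
                           LabelConfig(min_component_nodes=3))
    ncfg = NetworkConfig(base_channels=2, n_res_modules=3, input_patch=16)
    tcfg = TrainConfig(patch_size=16, max_epochs=6, patches_per_epoch=6,
                       lr=0.05, lr_halving_epochs=8, seed=0)
    return labels0, ncfg, tcfg


class TestRunIterations:
    def test_zero_convergence_dice_stops_after_one_iteration(self, small_phantom):
        labels0, ncfg, tcfg = _micro_setup(small_phantom)
        _, _, trail = run_iterations(small_phantom.image, labels0, ncfg, tcfg,
                                     MiningConfig(min_object_voxels=50),
                                     IterationConfig(max_iterations=4,
                                                     convergence_dice=0.0))
        assert len(trail.label_masks) == 1

    def test_iteration_cap_respected_when_never_converging(self, small_phantom,
                                                           monkeypatch):
        # stub the expensive stages: each iteration predicts a different tube,
        # so successive label generations never reach the convergence Dice
        import neurimine.mining as mining_mod
        labels0, ncfg, tcfg = _micro_setup(small_phantom)
        state = {"k": 0}

        def fake_train(model, patches, cfg, loss_cfg=None, rng=None):
            return model, [0.5]

        def fake_predict(model, image, patch_size=None):
            state["k"] += 1
            p = np.full(image.shape, 0.1, dtype=np.float32)
            p[10 + state["k"] * 4 : 12 + state["k"] * 4, 8:10, :] = 0.9
            return ProbabilityMap(values=p)

        monkeypatch.setattr(mining_mod, "train", fake_train)
        monkeypatch.setattr(mining_mod, "predict", fake_predict)
        _, final, trail = run_iterations(small_phantom.image, labels0, ncfg, tcfg,
                                         MiningConfig(min_object_voxels=10),
                                         IterationConfig(max_iterations=3,
                                                         convergence_dice=1.0))
        assert len(trail.label_masks) == 3
        assert np.array_equal(final.values, trail.label_masks[-1].values)

    def test_reproducible_under_fixed_seed(self, small_phantom):
        labels0, ncfg, tcfg = _micro_setup(small_phantom)
        runs = []
        for _ in range(2):
            _, final, _ = run_iterations(small_phantom.image, labels0, ncfg, tcfg,
                                         MiningConfig(min_object_voxels=50),
                                         IterationConfig(max_iterations=1), seed=5)
            runs.append(final.values)
        assert np.array_equal(runs[0], runs[1])


def test_iteration_config_validation():
    with pytest.raises(ValueError):
        IterationConfig(max_iterations=0)
    with pytest.raises(ValueError):
        MiningConfig(grow_neighborhood=8)
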