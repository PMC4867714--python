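"""Grow-cut automaton: seeding, attack rule, evolution and OD segmentation."""

import numpy as np
import pytest
from skimage import measure

from odseg import (
    Config,
    InvalidSeedError,
    SeedSpec,
    attack_strength,
    evaluate_masks,
    evolve,
    generate,
    init_grid,
    preprocess,
    segment_od,
    PhantomSpec,
)
from odseg.growcut import GrowCutGrid, step

from _oracles import chebyshev_nearest_partition, growcut_bruteforce, random_seeded_grid


class TestInitGrid:
    def test_eleven_by_eleven_seed_geometry(self):
        grid = init_grid(np.full((11, 11), 0.5), SeedSpec(5, 5, 1.0, 5.0))
        assert (grid.labels == 1).sum() == 5  # center plus 4-neighbors
        assert grid.labels[5, 5] == 1 and grid.labels[4, 5] == 1
        assert grid.labels[0, 0] == -1  # corner: distance sqrt(50) >= 5
        assert grid.labels[5, 8] == 0  # annulus cell at distance 3
        assert np.all(grid.strengths[grid.labels != 0] == 1.0)
        assert np.all(grid.strengths[grid.labels == 0] == 0.0)

    def test_seeds_can_cover_whole_grid(self):
        grid = init_grid(np.zeros((3, 3)), SeedSpec(0, 0, 1.5, 1.9))
        assert not (grid.labels == 0).any()

    def test_overlapping_radii_rejected(self):
        with pytest.raises(InvalidSeedError):
            SeedSpec(5, 5, 5.0, 5.0)

    def test_empty_background_rejected(self):
        with pytest.raises(InvalidSeedError):
            init_grid(np.zeros((5, 5)), SeedSpec(2, 2, 1.0, 50.0))


class TestAttackStrength:
    def test_equal_intensities_attack_at_full_force(self):
        assert attack_strength(0.3, 0.3) == 1.0

    def test_maximal_difference_zeroes_the_attack(self):
        assert attack_strength(0, 255, c_max=255) == 0.0

    def test_worked_eight_bit_example(self):
        assert attack_strength(100, 151, c_max=255) == pytest.approx(0.8)


class TestEvolve:
    def test_fully_seeded_grid_is_stable(self):
        grid = init_grid(np.zeros((3, 3)), SeedSpec(0, 0, 1.5, 1.9))
        grid, used = evolve(grid, max_iter=10)
        assert used == 1 and grid.converged
        assert grid.last_changed == 0

    def test_uniform_grid_gives_chebyshev_voronoi(self):
        labels = np.zeros((7, 7), dtype=np.int8)
        strengths = np.zeros((7, 7))
        labels[3, 3] = 1
        strengths[3, 3] = 1.0
        border = np.ones((7, 7), dtype=bool)
        border[1:-1, 1:-1] = False
        labels[border] = -1
        strengths[border] = 1.0
        grid = GrowCutGrid(labels.copy(), strengths.copy(), np.full((7, 7), 0.4))
        grid, _ = evolve(grid, 50)
        expected = chebyshev_nearest_partition(
            (7, 7), [(3, 3)], [tuple(p) for p in np.argwhere(border)]
        )
        assert grid.converged
        np.testing.assert_array_equal(grid.labels, expected)

    def test_step_image_boundary_lands_on_intensity_edge(self):
        values = np.full((7, 8), 0.2)
        values[:, 4:] = 0.8
        labels = np.zeros((7, 8), dtype=np.int8)
        strengths = np.zeros((7, 8))
        labels[3, 0], strengths[3, 0] = 1, 1.0
        labels[3, 7], strengths[3, 7] = -1, 1.0
        grid, _ = evolve(GrowCutGrid(labels, strengths, values), 100)
        assert grid.converged
        assert np.all(grid.labels[:, :4] == 1)
        assert np.all(grid.labels[:, 4:] == -1)

    def test_matches_bruteforce_on_random_grids(self, rng):
        for _ in range(25):
            values, labels, strengths = random_seeded_grid(rng)
            grid = GrowCutGrid(labels.copy(), strengths.copy(), values)
            grid, _ = evolve(grid, 200)
            ref_labels, ref_strengths, ref_conv = growcut_bruteforce(
                values, labels, strengths, max_iter=200
            )
            assert ref_conv and grid.converged
            np.testing.assert_array_equal(grid.labels, ref_labels)
            np.testing.assert_allclose(grid.strengths, ref_strengths)

    def test_strengths_never_decrease_and_seeds_never_change(self, rng):
        values, labels, strengths = random_seeded_grid(rng, 8, 8)
        seed_mask = labels != 0
        seed_labels = labels[seed_mask].copy()
        grid = GrowCutGrid(labels.copy(), strengths.copy(), values)
        for _ in range(30):
            before = grid.strengths.copy()
            changed = step(grid)
            assert np.all(grid.strengths >= before - 1e-15)
            np.testing.assert_array_equal(grid.labels[seed_mask], seed_labels)
            assert np.all(grid.strengths[seed_mask] == 1.0)
            if changed == 0:
                break
        assert changed == 0

    def test_no_undefined_labels_at_convergence(self, rng):
        values, labels, strengths = random_seeded_grid(rng, 10, 10)
        grid, _ = evolve(GrowCutGrid(labels, strengths, values), 500)
        assert grid.converged
        assert not (grid.labels == 0).any()


class TestSegmentOd:
    def test_clean_phantom_growcut_dice(self, clean_phantom, clean_detection):
        _, truth, _ = clean_phantom
        det, pre = clean_detection
        seg = segment_od(pre.i_sc, det)
        assert seg.converged
        assert evaluate_masks(seg.mask, truth).dice >= 0.90

    def test_mask_is_single_component_containing_center(self, clean_phantom, clean_detection):
        _, _, _ = clean_phantom
        det, pre = clean_detection
        seg = segment_od(pre.i_sc, det)
        comp = measure.label(seg.mask, connectivity=2)
        assert comp[det.native_center_row, det.native_center_col] != 0
        assert comp.max() == 1

    def test_disc_near_border_clips_background_seeds(self):
        # A disc whose 2.5 r background ring falls partly outside the image.
        spec = PhantomSpec(disc_center=(60, 282), disc_radius=36, rng_seed=9)
        img, truth = generate(spec)
        from odseg import detect_od

        det = detect_od(img)
        seg = segment_od(preprocess(img).i_sc, det)
        assert evaluate_masks(seg.mask, truth).dice >= 0.80
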