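"""SuperPCA reduction, superpixel segmentation, patch extraction."""

import numpy as np
import pytest
from scipy import ndimage

from canopyhsi.io import HyperspectralCube, LabelMap, SpectralAxis
from canopyhsi.superpca import (PatchSet, ReducedCube, SuperpixelMap,
                                boundary_recall, extract_patches, first_pc_image,
                                segment_superpixels, superpca_reduce,
                                undersegmentation_error)


@pytest.fixture(scope="module")
def random_cube():
    rng = np.random.default_rng(12)
    axis = SpectralAxis(np.linspace(400, 1000, 5))
    return HyperspectralCube(rng.random((8, 8, 5)), axis)


class TestFirstPC:
    def test_rank_one_cube_recovers_coefficients(self):
        rng = np.random.default_rng(1)
        direction = rng.random(6)
        coefs = rng.random((10, 10))
        values = 0.1 + coefs[..., None] * direction
        cube = HyperspectralCube(values / values.max(), SpectralAxis(np.linspace(400, 1000, 6)))
        image = first_pc_image(cube)
        # PC1 image is an affine function of the construction coefficients
        flat_c = (coefs - coefs.min()) / (coefs.max() - coefs.min())
        agreement = abs(np.corrcoef(image.ravel(), flat_c.ravel())[0, 1])
        assert agreement == pytest.approx(1.0, abs=1e-10)

    def test_matches_eigendecomposition(self, random_cube):
        image = first_pc_image(random_cube)
        pixels = random_cube.values.reshape(-1, 5)
        cov = np.cov(pixels, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(cov)
        pc1 = eigvecs[:, -1]
        scores = (pixels - pixels.mean(axis=0)) @ pc1
        scores = (scores - scores.min()) / (scores.max() - scores.min())
        flat = image.ravel()
        assert (np.allclose(flat, scores, atol=1e-10)
                or np.allclose(flat, 1 - scores, atol=1e-10))

    def test_two_class_scene_separates(self, mosaic_scene):
        cube, labels, _, _ = mosaic_scene
        image = first_pc_image(cube)
        veg = image[labels.labels > 0]
        bg = image[labels.labels == 0]
        overall = np.concatenate([veg, bg])
        between = (veg.size * (veg.mean() - overall.mean()) ** 2
                   + bg.size * (bg.mean() - overall.mean()) ** 2) / overall.size
        within = (veg.size * veg.var() + bg.size * bg.var()) / overall.size
        assert between > within

    def test_constant_cube_rejected(self, axis204):
        cube = HyperspectralCube(np.full((4, 4, 204), 0.4), axis204)
        with pytest.raises(ValueError, match="constant"):
            first_pc_image(cube)


class TestSegmentation:
    def test_single_segment(self):
        image = np.random.default_rng(0).random((10, 10))
        seg = segment_superpixels(image, 1)
        assert seg.n_segments == 1 and np.all(seg.segment_ids == 0)

    def test_constant_image_balanced_connected(self):
        seg = segment_superpixels(np.full((30, 30), 0.5), 4)
        assert seg.n_segments == 4
        sizes = np.bincount(seg.segment_ids.ravel())
        assert sizes.max() / sizes.min() < 3.0  # approximately equal areas
        for sid in range(4):
            _, n = ndimage.label(seg.segment_ids == sid)
            assert n == 1  # each segment connected

    def test_partition_property(self):
        image = np.random.default_rng(1).random((20, 20))
        seg = segment_superpixels(image, 7)
        assert seg.segment_ids.min() == 0
        assert np.array_equal(np.unique(seg.segment_ids), np.arange(seg.n_segments))

    def test_four_connectivity(self):
        image = np.random.default_rng(2).random((16, 16))
        seg = segment_superpixels(image, 6)
        for sid in range(seg.n_segments):
            _, n = ndimage.label(seg.segment_ids == sid)  # 4-connected structure
            assert n == 1

    def test_hard_border_plots_recovered(self):
        """On a step image with strong boundaries, segmentation adheres to
        the true plot borders."""
        rng = np.random.default_rng(3)
        truth = np.zeros((40, 40), int)
        truth[:20, 20:] = 1
        truth[20:, :20] = 2
        truth[20:, 20:] = 3
        image = truth / 3.0 + rng.normal(0, 0.02, truth.shape)
        seg = segment_superpixels(image, 4)
        assert boundary_recall(seg.segment_ids, truth) >= 0.9
        assert undersegmentation_error(seg.segment_ids, truth) < 0.05

    def test_mosaic_pc1_oversegmentation_respects_borders(self, mosaic_scene):
        """With hard vegetation/background contrast the dominant boundary is
        recovered even on a noisy PC1 image."""
        cube, labels, _, _ = mosaic_scene
        image = first_pc_image(cube)
        seg = segment_superpixels(image, 8)
        bg_truth = (labels.labels == 0).astype(int)
        assert boundary_recall(seg.segment_ids, bg_truth, tol=2) >= 0.9

    def test_slic_fallback(self):
        gx, gy = np.meshgrid(np.linspace(0, 1, 20), np.linspace(0, 1, 20))
        image = gx + gy  # smooth gradient segments cleanly
        seg = segment_superpixels(image, 5, method="slic")
        assert seg.segment_ids.shape == (20, 20)
        assert seg.n_segments >= 2

    def test_nonfinite_rejected(self):
        image = np.full((5, 5), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            segment_superpixels(image, 2)


class TestSuperPCAReduce:
    def test_single_segment_equals_global_pca(self, random_cube):
        segmap = SuperpixelMap(np.zeros((8, 8), dtype=np.int32))
        reduced = superpca_reduce(random_cube, segmap, 3)
        pixels = random_cube.values.reshape(-1, 5)
        centered = pixels - pixels.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        expected = pixels @ vt[:3].T
        got = reduced.values.reshape(-1, 3)
        for j in range(3):
            assert (np.allclose(got[:, j], expected[:, j], atol=1e-8)
                    or np.allclose(got[:, j], -expected[:, j], atol=1e-8))

    def test_full_rank_reconstruction(self, random_cube):
        """With b = D and one segment the projection is an orthonormal
        change of basis: the stored loadings invert it exactly."""
        segmap = SuperpixelMap(np.zeros((8, 8), dtype=np.int32))
        reduced = superpca_reduce(random_cube, segmap, 5)
        pixels = random_cube.values.reshape(-1, 5)
        loadings = reduced.provenance["loadings"][0]
        back = reduced.values.reshape(-1, 5) @ loadings.T
        np.testing.assert_allclose(back, pixels, atol=1e-10)

    def test_centered_variant_reconstructs_centered_data(self, random_cube):
        segmap = SuperpixelMap(np.zeros((8, 8), dtype=np.int32))
        reduced = superpca_reduce(random_cube, segmap, 5, center=True)
        pixels = random_cube.values.reshape(-1, 5)
        centered = pixels - pixels.mean(axis=0)
        scores = reduced.values.reshape(-1, 5)
        # norms preserved by the orthonormal change of basis
        np.testing.assert_allclose(np.linalg.norm(scores, axis=1),
                                   np.linalg.norm(centered, axis=1), atol=1e-8)

    def test_two_segments_match_independent_pca(self, random_cube):
        seg = np.zeros((8, 8), dtype=np.int32)
        seg[:, 4:] = 1
        reduced = superpca_reduce(random_cube, SuperpixelMap(seg), 2)
        pixels = random_cube.values.reshape(-1, 5)
        flat_seg = seg.ravel()
        for sid in (0, 1):
            members = np.flatnonzero(flat_seg == sid)
            block = pixels[members]
            _, _, vt = np.linalg.svd(block - block.mean(axis=0), full_matrices=False)
            expected = block @ vt[:2].T
            got = reduced.values.reshape(-1, 2)[members]
            for j in range(2):
                assert (np.allclose(got[:, j], expected[:, j], atol=1e-8)
                        or np.allclose(got[:, j], -expected[:, j], atol=1e-8))

    def test_small_segment_falls_back_to_global(self, random_cube):
        seg = np.zeros((8, 8), dtype=np.int32)
        seg[0, 0] = 1  # single-pixel segment < b
        seg[0, 1] = 2
        seg[0, 2:] = 3
        _, idx = np.unique(seg, return_inverse=True)
        segmap = SuperpixelMap(idx.reshape(8, 8).astype(np.int32))
        reduced = superpca_reduce(random_cube, segmap, 4)
        assert np.all(np.isfinite(reduced.values))

    def test_b_out_of_range(self, random_cube):
        segmap = SuperpixelMap(np.zeros((8, 8), dtype=np.int32))
        with pytest.raises(ValueError):
            superpca_reduce(random_cube, segmap, 6)


class TestExtractPatches:
    def make_reduced(self, m=4, n=4, b=2):
        rng = np.random.default_rng(5)
        return ReducedCube(rng.random((m, n, b)), b)

    def test_patch_count_conservation(self):
        reduced = self.make_reduced()
        labels = LabelMap(np.ones((4, 4), dtype=np.int32), ["a"])
        patches = extract_patches(reduced, labels, 3)
        assert len(patches) == 16
        assert patches.patches.shape == (16, 3, 3, 2)

    def test_corner_padding_cell_count(self):
        reduced = self.make_reduced()
        lab = np.zeros((4, 4), dtype=np.int32)
        lab[0, 0] = 1
        patches = extract_patches(reduced, LabelMap(lab, ["a"]), 3)
        corner = patches.patches[0]
        padded_cells = (corner.sum(axis=2) == 0).sum()
        assert padded_cells == 5  # 3x3 window at (0,0): 5 out-of-image cells

    def test_interior_patch_is_raw_subarray(self):
        reduced = self.make_reduced(6, 6, 3)
        lab = np.zeros((6, 6), dtype=np.int32)
        lab[3, 3] = 2
        patches = extract_patches(reduced, LabelMap(lab, ["a", "b"]), 3)
        np.testing.assert_allclose(patches.patches[0],
                                   reduced.values[2:5, 2:5, :], rtol=1e-6)

    def test_center_value_matches_cube(self):
        reduced = self.make_reduced(5, 5, 2)
        lab = np.random.default_rng(0).integers(0, 3, (5, 5)).astype(np.int32)
        patches = extract_patches(reduced, LabelMap(lab, ["a", "b"]), 3)
        half = 1
        for patch, (r, c) in zip(patches.patches, patches.centers):
            np.testing.assert_allclose(patch[half, half], reduced.values[r, c], rtol=1e-6)

    def test_label_multiset_conserved(self):
        reduced = self.make_reduced(5, 5, 2)
        lab = np.random.default_rng(1).integers(0, 4, (5, 5)).astype(np.int32)
        patches = extract_patches(reduced, LabelMap(lab, list("abc")), 3)
        assert sorted(patches.labels) == sorted(lab[lab > 0])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            extract_patches(self.make_reduced(), LabelMap(np.ones((4, 4), np.int32), ["a"]), 4)

    def test_save_load_round_trip(self, tmp_path):
        reduced = self.make_reduced()
        labels = LabelMap(np.ones((4, 4), dtype=np.int32), ["a"])
        patches = extract_patches(reduced, labels, 3)
        patches.save(tmp_path / "ps.npz")
        back = PatchSet.load(tmp_path / "ps.npz")
        np.testing.assert_array_equal(back.patches, patches.patches)
        np.testing.assert_array_equal(back.labels, patches.labels)
        assert back.s == 3
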