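"""Preprocessing, automatic thresholds, nucleus segmentation, watershed split."""

import numpy as np
import pytest
from scipy import ndimage

from nucorg.image import ImageStack
from nucorg.nucseg import (
    compute_threshold,
    preprocess,
    segment_nuclei,
    split_touching,
)
from nucorg.phantom import PhantomSpec, generate_phantom

ISO = (0.25, 0.25, 0.25)


def stack(values, spacing=ISO):
    return ImageStack(np.asarray(values, float), spacing)


def two_valued_image(lo=10, hi=200, frac_hi=0.3, shape=(10, 10, 10), seed=0):
    rng = np.random.default_rng(seed)
    vals = np.full(shape, lo, float)
    n = int(np.prod(shape) * frac_hi)
    idx = rng.choice(np.prod(shape), n, replace=False)
    vals.ravel()[idx] = hi
    return vals


class TestPreprocess:
    def test_empty_step_list_is_identity(self):
        img = stack(two_valued_image())
        out = preprocess(img, [])
        assert np.array_equal(out.values, img.values)

    def test_gray_hole_fill_raises_dark_core(self):
        vals = np.zeros((14, 14, 14))
        vals[2:12, 2:12, 2:12] = 100.0  # bright cube
        vals[6:9, 6:9, 6:9] = 10.0      # dark core, not border-connected
        out = preprocess(stack(vals), ["gray_hole_fill"])
        assert np.all(out.values[6:9, 6:9, 6:9] == 100.0)
        # background untouched
        assert np.all(out.values[0] == 0.0)

    def test_median_restores_salt_and_pepper_interior(self):
        rng = np.random.default_rng(1)
        vals = np.full((12, 12, 12), 50.0)
        idx = rng.choice(12**3, 40, replace=False)
        vals.ravel()[idx] = rng.choice([0.0, 255.0], 40)
        out = preprocess(stack(vals), ["median(1)"])
        interior = out.values[2:-2, 2:-2, 2:-2]
        assert np.all(interior == 50.0)

    def test_unknown_step_rejected(self):
        with pytest.raises(ValueError, match="unknown preprocessing step"):
            preprocess(stack(np.zeros((5, 5, 5))), ["sharpen(2)"])


class TestThresholds:
    @pytest.mark.parametrize("method", ["otsu", "max_entropy"])
    def test_two_valued_image_separated_exactly(self, method):
        vals = two_valued_image()
        t = compute_threshold(stack(vals), method=method)
        assert 10 < t <= 200
        assert np.array_equal(vals > t, vals == 200)

    def test_max_entropy_matches_brute_force_kapur(self):
        rng = np.random.default_rng(2)
        vals = np.clip(rng.normal(80, 30, (16, 16, 16)), 0, 255)
        t = compute_threshold(stack(vals), method="max_entropy")
        # independent brute force over the same 256-bin histogram
        hist, edges = np.histogram(vals, bins=256)
        p = hist / hist.sum()
        best_h, best_t = -np.inf, None
        for cut in range(1, 256):
            w0, w1 = p[:cut].sum(), p[cut:].sum()
            if w0 <= 0 or w1 <= 0:
                continue
            q0 = p[:cut][p[:cut] > 0] / w0
            q1 = p[cut:][p[cut:] > 0] / w1
            h = -(q0 * np.log(q0)).sum() - (q1 * np.log(q1)).sum()
            if h > best_h:
                best_h, best_t = h, cut
        assert np.array_equal(vals > t, vals > edges[best_t] - 1e-9)

    def test_rats_straddles_sharp_edge(self):
        z, y, x = np.mgrid[:32, :32, :32]
        r = np.sqrt((z - 15.5) ** 2 + (y - 15.5) ** 2 + (x - 15.5) ** 2)
        vals = np.where(r <= 10, 200.0, 10.0)
        t = compute_threshold(stack(vals, (1, 1, 1)), method="rats")
        # gradient-weighted mean of edge values: explicit oracle
        grads = np.gradient(vals, 1.0, 1.0, 1.0)
        w = sum(g**2 for g in grads)
        expected = (w * vals).sum() / w.sum()
        assert t == pytest.approx(expected, rel=1e-12)
        assert 60 <= t <= 150  # straddles the edge midpoint ~105

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_threshold(stack(np.full((8, 8, 8), 7.0)), method="otsu")


class TestSegmentNuclei:
    def test_phantom_volume_recovered(self, clean_phantom):
        spec, channels, truth = clean_phantom
        result = segment_nuclei(channels["dna"], min_volume_um3=100,
                                preprocess_steps=["gray_hole_fill"])
        assert result.n_labels == 1
        true_vol = truth.nucleus_mask.sum() * spec.voxel_volume
        assert result.table.volume_um3.iloc[0] == pytest.approx(true_vol, rel=0.05)

    def test_two_tiled_nuclei_found(self):
        spec = PhantomSpec(grid_shape=(20, 56, 56), spacing=(0.37, 0.25, 0.25),
                           nucleus_semiaxes=(3.0, 5.0, 5.0), n_npb=0,
                           noise_gaussian=0.0, noise_poisson_gain=0.0, seed=3)
        channels, _ = generate_phantom(spec)
        dna = channels["dna"].values
        tiled = np.concatenate([dna, dna], axis=2)
        img = ImageStack(tiled, spec.spacing)
        result = segment_nuclei(img, min_volume_um3=100)
        assert result.n_labels == 2

    def test_border_truncated_nucleus_removed(self, clean_phantom):
        spec, channels, truth = clean_phantom
        # clip half the nucleus with the image boundary
        zc = int(np.argwhere(truth.nucleus_mask)[:, 0].mean())
        img = ImageStack(channels["dna"].values[zc:], spec.spacing)
        result = segment_nuclei(img, min_volume_um3=100, max_border_fraction=0.3)
        assert result.n_labels == 0

    def test_empty_result_warns_not_raises(self):
        vals = two_valued_image(shape=(8, 8, 8))
        with pytest.warns(UserWarning, match="no nuclear component"):
            result = segment_nuclei(stack(vals), min_volume_um3=1e9)
        assert result.n_labels == 0


def two_sphere_mask(dist_um=8.0, r_um=5.0, spacing=(0.37, 0.25, 0.25),
                    shape=(44, 96, 96), axis=2):
    grid = [np.arange(n) * s for n, s in zip(shape, spacing)]
    Z, Y, X = np.meshgrid(*grid, indexing="ij")
    center = np.array([g[-1] / 2 for g in grid])
    offset = np.zeros(3)
    offset[axis] = dist_um / 2
    c1, c2 = center - offset, center + offset
    d1 = (Z - c1[0]) ** 2 + (Y - c1[1]) ** 2 + (X - c1[2]) ** 2
    d2 = (Z - c2[0]) ** 2 + (Y - c2[1]) ** 2 + (X - c2[2]) ** 2
    return (d1 <= r_um**2) | (d2 <= r_um**2), (c1, c2)


class TestSplitTouching:
    def test_single_sphere_unchanged(self, sphere_mask):
        out = split_touching(sphere_mask, ISO)
        assert out.n_labels == 1
        assert np.array_equal(out.labels > 0, sphere_mask)

    def test_two_merged_spheres_split(self):
        mask, (c1, c2) = two_sphere_mask()
        _, n_before = ndimage.label(mask)
        assert n_before == 1  # genuinely merged
        out = split_touching(mask, (0.37, 0.25, 0.25))
        assert out.n_labels == 2
        spacing = np.array([0.37, 0.25, 0.25])
        l1 = out.labels[tuple((c1 / spacing).astype(int))]
        l2 = out.labels[tuple((c2 / spacing).astype(int))]
        assert l1 != l2 and l1 > 0 and l2 > 0

    def test_voxel_conservation_and_idempotence(self):
        mask, _ = two_sphere_mask()
        out = split_touching(mask, (0.37, 0.25, 0.25))
        assert (out.labels > 0).sum() == mask.sum()
        again = split_touching(out, h_um=1.0)
        assert again.n_labels == out.n_labels
        assert np.array_equal(again.labels > 0, out.labels > 0)
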