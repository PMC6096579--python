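"""EVF map, equal-volume fractions, radial profiles, d_max."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from nucorg.phantom import PhantomSpec, make_nucleus_mask, sample_spot_centers
from nucorg.radial import (
    RadialProfile,
    dmax,
    equal_volume_fractions,
    evf_map,
    radial_profile,
    spot_evf,
)

ISO = (0.25, 0.25, 0.25)


def profile_from_p(p):
    return RadialProfile(np.asarray(p, float), mode="intensity", spacing=ISO)


class TestEVFMap:
    def test_range_strictly_inside_unit_interval(self, sphere_mask):
        em = evf_map(sphere_mask, ISO)
        vals = em.values[sphere_mask]
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_boundary_voxel_low_center_high(self, sphere_mask):
        em = evf_map(sphere_mask, ISO)
        depth = em.depth[sphere_mask]
        vals = em.values[sphere_mask]
        assert vals[np.argmin(depth)] < 0.2
        assert vals[np.argmax(depth)] > 0.99

    def test_sphere_closed_form_at_half_radius(self):
        # continuous ball: EVF(r) = 1 - (r/R)^3; check at r = R/2 on a fine grid
        spec = PhantomSpec(grid_shape=(88, 88, 88), spacing=(0.125,) * 3,
                           nucleus_semiaxes=(5.0, 5.0, 5.0), n_npb=0, seed=1)
        mask = make_nucleus_mask(spec)
        em = evf_map(mask, spec.spacing)
        ctr = (np.array(mask.shape) - 1) // 2
        idx = (ctr[0], ctr[1], ctr[2] + 20)  # 20 voxels * 0.125 um = R/2
        assert em.values[idx] == pytest.approx(1 - 0.5**3, abs=0.02)

    def test_uniform_points_property_any_shape(self, ellipsoid_mask, ellipsoid_spec):
        em = evf_map(ellipsoid_mask, ellipsoid_spec.spacing)
        rng = np.random.default_rng(0)
        samp = rng.choice(em.values[ellipsoid_mask], 10_000)
        assert sps.kstest(samp, "uniform").statistic <= 0.03

    def test_monotone_in_depth(self, sphere_mask):
        em = evf_map(sphere_mask, ISO)
        d = em.depth[sphere_mask]
        v = em.values[sphere_mask]
        order = np.argsort(d, kind="stable")
        # strictly deeper voxels never get smaller EVF
        dv, vv = d[order], v[order]
        boundaries = np.flatnonzero(np.diff(dv) > 0)
        assert (vv[boundaries + 1] >= np.maximum.accumulate(vv)[boundaries] - 1e-12).all()

    def test_rejects_multi_component_mask(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[2:4, 2:4, 2:4] = True
        mask[7:9, 7:9, 7:9] = True
        with pytest.raises(ValueError, match="single connected"):
            evf_map(mask, ISO)


class TestEqualVolumeFractions:
    @pytest.mark.parametrize("n_extra, expected_sizes", [(0, {100}), (3, {100, 101})])
    def test_fraction_sizes(self, n_extra, expected_sizes):
        # synthetic EVF map over an abstract 1D-ish mask: (1000 + extra) voxels
        n = 1000 + n_extra
        mask = np.zeros((1, 1, n + 2), bool)
        mask[0, 0, 1 : n + 1] = True
        em = evf_map(mask, (1, 1, 1))
        labels = equal_volume_fractions(em, 10)
        _, counts = np.unique(labels[labels > 0], return_counts=True)
        assert set(counts) == expected_sizes

    def test_mean_evf_linear_in_fraction_index(self, sphere_mask):
        em = evf_map(sphere_mask, ISO)
        F = 50
        labels = equal_volume_fractions(em, F)
        means = np.array([
            em.values[labels == k].mean() for k in range(1, F + 1)
        ])
        assert (np.diff(means) > 0).all()
        expected = (np.arange(1, F + 1) - 0.5) / F
        assert np.abs(means - expected).max() <= 1.0 / F + 0.01

    def test_clamps_large_F_with_warning(self, sphere_mask):
        em = evf_map(sphere_mask, ISO)
        with pytest.warns(UserWarning, match="clamping"):
            labels = equal_volume_fractions(em, em.n_voxels + 5)
        assert labels.max() == em.n_voxels


class TestRadialProfile:
    def test_constant_intensity_is_flat(self, sphere_mask):
        em = evf_map(sphere_mask, ISO)
        labels = equal_volume_fractions(em, 20)
        img = np.ones(sphere_mask.shape)
        prof = radial_profile(labels, img, spacing=ISO)
        assert np.abs(prof.p - 1 / 20).max() <= 1.0 / em.n_voxels + 1e-12

    def test_all_signal_in_innermost_fraction(self, sphere_mask):
        em = evf_map(sphere_mask, ISO)
        F = 10
        labels = equal_volume_fractions(em, F)
        img = np.where(labels == F, 5.0, 0.0)
        prof = radial_profile(labels, img, spacing=ISO)
        C = prof.cumulative
        assert np.allclose(C[:-1], 0) and C[-1] == pytest.approx(1.0)
        assert dmax(prof) == pytest.approx(-(F - 1) / F)

    def test_peripheral_spots_push_curve_above_diagonal(self, sphere_mask):
        centers, _ = sample_spot_centers(sphere_mask, ISO, 500, (1, 5), rng=9)
        em = evf_map(sphere_mask, ISO)
        labels = equal_volume_fractions(em, 20)
        spot_grid = np.zeros(sphere_mask.shape)
        idx = np.rint(centers / np.asarray(ISO)).astype(int)
        spot_grid[tuple(idx.T)] = 1
        prof = radial_profile(labels, spot_grid, mode="spots", spacing=ISO)
        assert dmax(prof) > 0.2

    def test_zero_signal_rejected(self, sphere_mask):
        em = evf_map(sphere_mask, ISO)
        labels = equal_volume_fractions(em, 10)
        with pytest.raises(ValueError, match="zero"):
            radial_profile(labels, np.zeros(sphere_mask.shape), spacing=ISO)


class TestDmax:
    def test_hand_computed_examples(self):
        assert dmax(profile_from_p([1, 0, 0, 0])) == pytest.approx(0.75)
        assert dmax(profile_from_p([0, 0, 0, 1])) == pytest.approx(-0.75)
        assert dmax(profile_from_p([0.25] * 4)) == pytest.approx(0.0)

    def test_max_signed_rule_differs_on_central_profiles(self):
        prof = profile_from_p([0, 0, 0, 1])
        assert dmax(prof, rule="max_signed") == pytest.approx(0.0)

    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=50))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_bounded_by_one_for_any_profile(self, raw):
        p = np.asarray(raw) / np.sum(raw)
        assert abs(dmax(profile_from_p(p))) <= 1.0


class TestSpotEVF:
    def test_center_and_boundary_spots(self, sphere_mask):
        em = evf_map(sphere_mask, ISO)
        centroid = np.argwhere(sphere_mask).mean(axis=0) * np.asarray(ISO)
        d = em.depth[sphere_mask]
        boundary_vox = np.argwhere(sphere_mask)[np.argmin(d)] * np.asarray(ISO)
        vals, outside = spot_evf(em, np.vstack([centroid, boundary_vox]))
        assert vals[0] >= 0.99 and vals[1] <= 0.05
        assert not outside.any()

    def test_recovers_generation_evf(self, sphere_mask):
        centers, gen_evf = sample_spot_centers(sphere_mask, ISO, 300, (2, 2), rng=3)
        em = evf_map(sphere_mask, ISO)
        vals, _ = spot_evf(em, centers)
        rms = np.sqrt(np.mean((vals - gen_evf) ** 2))
        assert rms <= 0.05

    def test_outside_centroid_flagged_and_mapped(self, sphere_mask):
        em = evf_map(sphere_mask, ISO)
        vals, outside = spot_evf(em, np.array([[0.0, 0.0, 0.0]]))
        assert outside[0] and 0.0 <= vals[0] <= 1.0
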