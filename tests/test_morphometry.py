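"""Morphometry: segmentation contracts, V/S/SI oracles, starch counting."""

import numpy as np
import pytest
from scipy import ndimage

from pollenodt import (
    make_bisaccate_phantom,
    compute_surface_area,
    compute_volume,
    segment_grain,
    segment_starch,
    sphericity_index,
    starch_mass,
)
from pollenodt.volume import homogeneous_volume

from conftest import PITCH, small_grain_spec


def sphere_mask(n=64, radius_vox=20):
    c = n // 2
    z, y, x = np.ogrid[:n, :n, :n]
    return (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius_vox**2


class TestSegmentGrain:
    def test_homogeneous_volume_has_no_grain(self):
        vol = homogeneous_volume((32, 32, 32), PITCH, 1.52)
        with pytest.raises(ValueError, match="no grain"):
            segment_grain(vol)

    def test_threshold_must_clear_noise_floor(self):
        rng = np.random.default_rng(0)
        vol = homogeneous_volume((32, 32, 32), PITCH, 1.52)
        vol.values += rng.normal(0, 0.004, vol.values.shape)
        vol.values = np.clip(vol.values, 1.0, 1.7)
        with pytest.raises(ValueError, match="noise"):
            segment_grain(vol, delta=0.005)

    def test_hollow_shell_occupancy_includes_enclosed_space(self):
        vol, labels = make_bisaccate_phantom(
            small_grain_spec(hollow=True), (64, 64, 64), PITCH
        )
        seg = segment_grain(vol)
        shell_only = labels.grain_mask().sum()
        assert seg.occupancy.sum() > 1.5 * shell_only
        # nearly all of the filled ground-truth grain is covered
        gt = labels.filled_grain_mask()
        assert (seg.occupancy & gt).sum() / gt.sum() > 0.95

    def test_halving_delta_barely_changes_clean_occupancy(self):
        # crisp rasterization: anti-aliased boundary voxels are partial-
        # volume by design and legitimately threshold-dependent
        vol, _ = make_bisaccate_phantom(
            small_grain_spec(), (64, 64, 64), PITCH, supersample=1
        )
        v1 = segment_grain(vol, delta=0.005).occupancy.sum()
        v2 = segment_grain(vol, delta=0.0025).occupancy.sum()
        assert abs(v1 - v2) / v1 < 0.02


class TestVolumeAndSurface:
    def test_volume_is_count_times_voxel_volume(self):
        mask = np.zeros((32, 32, 32), bool)
        mask.ravel()[:1000] = True
        assert compute_volume(mask, 0.2) == pytest.approx(0.008)

    def test_sphere_volume_within_one_percent(self):
        mask = sphere_mask(64, 20)  # radius 5 um at 0.25 um pitch
        v_pl = compute_volume(mask, PITCH)
        assert v_pl * 1000 == pytest.approx(4 / 3 * np.pi * 125, rel=0.01)

    def test_volume_additive_over_disjoint_masks(self):
        a = np.zeros((32, 32, 32), bool)
        b = np.zeros((32, 32, 32), bool)
        a[2:8, 2:8, 2:8] = True
        b[20:29, 20:29, 20:29] = True
        assert compute_volume(a | b, PITCH) == pytest.approx(
            compute_volume(a, PITCH) + compute_volume(b, PITCH)
        )

    def test_sphere_surface_area_within_two_percent(self):
        mask = sphere_mask(64, 20)
        s = compute_surface_area(mask, PITCH)
        assert s == pytest.approx(4 * np.pi * 25, rel=0.02)

    def test_cube_surface_area_within_five_percent(self):
        mask = np.zeros((64, 64, 64), bool)
        mask[12:52, 12:52, 12:52] = True  # 10 um cube
        s = compute_surface_area(mask, PITCH)
        assert s == pytest.approx(6 * 100, rel=0.05)

    def test_internal_cavity_does_not_change_outer_surface(self):
        solid = sphere_mask(64, 20)
        hollow = solid & ~sphere_mask(64, 8)
        assert compute_surface_area(hollow, PITCH) == pytest.approx(
            compute_surface_area(solid, PITCH), rel=1e-6
        )

    def test_surface_area_invariant_under_right_angle_rotation(self):
        vol, _ = make_bisaccate_phantom(small_grain_spec(), (64, 64, 64), PITCH)
        mask = segment_grain(vol).occupancy
        s0 = compute_surface_area(mask, PITCH)
        s1 = compute_surface_area(np.rot90(mask, axes=(0, 2)), PITCH)
        assert s1 == pytest.approx(s0, rel=1e-4)


class TestSphericity:
    def test_analytic_sphere_has_unit_sphericity(self):
        r = 5.0
        v_pl = 4 / 3 * np.pi * r**3 / 1000
        s = 4 * np.pi * r**2
        assert sphericity_index(v_pl, s) == pytest.approx(1.0, rel=1e-12)

    def test_cube_sphericity_matches_closed_form(self):
        a = 10.0
        si = sphericity_index(a**3 / 1000, 6 * a**2)
        assert si == pytest.approx((36 * np.pi) ** (1 / 3) / 6, rel=1e-12)

    def test_random_blobs_never_exceed_unit_sphericity(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            field = ndimage.gaussian_filter(
                rng.normal(size=(48, 48, 48)), 4.0
            )
            mask = field > np.quantile(field, 0.85)
            lab, _ = ndimage.label(mask)
            mask = lab == np.argmax(np.bincount(lab.ravel())[1:]) + 1
            mask = ndimage.binary_fill_holes(mask)
            if mask.sum() < 500:
                continue
            si = sphericity_index(
                compute_volume(mask, PITCH), compute_surface_area(mask, PITCH)
            )
            assert si <= 1.0


@pytest.fixture(scope="module")
def default_phantom():
    from pollenodt import PhantomSpec

    return make_bisaccate_phantom(PhantomSpec(seed=7))


class TestStarch:

    def test_all_granules_found_on_the_clean_phantom(self, default_phantom):
        vol, labels = default_phantom
        seg = segment_grain(vol, delta=0.005)
        mask, count = segment_starch(vol, seg, starch_delta=0.005)
        assert count == 20
        assert mask.sum() * vol.voxel_pitch**3 == pytest.approx(
            labels.volume_um3("starch"), rel=0.25
        )

    def test_oversized_minimum_diameter_empties_the_mask(self, default_phantom):
        vol, _ = default_phantom
        seg = segment_grain(vol, delta=0.005)
        mask, count = segment_starch(
            vol, seg, starch_delta=0.005, min_diameter=10.0, max_diameter=12.0
        )
        assert count == 0 and not mask.any()

    def test_hollow_grain_has_empty_starch_mask(self):
        vol, _ = make_bisaccate_phantom(
            small_grain_spec(hollow=True), (64, 64, 64), PITCH
        )
        seg = segment_grain(vol)
        mask, count = segment_starch(vol, seg)
        assert count == 0 and not mask.any()

    def test_starch_mass_arithmetic(self):
        mask = np.zeros((64, 64, 64), bool)
        nvox = int(round(666.7 / 0.25**3))
        mask.ravel()[:nvox] = True
        assert starch_mass(mask, 0.25, density=1.5) == pytest.approx(
            1.0, rel=1e-3
        )
        assert starch_mass(np.zeros((8, 8, 8), bool), 0.25) == 0.0

    def test_default_granule_load_is_of_reported_order(self, default_phantom):
        # tens of granules of a few um: a fraction of a nanogram of starch,
        # the order of magnitude reported for real grains
        vol, _ = default_phantom
        seg = segment_grain(vol, delta=0.005)
        mask, _ = segment_starch(vol, seg, starch_delta=0.005)
        mass = starch_mass(mask, vol.voxel_pitch)
        assert 0.05 < mass < 2.0
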