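"""Phantom generator: analytic volume oracles, invariants, determinism."""

import numpy as np
import pytest

from pollenodt import (
    PhantomSpec,
    make_bisaccate_phantom,
    make_sphere_phantom,
    sample_strain_population,
)
from pollenodt.phantom import LABEL_CORPUS_INTERIOR, LABEL_STARCH

from conftest import assert_valid_phantom, small_grain_spec


class TestSpherePhantom:
    def test_zero_contrast_is_constant_medium(self):
        vol = make_sphere_phantom(5.0, 0.0, (48, 48, 48), 0.3, 1.52)
        assert np.all(vol.values == 1.52)

    def test_voxel_sum_volume_matches_closed_form(self):
        # 4/3 pi 5^3 = 523.60 um^3
        vol = make_sphere_phantom(5.0, 0.02, (64, 64, 64), 0.2, 1.52)
        frac = (vol.values - 1.52) / 0.02
        measured = frac.sum() * 0.2**3
        assert measured == pytest.approx(4 / 3 * np.pi * 125, rel=0.01)

    def test_volume_error_shrinks_with_pitch(self):
        truth = 4 / 3 * np.pi * 3.0**3

        def err(pitch, n):
            vol = make_sphere_phantom(3.0, 0.02, (n, n, n), pitch, 1.52)
            v = ((vol.values - 1.52) / 0.02).sum() * pitch**3
            return abs(v - truth) / truth

        assert err(0.2, 64) <= 0.5 * err(0.4, 32) + 1e-4

    def test_extreme_values_match_construction(self):
        vol = make_sphere_phantom(5.0, 0.02, (64, 64, 64), 0.25, 1.52)
        assert vol.values.max() == pytest.approx(1.54, abs=1e-12)
        assert vol.values.min() == pytest.approx(1.52, abs=1e-12)
        assert_valid_phantom(vol)

    def test_oversized_sphere_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            make_sphere_phantom(10.0, 0.01, (48, 48, 48), 0.25, 1.52)


class TestBisaccatePhantom:
    def test_hollow_has_no_starch_and_no_interior_label(self):
        vol, labels = make_bisaccate_phantom(
            small_grain_spec(hollow=True), (64, 64, 64), 0.25
        )
        assert not np.any(labels.labels == LABEL_STARCH)
        assert not np.any(labels.labels == LABEL_CORPUS_INTERIOR)
        assert_valid_phantom(vol)

    def test_hollow_crisp_rasterization_uses_only_component_ri(self):
        _, labels = make_bisaccate_phantom(
            small_grain_spec(hollow=True), (64, 64, 64), 0.25, supersample=1
        )
        vol, _ = make_bisaccate_phantom(
            small_grain_spec(hollow=True), (64, 64, 64), 0.25, supersample=1
        )
        assert set(np.unique(vol.values)) <= {1.52, 1.53, 1.54}

    def test_seeded_outputs_are_bitwise_identical(self):
        spec = small_grain_spec(n_granules=5, seed=11)
        a_vol, a_lab = make_bisaccate_phantom(spec, (64, 64, 64), 0.25)
        b_vol, b_lab = make_bisaccate_phantom(spec, (64, 64, 64), 0.25)
        assert np.array_equal(a_vol.values, b_vol.values)
        assert np.array_equal(a_lab.labels, b_lab.labels)

    def test_starch_label_volume_matches_granule_oracle(self):
        # 50 granules of exactly 3 um diameter: 50 * (pi/6) * 27 = 706.9 um^3
        spec = PhantomSpec(
            corpus_semiaxes=(13.0, 12.5, 12.0),
            saccus_radii=(3.0, 3.0),
            n_granules=50,
            granule_diameter_range=(3.0, 3.0),
            granule_gap_lateral=0.2,
            granule_gap_axial=0.2,
            granule_margin=0.3,
            seed=5,
        )
        _, labels = make_bisaccate_phantom(
            spec, (160, 160, 160), 0.25, supersample=1
        )
        measured = labels.volume_um3("starch")
        assert measured == pytest.approx(50 * np.pi / 6 * 27, rel=0.03)

    def test_starch_lies_inside_the_corpus_interior(self):
        spec = small_grain_spec(n_granules=4)
        _, labels = make_bisaccate_phantom(spec, (64, 64, 64), 0.25)
        starch = labels.labels == LABEL_STARCH
        zz, yy, xx = np.where(starch)
        c = np.array([32, 32, 32])
        ax, ay, az = spec.corpus_semiaxes
        t = spec.exine_thickness
        r = (
            ((zz - c[0]) * 0.25 / (az - t)) ** 2
            + ((yy - c[1]) * 0.25 / (ay - t)) ** 2
            + ((xx - c[2]) * 0.25 / (ax - t)) ** 2
        )
        assert starch.any() and np.all(r <= 1.0 + 1e-9)

    def test_unplaceable_granules_error_reports_progress(self):
        spec = small_grain_spec(
            n_granules=500, granule_diameter_range=(2.0, 2.0)
        )
        with pytest.raises(ValueError, match=r"placed \d+/500"):
            make_bisaccate_phantom(spec, (64, 64, 64), 0.25, supersample=1)

    def test_geometry_overflow_rejected(self):
        spec = small_grain_spec(corpus_semiaxes=(9.0, 9.0, 9.0))
        with pytest.raises(ValueError, match="exceeds grid"):
            make_bisaccate_phantom(spec, (64, 64, 64), 0.25)


class TestStrainPopulation:
    def test_zero_cv_gives_identical_geometry(self):
        base = small_grain_spec(n_granules=3)
        pop = sample_strain_population(
            base, 3, 0.0, seed=1, grid_shape=(64, 64, 64), voxel_pitch=0.25,
            supersample=1,
        )
        # geometry identical up to granule placement: compare non-starch labels
        ref = np.where(
            pop[0][1].labels == LABEL_STARCH, LABEL_CORPUS_INTERIOR,
            pop[0][1].labels,
        )
        for _, labels in pop[1:]:
            other = np.where(
                labels.labels == LABEL_STARCH, LABEL_CORPUS_INTERIOR,
                labels.labels,
            )
            assert np.array_equal(ref, other)

    def test_different_seeds_differ(self):
        base = small_grain_spec()
        a = sample_strain_population(
            base, 1, 0.1, seed=1, grid_shape=(64, 64, 64), voxel_pitch=0.25,
            supersample=1,
        )
        b = sample_strain_population(
            base, 1, 0.1, seed=2, grid_shape=(64, 64, 64), voxel_pitch=0.25,
            supersample=1,
        )
        assert not np.array_equal(a[0][0].values, b[0][0].values)

    def test_volume_cv_matches_sampling_model(self):
        # independent log-normal scaling of the linear dimensions with
        # cv = 0.15 puts the volume CV in a broad but bounded band
        base = small_grain_spec(saccus_radii=(1.6, 1.6))
        pop = sample_strain_population(
            base, 20, 0.15, seed=7, grid_shape=(72, 72, 72),
            voxel_pitch=0.25, supersample=1,
        )
        vols = [labels.filled_volume_um3() for _, labels in pop]
        cv = np.std(vols, ddof=1) / np.mean(vols)
        assert 0.08 <= cv <= 0.35

    def test_every_member_is_a_valid_phantom(self):
        base = small_grain_spec()
        pop = sample_strain_population(
            base, 3, 0.1, seed=9, grid_shape=(64, 64, 64), voxel_pitch=0.25,
            supersample=1,
        )
        for vol, labels in pop:
            assert_valid_phantom(vol)
            assert labels.labels.shape == vol.grid_shape
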