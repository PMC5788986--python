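"""Field retrieval: demodulation guards, normalization, LS unwrapping."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from pollenodt import (
    ComplexField2D,
    OpticalConfig,
    acquire_hologram_set,
    demodulate,
    make_bisaccate_phantom,
    normalize_background,
    propagate_field,
    rytov_field,
    unwrap_phase,
)
from pollenodt.field_retrieval import retrieve_set, wrap_phase
from pollenodt.volume import homogeneous_volume

from conftest import PITCH, SMALL_N, small_grain_spec


class TestDemodulate:
    def test_reference_only_hologram_gives_unit_field(self, optics):
        fld = ComplexField2D(np.zeros((SMALL_N, SMALL_N), complex), PITCH)
        from pollenodt import synthesize_hologram

        holo = synthesize_hologram(fld, optics)
        rec = demodulate(holo, optics, (SMALL_N, SMALL_N))
        assert np.allclose(rec.data, 0.0, atol=1e-10)

    def test_unseparable_carrier_rejected(self, optics):
        holo = np.ones((256, 256))
        bad = copy.copy(optics)
        bad.carrier_frequency = (0.0, 0.0)  # bypass constructor validation
        with pytest.raises(ValueError, match="separab"):
            demodulate(holo, bad, (64, 64))


class TestNormalizeBackground:
    def test_sample_equals_background_gives_unit_field(self):
        rng = np.random.default_rng(0)
        data = np.exp(1j * rng.normal(0, 0.3, (32, 32)))
        a = ComplexField2D(data, PITCH)
        b = ComplexField2D(data.copy(), PITCH)
        rf = normalize_background(a, b)
        assert np.allclose(rf.field, 1.0)
        assert np.allclose(rf.phase, 0.0, atol=1e-9)

    def test_common_tilt_cancels_exactly(self):
        y = np.arange(32)[:, None]
        tilt = np.exp(2j * np.pi * 0.07 * y) * np.ones((32, 32))
        payload = np.exp(1j * 0.2 * np.sin(np.arange(32) / 5.0))[None, :]
        rf = normalize_background(
            ComplexField2D(tilt * payload, PITCH), ComplexField2D(tilt, PITCH)
        )
        assert np.allclose(rf.field, payload * np.ones((32, 32)), atol=1e-12)

    def test_vanishing_background_pixels_are_masked(self):
        data = np.ones((32, 32), complex)
        bg = data.copy()
        bg[5, 7] = 1e-6
        rf = normalize_background(
            ComplexField2D(data, PITCH), ComplexField2D(bg, PITCH)
        )
        assert rf.invalid[5, 7]
        assert np.isfinite(rf.field).all()


class TestUnwrap:
    def test_smooth_phase_returned_unchanged(self):
        rng = np.random.default_rng(1)
        smooth = ndimage.gaussian_filter(rng.normal(0, 1, (48, 48)), 6)
        smooth *= 1.2 / np.abs(smooth).max()  # range < pi, no wraps
        out = unwrap_phase(smooth)
        assert np.abs(out - smooth).max() < 1e-8

    def test_triple_wrapped_ramp_recovered(self):
        x = np.arange(64) / 63.0
        ramp = 6.5 * np.pi * x[None, :] * np.ones((64, 1))
        out = unwrap_phase(wrap_phase(ramp))
        # least-squares unwrapping recovers the ramp up to a 2*pi offset
        offset = 2 * np.pi * np.round(np.median(ramp - out) / (2 * np.pi))
        assert np.abs(out + offset - ramp).max() < 1e-3

    def test_grain_phase_unwraps_without_discontinuities(self, optics):
        vol, _ = make_bisaccate_phantom(
            small_grain_spec(), (SMALL_N,) * 3, PITCH
        )
        fld = propagate_field(vol, (0.0, 0.0), optics)
        bg = propagate_field(
            homogeneous_volume((SMALL_N,) * 3, PITCH, optics.medium_ri),
            (0.0, 0.0),
            optics,
        )
        rf = normalize_background(fld, bg)
        assert np.abs(np.diff(rf.phase, axis=0)).max() < np.pi
        assert np.abs(np.diff(rf.phase, axis=1)).max() < np.pi


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_unwrapping_is_idempotent_on_smooth_fields(seed):
    rng = np.random.default_rng(seed)
    smooth = ndimage.gaussian_filter(rng.normal(0, 1, (40, 40)), 5)
    smooth *= 2.5 / max(np.abs(smooth).max(), 1e-9)  # may exceed pi overall
    once = unwrap_phase(wrap_phase(smooth))
    twice = unwrap_phase(wrap_phase(once))
    assert np.abs(once - twice).max() < 1e-6


class TestRytov:
    def test_unit_field_gives_zero_rytov_data(self):
        rf = normalize_background(
            ComplexField2D(np.ones((32, 32), complex), PITCH),
            ComplexField2D(np.ones((32, 32), complex), PITCH),
        )
        assert np.allclose(rytov_field(rf), 0.0)

    def test_pure_phase_object_has_negligible_real_part(self):
        phase = 0.4 * np.sin(np.arange(32) / 4.0)[None, :] * np.ones((32, 1))
        rf = normalize_background(
            ComplexField2D(np.exp(1j * phase), PITCH),
            ComplexField2D(np.ones((32, 32), complex), PITCH),
        )
        data = rytov_field(rf)
        assert np.abs(data.real).max() < 1e-9
        assert np.allclose(data.imag, phase, atol=1e-9)

    def test_weak_sphere_matches_first_rytov_prediction(self, optics):
        """Simulated Rytov data agree with the analytic single-scattering
        prediction for a weak sphere to better than 5% RMS."""
        n, radius, dn = SMALL_N, 3.0, 0.002
        from pollenodt import make_sphere_phantom

        vol = make_sphere_phantom(radius, dn, (n,) * 3, PITCH)
        fld = propagate_field(vol, (0.0, 0.0), optics)
        bg = propagate_field(
            homogeneous_volume((n,) * 3, PITCH, optics.medium_ri),
            (0.0, 0.0),
            optics,
        )
        measured = rytov_field(normalize_background(fld, bg))

        # independent closed-form evaluation: ball spectrum placed on the
        # Ewald cap, scaled by the Fourier-diffraction weight
        k0 = 2 * np.pi / optics.wavelength
        nm = optics.medium_ri
        v0 = k0**2 * ((nm + dn) ** 2 - nm**2)
        f = np.fft.fftfreq(n, PITCH)
        km = nm / optics.wavelength
        det2 = f[:, None] ** 2 + f[None, :] ** 2
        nu_z = np.sqrt(np.maximum(km**2 - det2, 1e-12))
        kz = nu_z - km
        kmag = np.sqrt(det2 + kz**2)
        u = 2 * np.pi * kmag * radius
        ball = np.where(
            u < 1e-6, 1.0, 3 * (np.sin(u) - u * np.cos(u)) / np.maximum(u, 1e-12) ** 3
        )
        spectrum = v0 * (4 / 3 * np.pi * radius**3) * ball
        us_hat = 1j * spectrum / (4 * np.pi * nu_z)
        us_hat[det2 > optics.band_limit**2] = 0.0
        predicted = np.roll(
            np.fft.ifft2(us_hat) / PITCH**2, (n // 2, n // 2), axis=(0, 1)
        )
        err = np.sqrt(np.mean(np.abs(measured - predicted) ** 2))
        norm = np.sqrt(np.mean(np.abs(predicted) ** 2))
        assert err / norm < 0.05


def test_retrieve_set_round_trips_weak_object(optics, small_scan):
    from pollenodt import make_sphere_phantom

    vol = make_sphere_phantom(2.0, 0.003, (SMALL_N,) * 3, PITCH)
    hs = acquire_hologram_set(vol, small_scan, optics)
    fields = retrieve_set(hs, (2 * SMALL_N, 2 * SMALL_N))
    assert len(fields) == len(small_scan)
    assert all(rf.masked_fraction == 0.0 for rf in fields)
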