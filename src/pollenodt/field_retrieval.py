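"""Complex-field retrieval from off-axis interferograms.

The hologram spectrum carries the object field on a sideband at the
reference-tilt carrier frequency.  Demodulation crops a circular sideband of
radius ``NA_det / lambda`` around the carrier, recenters it to baseband and
inverse-transforms, optionally down-sampling to the reconstruction grid in
the same step.  Sample frames are normalized by sample-free background
frames, cancelling the reference tilt and any fixed system phase.  The
normalized field's phase is unwrapped by the transform-based least-squares
(DCT/Poisson) method and combined with the log-amplitude into complex Rytov
data ``u_R = ln A + i phi``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from .forward_model import ComplexField2D, HologramSet, OpticalConfig

log = logging.getLogger(__name__)


def demodulate(
    interferogram: np.ndarray,
    config: OpticalConfig,
    out_shape: tuple[int, int] | None = None,
) -> ComplexField2D:
    """Recover the complex field from one off-axis interferogram.

    ``out_shape`` selects the baseband grid (defaults to the camera grid
    divided by the camera oversampling implied by the carrier); choosing the
    reconstruction grid here performs the down-sampling for free, since the
    sideband bandwidth is far below the camera Nyquist rate.
    """
    holo = np.asarray(interferogram, dtype=np.float64)
    n_cam_y, n_cam_x = holo.shape
    dnu = 1.0 / (n_cam_x * config.camera_pitch)
    if n_cam_y != n_cam_x:
        raise ValueError("square camera frames expected")
    ciy = round(config.carrier_frequency[0] / dnu)
    cix = round(config.carrier_frequency[1] / dnu)
    band_px = config.band_limit / dnu
    if np.hypot(ciy, cix) <= 3.0 * band_px:
        raise ValueError(
            "carrier too close to DC: hologram sideband overlaps the "
            "autocorrelation term (separability violated)"
        )

    if out_shape is None:
        out_shape = holo.shape
    no_y, no_x = out_shape
    if band_px >= no_x // 2 or band_px >= no_y // 2:
        raise ValueError("output grid too small to hold the detection band")

    spec = np.fft.fft2(holo)
    # the u R* sideband (the non-conjugate object field) sits at -carrier
    idx_y = np.rint(np.fft.fftfreq(no_y) * no_y).astype(int)
    idx_x = np.rint(np.fft.fftfreq(no_x) * no_x).astype(int)
    src_y = (-ciy + idx_y) % n_cam_y
    src_x = (-cix + idx_x) % n_cam_x
    block = spec[np.ix_(src_y, src_x)]
    mask = idx_y[:, None] ** 2 + idx_x[None, :] ** 2 <= band_px**2
    block = np.where(mask, block, 0.0)
    # the reference beam is defined on center-origin coordinates, which
    # contributes a constant carrier phase exp(2*pi*i c.r0); remove it
    phase0 = np.exp(
        -2j * np.pi * (ciy * (n_cam_y // 2) / n_cam_y
                       + cix * (n_cam_x // 2) / n_cam_x)
    )
    fld = np.fft.ifft2(block) * phase0 * (no_y * no_x) / (n_cam_y * n_cam_x)
    pitch_out = n_cam_x * config.camera_pitch / no_x
    return ComplexField2D(fld, pitch_out)


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    return np.angle(np.exp(1j * phi))


def unwrap_phase(wrapped: np.ndarray) -> np.ndarray:
    """Least-squares 2D phase unwrapping (Ghiglia-Romero, DCT form).

    Solves the discrete Poisson equation whose source is the divergence of
    the wrapped phase gradients, under Neumann boundary conditions, via the
    type-II cosine transform.  Deterministic and seed-free; for smooth input
    whose true gradients never exceed pi per pixel the result equals the
    input up to a constant.  The constant is anchored so the result agrees
    with the wrapped input modulo 2*pi in the median.
    """
    phi = np.asarray(wrapped, dtype=np.float64)
    gy = wrap_phase(np.diff(phi, axis=0))
    gx = wrap_phase(np.diff(phi, axis=1))
    rho = np.zeros_like(phi)
    rho[:-1, :] += gy
    rho[1:, :] -= gy
    rho[:, :-1] += gx
    rho[:, 1:] -= gx

    ny, nx = phi.shape
    dct_rho = sfft.dctn(rho, type=2, norm="ortho")
    ky = np.arange(ny)[:, None]
    kx = np.arange(nx)[None, :]
    denom = 2.0 * (np.cos(np.pi * ky / ny) + np.cos(np.pi * kx / nx) - 2.0)
    denom[0, 0] = 1.0
    sol = dct_rho / denom
    sol[0, 0] = 0.0
    out = sfft.idctn(sol, type=2, norm="ortho")
    # anchor the free constant to the wrapped data modulo 2*pi
    offset = np.median(wrap_phase(phi - out))
    out = out + offset
    k = np.round(np.median(phi - out) / (2 * np.pi))
    return out + 2 * np.pi * k


@dataclass
class RetrievedField:
    """Background-normalized complex field for one illumination angle."""

    field: np.ndarray  # complex ratio sample/background
    amplitude: np.ndarray
    phase: np.ndarray  # unwrapped, radians
    invalid: np.ndarray  # pixels masked for vanishing background amplitude
    pixel_pitch: float
    k_transverse: tuple[float, float] = (0.0, 0.0)
    masked_fraction: float = 0.0


def _nearest_fill(arr: np.ndarray, invalid: np.ndarray) -> np.ndarray:
    if not invalid.any():
        return arr
    idx = ndimage.distance_transform_edt(
        invalid, return_distances=False, return_indices=True
    )
    return arr[tuple(idx)]


def normalize_background(
    sample_field: ComplexField2D,
    background_field: ComplexField2D,
    eps: float = 1e-3,
    k_transverse: tuple[float, float] = (0.0, 0.0),
) -> RetrievedField:
    """Divide sample by background field and unwrap the resulting phase.

    Pixels where the background amplitude falls below ``eps`` are masked and
    nearest-neighbor inpainted before unwrapping; a masked fraction above 1%
    is logged as a QC warning.
    """
    s, b = sample_field.data, background_field.data
    if s.shape != b.shape:
        raise ValueError("sample and background grids must match")
    invalid = np.abs(b) <= eps
    frac = float(invalid.mean())
    if frac > 0.01:
        log.warning(
            "background amplitude below eps on %.2f%% of pixels", 100 * frac
        )
    ratio = np.where(invalid, 1.0 + 0.0j, s / np.where(invalid, 1.0, b))
    ratio = _nearest_fill(ratio, invalid)
    phase = unwrap_phase(np.angle(ratio))
    return RetrievedField(
        field=ratio,
        amplitude=np.abs(ratio),
        phase=phase,
        invalid=invalid,
        pixel_pitch=sample_field.pixel_pitch,
        k_transverse=k_transverse,
        masked_fraction=frac,
    )


def rytov_field(retrieved: RetrievedField) -> np.ndarray:
    """Complex Rytov data ``ln A + i phi`` with masked pixels inpainted."""
    amp = _nearest_fill(retrieved.amplitude, retrieved.invalid)
    bad = amp <= 0
    amp = np.where(bad, 1.0, amp)
    return np.log(amp) + 1j * retrieved.phase


def retrieve_set(
    holo_set: HologramSet, out_shape: tuple[int, int]
) -> list[RetrievedField]:
    """Demodulate and background-normalize every angle of a hologram set."""
    out = []
    for i, k in enumerate(holo_set.illumination.k_transverse):
        s = demodulate(holo_set.holograms[i], holo_set.config, out_shape)
        b = demodulate(holo_set.backgrounds[i], holo_set.config, out_shape)
        out.append(normalize_background(s, b, k_transverse=tuple(k)))
    return out
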