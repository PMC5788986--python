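"""Instrument simulator: angle-scanned illumination and off-axis holograms.

Models a Mach-Zehnder off-axis holographic microscope: a coherent plane wave
tilted within the illumination NA traverses the sample volume, the exit
field is band-limited by the detection objective (NA 0.8 by default), and on
the camera the field interferes with a tilted plane reference beam, writing
the complex field onto a spatial carrier.

Propagation through the volume uses the multi-slice beam propagation method:
each voxel slab contributes a thin phase screen ``exp(i 2*pi (n - n_m) dz /
lambda)`` and free-space gaps are bridged by the angular-spectrum propagator
in the medium.  This includes multiple forward scattering, so the linearized
(Rytov) inverse model downstream is exercised as a genuine approximation.

Frequencies are spatial frequencies in cycles/um throughout; 2-vectors are
ordered ``(f_y, f_x)`` to match the ``(y, x)`` array axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import RIVolume, homogeneous_volume


@dataclass
class OpticalConfig:
    """Optical system description.

    The default wavelength (532 nm) together with NA 0.8 gives the usual
    coherent lateral resolution limit ``lambda / (4 NA)`` of 166 nm.
    ``carrier_frequency`` is the off-axis reference tilt in cycles/um at the
    sample plane; it must exceed three detection bandwidths so the hologram
    sideband separates from the autocorrelation term, while staying below
    the camera Nyquist frequency.
    """

    wavelength: float = 0.532  # um, in vacuum
    na_illumination: float = 0.8
    na_detection: float = 0.8
    medium_ri: float = 1.52
    camera_pitch: float = 0.0625  # um at the sample plane
    carrier_frequency: tuple[float, float] = (0.0, 4.8125)  # (f_y, f_x)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def band_limit(self) -> float:
        """Detection-side transverse frequency cutoff, cycles/um."""
        return self.na_detection / self.wavelength

    @property
    def illumination_limit(self) -> float:
        return self.na_illumination / self.wavelength

    @property
    def medium_wavenumber(self) -> float:
        """|k| in the medium, cycles/um."""
        return self.medium_ri / self.wavelength

    def validate(self) -> None:
        if not (0 < self.na_illumination <= self.na_detection < self.medium_ri):
            raise ValueError(
                "require 0 < na_illumination <= na_detection < medium_ri"
            )
        c = float(np.hypot(*self.carrier_frequency))
        if c <= 3.0 * self.band_limit:
            raise ValueError(
                f"carrier |f|={c:.3f} cycles/um must exceed 3x the detection "
                f"band ({3.0 * self.band_limit:.3f}) for sideband separation"
            )
        nyquist = 0.5 / self.camera_pitch
        if c + self.band_limit >= nyquist:
            raise ValueError(
                f"carrier plus band ({c + self.band_limit:.3f}) reaches the "
                f"camera Nyquist frequency ({nyquist:.3f} cycles/um)"
            )


@dataclass
class IlluminationSet:
    """Transverse illumination wavevectors (cycles/um) and scan descriptor."""

    k_transverse: np.ndarray  # (n_angles, 2), ordered (f_y, f_x)
    pattern: str = "custom"

    def __post_init__(self) -> None:
        self.k_transverse = np.atleast_2d(np.asarray(self.k_transverse, float))

    def __len__(self) -> int:
        return self.k_transverse.shape[0]

    def validate(self, config: OpticalConfig) -> None:
        mags = np.hypot(self.k_transverse[:, 0], self.k_transverse[:, 1])
        if np.any(mags > config.illumination_limit * (1 + 1e-9)):
            raise ValueError("illumination vector exceeds the illumination NA")
        if not np.any(mags == 0):
            raise ValueError("scan must contain the normal-incidence vector")


#: default multi-ring scan: (radius fraction of the illumination NA, count)
DEFAULT_RINGS = ((0.95, 48), (0.7, 32), (0.4, 16))


def make_multiring_scan(
    config: OpticalConfig,
    grid_shape: tuple[int, ...],
    voxel_pitch: float,
    rings: tuple[tuple[float, int], ...] = DEFAULT_RINGS,
) -> IlluminationSet:
    """Normal incidence plus several rings of tilted illuminations.

    A single-radius ring sweeps the Ewald cap along one circle only and
    samples the reachable frequency support as a sparse sheaf of thin
    sheets; adding rings at smaller tilt radii thickens the sampled support
    so that inversion and missing-cone regularization rest on solid
    frequency coverage.  Vectors are snapped to the simulation grid's
    transverse frequency lattice (see :func:`make_circular_scan`).
    """
    dnu_y = 1.0 / (grid_shape[-2] * voxel_pitch)
    dnu_x = 1.0 / (grid_shape[-1] * voxel_pitch)
    ks = [(0.0, 0.0)]
    for radius_frac, n_angles in rings:
        radius = radius_frac * config.illumination_limit
        for phi in np.linspace(0, 2 * np.pi, n_angles, endpoint=False):
            fy, fx = radius * np.sin(phi), radius * np.cos(phi)
            iy, ix = round(fy / dnu_y), round(fx / dnu_x)
            while np.hypot(iy * dnu_y, ix * dnu_x) > config.illumination_limit:
                iy -= int(np.sign(iy)) or 0
                ix -= int(np.sign(ix)) or 0
            ks.append((iy * dnu_y, ix * dnu_x))
    ill = IlluminationSet(
        np.array(ks),
        pattern="+".join(f"ring{n}@{r}" for r, n in rings),
    )
    ill.validate(config)
    return ill


def make_circular_scan(
    config: OpticalConfig,
    grid_shape: tuple[int, ...],
    voxel_pitch: float,
    n_angles: int = 48,
    radius_frac: float = 0.95,
) -> IlluminationSet:
    """Normal incidence plus ``n_angles`` directions on a circle in NA space.

    The circle sits at ``radius_frac`` of the illumination NA.  Vectors are
    snapped to the transverse frequency lattice of the simulation grid so
    tilted plane waves are exactly periodic (no spectral leakage); snapping
    that would overshoot the NA is rounded inward instead.
    """
    dnu_y = 1.0 / (grid_shape[-2] * voxel_pitch)
    dnu_x = 1.0 / (grid_shape[-1] * voxel_pitch)
    radius = radius_frac * config.illumination_limit
    ks = [(0.0, 0.0)]
    for phi in np.linspace(0, 2 * np.pi, n_angles, endpoint=False):
        fy, fx = radius * np.sin(phi), radius * np.cos(phi)
        iy, ix = round(fy / dnu_y), round(fx / dnu_x)
        while np.hypot(iy * dnu_y, ix * dnu_x) > config.illumination_limit:
            iy -= int(np.sign(iy)) or 0
            ix -= int(np.sign(ix)) or 0
        ks.append((iy * dnu_y, ix * dnu_x))
    ill = IlluminationSet(np.array(ks), pattern=f"ring{n_angles}@{radius_frac}")
    ill.validate(config)
    return ill


@dataclass
class ComplexField2D:
    """A complex optical field sampled on the transverse grid."""

    data: np.ndarray  # complex, (ny, nx)
    pixel_pitch: float  # um
    k_transverse: tuple[float, float] = (0.0, 0.0)  # illumination, cycles/um

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2:
            raise ValueError("ComplexField2D.data must be 2D")


@dataclass
class HologramSet:
    """Per-angle off-axis interferograms with matching background frames."""

    holograms: np.ndarray  # (n_angles, n, n), real, >= 0
    backgrounds: np.ndarray  # same shape, sample-free
    config: OpticalConfig
    illumination: IlluminationSet
    volume_pitch: float  # um, pitch of the simulated volume grid

    def __post_init__(self) -> None:
        if self.holograms.shape != self.backgrounds.shape:
            raise ValueError("sample and background sets must match in shape")
        if self.holograms.shape[0] != len(self.illumination):
            raise ValueError("hologram count must match the angle list")


def _transverse_freqs(shape: tuple[int, int], pitch: float):
    fy = np.fft.fftfreq(shape[0], d=pitch)
    fx = np.fft.fftfreq(shape[1], d=pitch)
    return fy[:, None], fx[None, :]


def propagate_field(
    volume: RIVolume,
    k_transverse: tuple[float, float],
    config: OpticalConfig,
    na_filter: bool = True,
) -> ComplexField2D:
    """Exit field of a tilted plane wave after multi-slice propagation.

    The field is numerically refocused back to the axial center plane of the
    volume (the plane ODT data are referenced to) and, by default, low-pass
    filtered to the detection NA.
    """
    fy0, fx0 = float(k_transverse[0]), float(k_transverse[1])
    if np.hypot(fy0, fx0) >= config.medium_wavenumber:
        raise ValueError("illumination is evanescent in the medium")
    nz, ny, nx = volume.grid_shape
    pitch = volume.voxel_pitch
    dz = pitch
    lam = config.wavelength
    n_m = config.medium_ri

    y = (np.arange(ny) - ny // 2) * pitch
    x = (np.arange(nx) - nx // 2) * pitch
    field = np.exp(
        2j * np.pi * (fy0 * y[:, None] + fx0 * x[None, :])
    ).astype(np.complex128)

    fy, fx = _transverse_freqs((ny, nx), pitch)
    nu_z_sq = config.medium_wavenumber**2 - fy**2 - fx**2
    nu_z = np.sqrt(np.maximum(nu_z_sq, 0.0))
    evanescent = nu_z_sq < 0
    prop = np.exp(2j * np.pi * nu_z * dz)
    prop[evanescent] = np.exp(-2 * np.pi * np.sqrt(-nu_z_sq[evanescent]) * dz)

    phase_coeff = 2j * np.pi * dz / lam
    for iz in range(nz):
        screen = np.exp(phase_coeff * (volume.values[iz] - n_m))
        field = np.fft.ifft2(np.fft.fft2(field * screen) * prop)

    # refocus from the exit face back to the volume-center plane
    back = (nz - nz // 2) * dz
    spec = np.fft.fft2(field)
    refocus = np.exp(-2j * np.pi * nu_z * back)
    refocus[evanescent] = 1.0  # decayed already; do not re-amplify
    spec *= refocus
    if na_filter:
        spec[fy**2 + fx**2 > config.band_limit**2] = 0.0
    field = np.fft.ifft2(spec)
    return ComplexField2D(field, pitch, (fy0, fx0))


def _aligned_carrier(
    config: OpticalConfig, n_cam: int
) -> tuple[int, int, tuple[float, float]]:
    """Snap the configured carrier to the camera spectral lattice."""
    dnu = 1.0 / (n_cam * config.camera_pitch)
    iy = round(config.carrier_frequency[0] / dnu)
    ix = round(config.carrier_frequency[1] / dnu)
    return iy, ix, (iy * dnu, ix * dnu)


def synthesize_hologram(
    fld: ComplexField2D,
    config: OpticalConfig,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Off-axis interferogram ``|U + R|^2`` on the camera grid.

    The sample field is Fourier-interpolated (exact for band-limited fields)
    up to the camera sampling; the reference ``R`` is a unit-amplitude plane
    wave at the carrier frequency, snapped to the camera spectral lattice.
    Optional additive Gaussian noise emulates shot/read noise; intensities
    are clipped at zero.
    """
    factor = fld.pixel_pitch / config.camera_pitch
    f = round(factor)
    if abs(factor - f) > 1e-9 or f < 1:
        raise ValueError(
            "volume pitch must be an integer multiple of the camera pitch"
        )
    ny, nx = fld.data.shape
    if f == 1:
        cam = fld.data
    else:
        spec = np.fft.fftshift(np.fft.fft2(fld.data))
        big = np.zeros((ny * f, nx * f), dtype=np.complex128)
        big[
            (ny * f - ny) // 2 : (ny * f + ny) // 2,
            (nx * f - nx) // 2 : (nx * f + nx) // 2,
        ] = spec
        cam = np.fft.ifft2(np.fft.ifftshift(big)) * f**2

    n_cam = cam.shape[0]
    _, _, (cy, cx) = _aligned_carrier(config, n_cam)
    yy = (np.arange(cam.shape[0]) - cam.shape[0] // 2) * config.camera_pitch
    xx = (np.arange(cam.shape[1]) - cam.shape[1] // 2) * config.camera_pitch
    ref = np.exp(2j * np.pi * (cy * yy[:, None] + cx * xx[None, :]))
    intensity = np.abs(cam + ref) ** 2
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        intensity = intensity + rng.normal(0.0, noise_sigma, intensity.shape)
    return np.clip(intensity, 0.0, None)


def acquire_hologram_set(
    volume: RIVolume,
    illumination: IlluminationSet,
    config: OpticalConfig,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> HologramSet:
    """Simulate a full angle scan plus matching sample-free backgrounds."""
    illumination.validate(config)
    rng = np.random.default_rng(seed)
    bg_volume = homogeneous_volume(
        volume.grid_shape, volume.voxel_pitch, config.medium_ri
    )
    holos, bgs = [], []
    for k in illumination.k_transverse:
        fld = propagate_field(volume, tuple(k), config)
        bg = propagate_field(bg_volume, tuple(k), config)
        holos.append(synthesize_hologram(fld, config, noise_sigma, rng))
        bgs.append(synthesize_hologram(bg, config, noise_sigma, rng))
    return HologramSet(
        np.stack(holos),
        np.stack(bgs),
        config,
        illumination,
        volume.voxel_pitch,
    )
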