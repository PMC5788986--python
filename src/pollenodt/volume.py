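"""Refractive-index volume container.

The central object of the pipeline is a 3D grid of refractive index (RI)
values on an isotropic voxel lattice, together with the RI of the mounting
medium (index-matching oil).  Array axes are ordered ``(z, y, x)`` with ``z``
the optical axis; the coordinate origin sits at the volume center, voxel
``i`` along an axis of length ``N`` being at ``(i - N//2) * voxel_pitch``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: physical bounds for any credible RI value in oil-mounted biological samples
RI_MIN = 1.0
RI_MAX = 1.7


@dataclass
class RIVolume:
    """A 3D refractive-index map.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Unitless refractive index per voxel.
    voxel_pitch : float
        Isotropic voxel edge length in micrometers.
    medium_ri : float
        Refractive index of the surrounding medium.
    """

    values: np.ndarray
    voxel_pitch: float
    medium_ri: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("RIVolume.values must be a 3D array")
        if not self.voxel_pitch > 0:
            raise ValueError("voxel_pitch must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical edge lengths of the grid in micrometers."""
        return tuple(n * self.voxel_pitch for n in self.values.shape)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Center-origin physical coordinates along one axis (um)."""
        n = self.values.shape[axis]
        return (np.arange(n) - n // 2) * self.voxel_pitch

    def validate(self, check_boundary: bool = False) -> None:
        """Assert the container invariants; raise ``ValueError`` otherwise.

        ``check_boundary=True`` additionally requires the outermost 2-voxel
        shell on every face to equal ``medium_ri`` exactly, which holds for
        generated phantoms but only approximately for reconstructions.
        """
        v = self.values
        if any(n < 8 for n in v.shape):
            raise ValueError("grid_shape must be >= 8 along every axis")
        if not np.all(np.isfinite(v)):
            raise ValueError("RI values must be finite")
        if v.min() < RI_MIN or v.max() > RI_MAX:
            raise ValueError(
                f"RI values outside physical bounds [{RI_MIN}, {RI_MAX}]: "
                f"min={v.min():.4f}, max={v.max():.4f}"
            )
        if check_boundary:
            shell = boundary_shell_mask(v.shape, width=2)
            if not np.all(v[shell] == self.medium_ri):
                raise ValueError("boundary shell deviates from medium_ri")

    def copy(self) -> "RIVolume":
        return RIVolume(self.values.copy(), self.voxel_pitch, self.medium_ri)


def boundary_shell_mask(shape: tuple[int, ...], width: int = 2) -> np.ndarray:
    """Boolean mask of the outermost ``width`` voxels on every face."""
    mask = np.ones(shape, dtype=bool)
    core = tuple(slice(width, n - width) for n in shape)
    mask[core] = False
    return mask


def homogeneous_volume(
    grid_shape: tuple[int, int, int], voxel_pitch: float, medium_ri: float
) -> RIVolume:
    """A volume containing nothing but the mounting medium."""
    return RIVolume(
        np.full(grid_shape, float(medium_ri), dtype=np.float64),
        float(voxel_pitch),
        float(medium_ri),
    )
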