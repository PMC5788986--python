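"""File formats: HDF5 (authoritative) and 32-bit multi-page TIFF.

HDF5 volumes carry ``/ri`` (and optionally ``/labels``) datasets with
``voxel_pitch_um`` and ``medium_ri`` root attributes.  TIFF export writes
the RI stack as 32-bit float pages with a JSON sidecar (``<path>.json``)
holding the same metadata, since plain TIFF has no standard slot for it.
Hologram sets are HDF5-only (complex stacks plus the optical config).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .forward_model import HologramSet, IlluminationSet, OpticalConfig
from .phantom import ComponentLabels
from .volume import RIVolume


def write_ri_volume(
    volume: RIVolume,
    path: str | Path,
    labels: ComponentLabels | None = None,
) -> None:
    """Write an RI volume (HDF5 for ``.h5``/``.hdf5``, else TIFF+sidecar)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("ri", data=volume.values)
            if labels is not None:
                f.create_dataset("labels", data=labels.labels)
            f.attrs["voxel_pitch_um"] = volume.voxel_pitch
            f.attrs["medium_ri"] = volume.medium_ri
    else:
        tifffile.imwrite(path, volume.values.astype(np.float32))
        sidecar = {
            "voxel_pitch_um": volume.voxel_pitch,
            "medium_ri": volume.medium_ri,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_ri_volume(
    path: str | Path,
) -> tuple[RIVolume, ComponentLabels | None]:
    """Read an RI volume written by :func:`write_ri_volume`.

    HDF5 round-trips bitwise; TIFF requires its JSON sidecar and raises a
    ``KeyError``-style message naming any absent metadata attribute.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            for attr in ("voxel_pitch_um", "medium_ri"):
                if attr not in f.attrs:
                    raise ValueError(f"missing HDF5 attribute {attr!r}")
            vol = RIVolume(
                f["ri"][...],
                float(f.attrs["voxel_pitch_um"]),
                float(f.attrs["medium_ri"]),
            )
            labels = None
            if "labels" in f:
                labels = ComponentLabels(f["labels"][...], vol.voxel_pitch)
            return vol, labels
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise ValueError(
            f"TIFF volume {path} lacks its metadata sidecar "
            f"({sidecar_path.name}); 'voxel_pitch_um' is unavailable"
        )
    meta = json.loads(sidecar_path.read_text())
    for attr in ("voxel_pitch_um", "medium_ri"):
        if attr not in meta:
            raise ValueError(f"missing sidecar attribute {attr!r}")
    data = tifffile.imread(path)
    return (
        RIVolume(
            np.asarray(data, np.float64),
            float(meta["voxel_pitch_um"]),
            float(meta["medium_ri"]),
        ),
        None,
    )


def write_hologram_set(holo_set: HologramSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("holograms", data=holo_set.holograms.astype(np.float32))
        f.create_dataset("backgrounds", data=holo_set.backgrounds.astype(np.float32))
        f.create_dataset("k_transverse", data=holo_set.illumination.k_transverse)
        f.attrs["pattern"] = holo_set.illumination.pattern
        f.attrs["volume_pitch_um"] = holo_set.volume_pitch
        cfg = holo_set.config
        for name in (
            "wavelength",
            "na_illumination",
            "na_detection",
            "medium_ri",
            "camera_pitch",
        ):
            f.attrs[name] = getattr(cfg, name)
        f.attrs["carrier_frequency"] = cfg.carrier_frequency


def read_hologram_set(path: str | Path) -> HologramSet:
    with h5py.File(path, "r") as f:
        cfg = OpticalConfig(
            wavelength=float(f.attrs["wavelength"]),
            na_illumination=float(f.attrs["na_illumination"]),
            na_detection=float(f.attrs["na_detection"]),
            medium_ri=float(f.attrs["medium_ri"]),
            camera_pitch=float(f.attrs["camera_pitch"]),
            carrier_frequency=tuple(f.attrs["carrier_frequency"]),
        )
        ill = IlluminationSet(
            f["k_transverse"][...], pattern=str(f.attrs["pattern"])
        )
        return HologramSet(
            holograms=f["holograms"][...].astype(np.float64),
            backgrounds=f["backgrounds"][...].astype(np.float64),
            config=cfg,
            illumination=ill,
            volume_pitch=float(f.attrs["volume_pitch_um"]),
        )
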