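"""End-to-end pipeline: phantoms -> holograms -> RI maps -> morphometry -> stats.

A :class:`PipelineConfig` describes every stage; :func:`run_pipeline`
executes phantom generation, the hologram simulation, field retrieval and
tomographic reconstruction, per-grain quantification, and the pairwise
strain comparisons, writing CSV tables and a QC log to an output directory.
A single global seed is fanned out deterministically to per-stage,
per-grain child seeds, so a given config and seed reproduce every artifact
bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as podt_io
from .forward_model import (
    OpticalConfig,
    acquire_hologram_set,
    make_multiring_scan,
)
from .morphometry import DEFAULT_STARCH_DENSITY, quantify_grain
from .phantom import PhantomSpec, sample_strain_population
from .reconstruction import characterize, reconstruct
from .stats import GroupTable, compare_all, comparisons_frame, summarize
from .volume import boundary_shell_mask

log = logging.getLogger(__name__)


@dataclass
class StrainConfig:
    """One strain's phantom population."""

    n_grains: int = 4
    variation_cv: float = 0.15
    spec_overrides: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    """Full configuration of a pipeline run (round-trips through YAML)."""

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_pitch: float = 0.25
    medium_ri: float = 1.52
    supersample: int = 2
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    strains: dict[str, StrainConfig] = field(
        default_factory=lambda: {"strain_a": StrainConfig()}
    )
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    scan_rings: tuple = ((0.95, 48), (0.7, 32), (0.4, 16))
    noise_sigma: float = 0.0
    recon_iters: int = 60
    recon_tol: float = 1e-7
    lower_bound_ri: float = 1.0
    support_dilation: int = 5
    support_dilation_axial: int = 0  # extra axial margin for volume studies
    support_delta: float | None = None  # defaults to `delta`
    axial_taper: float = 0.1  # cycles/um, spectral rolloff at the cone edge
    gap_fill: int = 6
    delta: float = 0.003
    starch_delta: float = 0.004
    starch_density: float = DEFAULT_STARCH_DENSITY
    min_granule_diameter: float = 1.0
    stats_mode: str = "auto"
    holm: bool = False
    seed: int = 0
    save_volumes: bool = False
    save_holograms: bool = False

    def __post_init__(self) -> None:
        self.grid_shape = tuple(self.grid_shape)
        self.scan_rings = tuple(
            (float(r), int(n)) for r, n in self.scan_rings
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)

        def build(klass, data):
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(data) - names
            if unknown:
                raise ValueError(
                    f"unknown {klass.__name__} key(s): {sorted(unknown)}"
                )
            return klass(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in data.items()
            })

        if "phantom" in raw:
            raw["phantom"] = build(PhantomSpec, raw["phantom"])
        if "optics" in raw:
            raw["optics"] = build(OpticalConfig, raw["optics"])
        if "strains" in raw:
            raw["strains"] = {
                name: build(StrainConfig, sc) if isinstance(sc, dict) else sc
                for name, sc in raw["strains"].items()
            }
        if "grid_shape" in raw and isinstance(raw["grid_shape"], list):
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return build(cls, raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _child_seed(base: int, *tags) -> int:
    blob = json.dumps([base, *tags], default=str).encode()
    return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big") % (2**31)


def process_grain(
    volume,
    config: PipelineConfig,
    grain_id: str,
    strain: str,
):
    """Simulate, reconstruct and quantify a single phantom grain."""
    rings = tuple(
        (float(r), int(n)) for r, n in config.scan_rings
    )
    scan = make_multiring_scan(
        config.optics, config.grid_shape, config.voxel_pitch, rings=rings
    )
    holo = acquire_hologram_set(
        volume, scan, config.optics,
        noise_sigma=config.noise_sigma,
        seed=_child_seed(config.seed, "noise", grain_id),
    )
    # two passes: an unregularized inversion yields the grain support, which
    # then drives the support-constrained missing-cone regularization
    result = reconstruct(
        holo, config.grid_shape, n_iter=0,
        axial_taper=config.axial_taper, gap_fill=config.gap_fill,
    )
    if config.recon_iters > 0:
        from scipy import ndimage

        from .morphometry import segment_grain
        from .reconstruction import regularize_missing_cone

        seg0 = segment_grain(
            result.volume, delta=config.support_delta or config.delta
        )
        support = ndimage.binary_dilation(
            seg0.occupancy, iterations=config.support_dilation
        )
        if config.support_dilation_axial > 0:
            zstruct = np.zeros((3, 3, 3), bool)
            zstruct[:, 1, 1] = True
            support = ndimage.binary_dilation(
                support, structure=zstruct,
                iterations=config.support_dilation_axial,
            )
        result = regularize_missing_cone(
            result,
            lower_bound_ri=config.lower_bound_ri,
            n_iter=config.recon_iters,
            tol=config.recon_tol,
            support=support,
            axial_taper=config.axial_taper,
        )
    record = quantify_grain(
        result.volume,
        grain_id=grain_id,
        strain=strain,
        delta=config.delta,
        starch_delta=config.starch_delta,
        starch_density=config.starch_density,
        min_granule_diameter=config.min_granule_diameter,
    )
    shell = boundary_shell_mask(config.grid_shape, width=2)
    qc = characterize(result, shell)
    qc.update(result.qc)
    qc["missing_cone_fraction"] = result.missing_cone_fraction
    return record, result, qc


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> pd.DataFrame:
    """Execute the full pipeline and write result tables to ``outdir``.

    Writes ``morphometrics.csv``, ``comparisons.csv`` (when more than one
    strain is configured), ``summary.csv`` and ``qc.json``; returns the
    morphometrics table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    records, qc_all = [], {}
    for strain, sc in config.strains.items():
        spec = dataclasses.replace(config.phantom, **sc.spec_overrides)
        try:
            population = sample_strain_population(
                spec,
                n_grains=sc.n_grains,
                variation_cv=sc.variation_cv,
                seed=_child_seed(config.seed, "phantom", strain),
                grid_shape=config.grid_shape,
                voxel_pitch=config.voxel_pitch,
                medium_ri=config.medium_ri,
                supersample=config.supersample,
            )
        except Exception as exc:
            raise RuntimeError(f"[phantom/{strain}] {exc}") from exc
        for i, (vol, labels) in enumerate(population):
            grain_id = f"{strain}_{i:03d}"
            if config.save_volumes:
                podt_io.write_ri_volume(
                    vol, outdir / f"phantom_{grain_id}.h5", labels
                )
            try:
                record, result, qc = process_grain(
                    vol, config, grain_id, strain
                )
            except Exception as exc:
                raise RuntimeError(f"[pipeline/{grain_id}] {exc}") from exc
            if config.save_volumes:
                podt_io.write_ri_volume(
                    result.volume, outdir / f"recon_{grain_id}.h5"
                )
            qc["ground_truth_volume_pl"] = labels.volume_um3() / 1000.0
            records.append(record)
            qc_all[grain_id] = qc
    table = GroupTable.from_records(records)
    morpho = table.data.copy()
    for k, v in stamp.items():
        morpho[k] = v
    morpho.to_csv(outdir / "morphometrics.csv", index=False)

    summaries = pd.concat(
        [summarize(table, p) for p in table.parameters], ignore_index=True
    )
    summaries.to_csv(outdir / "summary.csv", index=False)

    if len(config.strains) >= 2:
        comps = []
        for p in table.parameters:
            comps.extend(
                compare_all(table, p, mode=config.stats_mode, holm=config.holm)
            )
        comparisons_frame(comps).to_csv(outdir / "comparisons.csv", index=False)

    (outdir / "qc.json").write_text(
        json.dumps({**stamp, "grains": qc_all}, indent=2, default=float)
    )
    return morpho
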