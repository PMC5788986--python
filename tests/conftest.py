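"""Shared fixtures: optical configs, scaled-down scans and phantom specs.

Simulation-backed tests run on reduced grids (64^3 at 0.25 um pitch, two
illumination rings) so the whole suite stays desk-scale; the one
full-default test (starch-count recovery) uses the package defaults.
"""

import numpy as np
import pytest

from pollenodt import (
    OpticalConfig,
    PhantomSpec,
    make_multiring_scan,
)
from pollenodt.volume import RIVolume, boundary_shell_mask

SMALL_N = 64
PITCH = 0.25
SMALL_RINGS = ((0.95, 24), (0.6, 12))


@pytest.fixture(scope="session")
def optics() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture(scope="session")
def small_scan(optics):
    return make_multiring_scan(
        optics, (SMALL_N, SMALL_N, SMALL_N), PITCH, rings=SMALL_RINGS
    )


def small_grain_spec(**overrides) -> PhantomSpec:
    """A bisaccate spec scaled to fit a 16 um (64^3) simulation box."""
    params = dict(
        corpus_semiaxes=(4.2, 4.0, 3.8),
        exine_thickness=0.8,
        cappa_thickness=1.2,
        saccus_radii=(2.0, 2.0),
        saccus_wall_thickness=0.6,
        wrinkle_depth=1.0,
        n_granules=0,
        granule_diameter_range=(1.2, 1.8),
        granule_gap_lateral=0.3,
        granule_gap_axial=0.4,
        granule_margin=0.4,
        seed=3,
    )
    params.update(overrides)
    return PhantomSpec(**params)


def assert_valid_phantom(volume: RIVolume) -> None:
    volume.validate(check_boundary=True)
    shell = boundary_shell_mask(volume.grid_shape, width=2)
    assert np.all(volume.values[shell] == volume.medium_ri)
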