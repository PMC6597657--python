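import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from octmorph.scan import ScanMeta
from octmorph.synth import FoveaGeometry, NoiseModel, OnhGeometry

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

AX_PX = 3.9      # default axial pitch, um/px
LAT_PX = 20.0    # default lateral pitch, um/px
DEG_PX = LAT_PX / 292.0   # one lateral pixel in degrees


@pytest.fixture(scope="session")
def onh_meta():
    return ScanMeta(scan_kind="onh")


@pytest.fixture(scope="session")
def fovea_meta():
    return ScanMeta(scan_kind="fovea")


@pytest.fixture(scope="session")
def pcg_geometry():
    """Disc geometry at the childhood-glaucoma group means."""
    return OnhGeometry()


@pytest.fixture(scope="session")
def control_fovea_geometry():
    """Foveal geometry at the healthy-child group mean pit width."""
    return FoveaGeometry()


@pytest.fixture(scope="session")
def no_noise():
    return NoiseModel.zero()


def random_onh_geometry(rng: np.random.Generator) -> OnhGeometry:
    disc = rng.uniform(4.5, 7.5)
    cup = rng.uniform(0.8, 0.85 * disc)
    return OnhGeometry(
        disc_diameter_deg=disc,
        cup_diameter_deg=cup,
        cup_depth_um=rng.uniform(250.0, 1100.0),
        rim_height_um=rng.uniform(60.0, 220.0),
        rnfl_nasal_um=rng.uniform(30.0, 100.0),
        rnfl_temporal_um=rng.uniform(30.0, 100.0),
        cup_profile=rng.choice(["parabolic", "cosine"]),
    )


def random_fovea_geometry(rng: np.random.Generator) -> FoveaGeometry:
    base = FoveaGeometry()
    scale = rng.uniform(0.8, 1.2)
    layers = {l: tuple(v * scale for v in zones)
              for l, zones in base.layer_thicknesses_um.items()}
    # the rim must clear the 2-6 deg plateau: depth at least the scaled
    # central-to-peripheral thickness difference
    min_depth = 82.0 * scale + 12.0
    return FoveaGeometry(
        pit_width_deg=rng.uniform(7.0, 11.0),
        pit_depth_um=rng.uniform(min_depth, min_depth + 55.0),
        layer_thicknesses_um=layers,
        elm_present=bool(rng.integers(0, 2)),
    )
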