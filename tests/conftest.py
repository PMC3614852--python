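"""Shared fixtures: small analytic phantoms with exact ground truth."""

import numpy as np
import pytest

from slicerecon import PhantomSpec, Volume, random_jitter

SPHERE_RADIUS = 10.0
SPHERE_CENTER = (15.35, 15.55, 15.45)  # slightly off-grid: no exact ties


@pytest.fixture(scope="session")
def sphere_spec() -> PhantomSpec:
    """r = 10 mm sphere on a 32^3 grid at 1 mm isotropic spacing."""
    return PhantomSpec(
        shape_kind="sphere",
        shape_params={"radius": SPHERE_RADIUS, "center": SPHERE_CENTER},
        grid_shape=(32, 32, 32),
        spacing=(1.0, 1.0, 1.0),
    )


@pytest.fixture(scope="session")
def torus_spec() -> PhantomSpec:
    return PhantomSpec(
        shape_kind="torus",
        shape_params={"major_radius": 8.0, "minor_radius": 3.0, "center": (15.4, 15.6, 15.5)},
        grid_shape=(32, 32, 32),
        spacing=(1.0, 1.0, 1.0),
    )


@pytest.fixture(scope="session")
def tube_spec() -> PhantomSpec:
    return PhantomSpec(
        shape_kind="tube",
        shape_params={
            "radius": 3.0,
            "control_points": [(8.0, 15.5, 7.0), (16.0, 13.0, 15.5), (23.0, 16.5, 24.0)],
        },
        grid_shape=(32, 32, 32),
        spacing=(1.0, 1.0, 1.0),
    )


def bright_field(volume: Volume) -> Volume:
    """Negated signed-distance field: inside positive (bright), isovalue 0."""
    return Volume(-volume.data, volume.spacing, volume.origin)


# --- rendered stack phantom with fiducials (pixel grid 96x96, 0.33 mm) ----

STACK_GRID = (96, 96, 20)
STACK_SPACING = (0.33, 0.33, 1.0)
_W = (STACK_GRID[0] - 1) * STACK_SPACING[0]
_H = (STACK_GRID[1] - 1) * STACK_SPACING[1]
#: rods with well-separated y so (y, x) label order survives jitter
STACK_FIDUCIALS = [(_W / 2, 3.0, 1.2), (_W - 3.0, _H / 2, 1.2), (3.0, _H - 3.0, 1.2)]
STACK_SPHERE = {"radius": 8.0, "center": (_W / 2, _H / 2, 9.5)}


def stack_spec(noise_sigma=0.0, jitter=None, seed=0) -> PhantomSpec:
    return PhantomSpec(
        shape_kind="sphere",
        shape_params=dict(STACK_SPHERE),
        grid_shape=STACK_GRID,
        spacing=STACK_SPACING,
        fiducials=list(STACK_FIDUCIALS),
        noise_sigma=noise_sigma,
        jitter=jitter,
        seed=seed,
    )


@pytest.fixture(scope="session")
def rigid_jitter() -> list:
    return random_jitter(
        STACK_GRID[2], seed=5, max_translation_px=3.0, max_rotation_deg=2.0,
        image_shape=(STACK_GRID[1], STACK_GRID[0]),
    )
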