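"""Shared fixtures: small, fast phantoms reused across the suite."""

import numpy as np
import pytest

import craniogen as cg


@pytest.fixture(scope="session")
def small_geometry():
    """Compact grid for fast unit tests (96 mm cube at 1.5 mm)."""
    return cg.VolumeGeometry((64, 64, 48), (1.5, 1.5, 1.5))


@pytest.fixture(scope="session")
def small_spec(small_geometry):
    """A clean shell phantom that fits the small grid."""
    return cg.PhantomSpec(
        geometry=small_geometry,
        outer_radii=(34.0, 40.0, 28.0),
        shell_thickness=5.0,
        n_calcifications=0,
        include_table=False,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return cg.generate_phantom(small_spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Default-geometry phantom with all nuisance structures disabled."""
    return cg.generate_phantom(
        cg.PhantomSpec(n_calcifications=0, include_table=False, seed=7)
    )


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-geometry phantom with table slab and calcifications."""
    return cg.generate_phantom(
        cg.PhantomSpec(n_calcifications=8, include_table=True, seed=7)
    )


def dice(a: cg.SkullMask, b: cg.SkullMask) -> float:
    inter = (a.as_bool() & b.as_bool()).sum()
    denom = a.voxel_count + b.voxel_count
    return 2.0 * inter / denom if denom else 1.0
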