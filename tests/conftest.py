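import numpy as np
import pytest

from ezloc.imaging import BinaryMask, Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    data = rng.random((8, 8, 8))
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = [-7.0, -7.0, -7.0]
    return Volume3D(data, affine)


@pytest.fixture
def small_mask(small_volume, rng):
    return BinaryMask(rng.random(small_volume.shape) > 0.4, small_volume.affine)


@pytest.fixture(scope="session")
def focal_bundle():
    """One focal ground-truth bundle shared by read-only tests."""
    from ezloc.synthetic import ScenarioSpec, build_bundle

    return build_bundle(ScenarioSpec(scenario="focal", seed=42))


@pytest.fixture(scope="session")
def sphere_setup():
    """642-vertex source sphere, 10-20 montage, sphere leadfield."""
    from ezloc.headmodel import (
        leadfield_sphere3,
        make_sphere_source_space,
        standard_montage,
    )
    from ezloc.synthetic import (
        CORTEX_RADIUS_MM,
        HEAD_RADIUS_MM,
        SHELL_CONDUCTIVITIES,
        SHELL_RADII_MM,
    )

    src = make_sphere_source_space(3, CORTEX_RADIUS_MM)
    elec = standard_montage("10-20", scalp_radius_mm=HEAD_RADIUS_MM)
    lf = leadfield_sphere3(src, elec, SHELL_RADII_MM, SHELL_CONDUCTIVITIES)
    return src, elec, lf
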