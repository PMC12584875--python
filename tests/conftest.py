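"""Shared fixtures: small phantoms and point clouds generated at test time."""

import numpy as np
import pytest

from tomothick import phantom, surface
from tomothick.volume_io import LabelVolume


@pytest.fixture(scope="session")
def slab_phantom():
    """Default tilted slab phantom (noise-free), shared across tests."""
    spec = phantom.PhantomSpec(geometry="slab", shape=(48, 64, 64))
    vol, lab, truth = phantom.generate(spec)
    return vol, lab, truth


@pytest.fixture(scope="session")
def slab_surface(slab_phantom):
    _vol, lab, _truth = slab_phantom
    return surface.reconstruct_surface(lab, 1)


@pytest.fixture(scope="session")
def small_sphere_phantom():
    """Small hollow sphere phantom for curvature/side-assignment tests."""
    spec = phantom.PhantomSpec(
        geometry="sphere", shape=(64, 64, 64), sphere_radius_nm=18.0,
        thickness_nm=4.6,
    )
    vol, lab, truth = phantom.generate(spec)
    return vol, lab, truth


@pytest.fixture()
def flat_slab_labels():
    """Axis-aligned 18x18x4-voxel slab instance inside a larger volume."""
    labels = np.zeros((12, 24, 24), dtype=np.int32)
    labels[4:8, 3:21, 3:21] = 1
    return LabelVolume(labels, 7.84)


@pytest.fixture()
def hollow_shell_labels():
    """Hollow sphere shell: outer radius 12, inner radius 8 voxels."""
    n = 30
    c = (n - 1) / 2
    idx = np.indices((n, n, n))
    r = np.sqrt(((idx - c) ** 2).sum(axis=0))
    labels = ((r <= 12) & (r >= 8)).astype(np.int32)
    return LabelVolume(labels, 10.0)
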