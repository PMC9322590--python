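"""Shared fixtures: the default phantom and its segmentation are expensive
(seconds), so they are built once per session and shared read-only."""

import numpy as np
import pytest

import spinevoi as sv

#: Reduced-resolution phantom used where full 1.5 mm resolution is not the
#: point of the test (identical geometry in mm, 2.5 mm voxels).
SMALL_GRID = dict(grid_shape=(78, 78, 104), voxel_spacing_mm=(2.5, 2.5, 2.5))


@pytest.fixture(scope="session")
def default_phantom() -> sv.PhantomResult:
    return sv.generate_spine_phantom(sv.PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def default_vois(default_phantom) -> sv.VoiSet:
    return sv.segment_all(default_phantom.labels, sv.MorphParams())


@pytest.fixture(scope="session")
def small_phantom() -> sv.PhantomResult:
    return sv.generate_spine_phantom(sv.PhantomConfig(seed=7, **SMALL_GRID))


def box(shape, x, y, z):
    """Boolean volume with a single axis-aligned box set (index ranges)."""
    m = np.zeros(shape, bool)
    m[x[0]:x[1], y[0]:y[1], z[0]:z[1]] = True
    return m
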