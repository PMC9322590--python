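"""VOI extraction: box-toy oracles, inventory, invariants, determinism."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import cKDTree

import spinevoi as sv
from spinevoi import voi

from conftest import SMALL_GRID, box

SP1 = (1.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# Independent brute-force morphology oracle (no scipy.ndimage)
# ---------------------------------------------------------------------------

def brute_erode(mask, radius, spacing):
    """Keep voxels whose distance to the nearest background voxel centre
    (outside-grid counts as background) exceeds the radius."""
    padded = np.pad(mask, 1)
    bg = (np.argwhere(~padded) - 1) * np.asarray(spacing, float)
    fg_idx = np.argwhere(mask)
    d, _ = cKDTree(bg).query(fg_idx * np.asarray(spacing, float))
    out = np.zeros_like(mask)
    out[tuple(fg_idx[d > radius + 1e-7].T)] = True
    return out


def brute_capped_box_dilate(mask, radius, cap, spacing):
    """Union of integer shifts within the capped box, via np.roll-free pads."""
    r = [int(np.floor(radius / s + 1e-7)) for s in spacing]
    out = np.zeros_like(mask)
    for dx in range(-r[0], r[0] + 1):
        for dy in range(-r[1], r[1] + 1):
            if dy * spacing[1] > cap + 1e-7:
                continue
            for dz in range(-r[2], r[2] + 1):
                shifted = mask
                for ax, d in ((0, dx), (1, dy), (2, dz)):
                    if d:
                        shifted = np.roll(shifted, d, axis=ax)
                        sl = [slice(None)] * 3
                        sl[ax] = slice(0, d) if d > 0 else slice(d, None)
                        shifted = shifted.copy()
                        shifted[tuple(sl)] = False
                out |= shifted
    return out


def test_body_matches_brute_force_set_oracle():
    """Flush-attached posterior process: voxel-for-voxel agreement with an
    independently coded erode / largest-component / capped-dilate / intersect
    composition."""
    m = box((60, 70, 50), (10, 44), (10, 44), (10, 38))
    m |= box((60, 70, 50), (23, 31), (44, 60), (15, 23))  # 8 mm process
    p = sv.MorphParams()
    got = sv.extract_vertebral_body(m, SP1, p)
    er = brute_erode(m, p.body_erosion_mm, SP1)
    # single component by construction here
    oracle = brute_capped_box_dilate(er, p.body_dilation_mm,
                                     p.body_dilation_posterior_mm, SP1) & m
    assert np.array_equal(got, oracle)


def test_body_recovers_block_when_process_detached():
    """A posterior process beyond the dilation reach: the body VOI is
    exactly the original block (the process is annihilated by erosion and
    never re-captured)."""
    shape = (60, 70, 50)
    block = box(shape, (10, 44), (10, 44), (10, 38))
    m = block | box(shape, (23, 31), (46, 62), (15, 23))
    got = sv.extract_vertebral_body(m, SP1, sv.MorphParams())
    assert np.array_equal(got, block)


def test_body_subset_of_vertebra_on_phantom(default_phantom, default_vois):
    labels = default_phantom.labels
    for name, mask in default_vois.bodies.items():
        vert = labels.mask(labels.label_of(name))
        assert mask.any()
        assert not (mask & ~vert).any()


def test_body_erosion_annihilates_thin_cube():
    cube = box((40, 40, 40), (10, 28), (10, 28), (10, 28))  # 18 mm
    with pytest.raises(sv.DegenerateGeometryError):
        sv.extract_vertebral_body(cube, SP1, sv.MorphParams())


def test_body_empty_input_raises():
    with pytest.raises(sv.InvalidInputError):
        sv.extract_vertebral_body(np.zeros((5, 5, 5), bool), SP1)


# ---------------------------------------------------------------------------
# Facets
# ---------------------------------------------------------------------------

def _toy_vertebra(zb, posterior="columns", shape=(80, 80, 100)):
    v = box(shape, (20, 60), (10, 40), (zb, zb + 28))
    if posterior == "columns":
        for x0, x1 in ((12, 20), (60, 68)):
            v |= box(shape, (x0, x1), (40, 48), (zb - 6, zb + 26))
    elif posterior == "spinous":
        v |= box(shape, (36, 44), (40, 56), (zb - 6, zb + 26))
    return v


def test_facet_toy_bilateral_and_mirror_symmetric():
    """Columns 4 mm apart cranio-caudally, mirror-symmetric about the
    midline: exactly two facet components with equal voxel counts."""
    p = sv.MorphParams()
    lower, upper = _toy_vertebra(20), _toy_vertebra(56)
    lb = sv.extract_vertebral_body(lower, SP1, p)
    ub = sv.extract_vertebral_body(upper, SP1, p)
    left, right = sv.extract_facet_joints(upper, lower, ub, lb, SP1, p)
    assert left.sum() == right.sum() > 0
    assert np.array_equal(left, right[::-1, :, :])
    # each facet stays inside its source vertebrae
    assert not ((left | right) & ~(upper | lower)).any()


def test_midline_spinous_contact_is_removed():
    """When the only posterior contact is between midline spinous
    processes, the centerline rule removes every component."""
    p = sv.MorphParams()
    lower, upper = _toy_vertebra(20, "spinous"), _toy_vertebra(56, "spinous")
    lb = sv.extract_vertebral_body(lower, SP1, p)
    ub = sv.extract_vertebral_body(upper, SP1, p)
    left, right = sv.extract_facet_joints(upper, lower, ub, lb, SP1, p)
    assert not left.any() and not right.any()


def test_facet_no_contact_returns_empty():
    p = sv.MorphParams()
    lower, upper = _toy_vertebra(10), _toy_vertebra(62)  # 24 mm column gap
    lb = sv.extract_vertebral_body(lower, SP1, p)
    ub = sv.extract_vertebral_body(upper, SP1, p)
    left, right = sv.extract_facet_joints(upper, lower, ub, lb, SP1, p)
    assert not left.any() and not right.any()


def test_lowest_facets_confined_to_inferior_slab():
    p = sv.MorphParams()
    l5 = _toy_vertebra(40)
    l5b = sv.extract_vertebral_body(l5, SP1, p)
    left, right = sv.extract_lowest_facets(l5, l5b, None, SP1, p)
    assert left.sum() == right.sum() > 0
    zmin = np.nonzero(l5)[2].min()
    zmax = np.nonzero(left | right)[2].max()
    # slab plus the geodesic refinement reach
    assert (zmax - zmin + 1) * SP1[2] <= (p.lowest_facet_slab_mm
                                          + p.facet_refine_dilation_mm)
    assert np.array_equal(left, right[::-1, :, :])


def test_lowest_facets_zero_slab_raises():
    p = dataclasses.replace(sv.MorphParams(), lowest_facet_slab_mm=0.0)
    l5 = _toy_vertebra(40)
    l5b = sv.extract_vertebral_body(l5, SP1, sv.MorphParams())
    with pytest.raises(sv.DegenerateGeometryError):
        sv.extract_lowest_facets(l5, l5b, None, SP1, p)


# ---------------------------------------------------------------------------
# Discs
# ---------------------------------------------------------------------------

def test_disc_toy_matches_set_operation_oracle():
    """Coaxial 30x30x25 bodies with an 8 mm gap: the disc is exactly the
    gap region under the shared footprint."""
    shape = (60, 60, 80)
    lower = box(shape, (15, 45), (15, 45), (10, 35))
    upper = box(shape, (15, 45), (15, 45), (43, 68))
    got = sv.extract_disc(upper, lower, SP1, sv.MorphParams())
    oracle = box(shape, (15, 45), (15, 45), (35, 43))
    assert np.array_equal(got, oracle)


def test_disc_offset_bodies_matches_shared_footprint_oracle():
    """Laterally offset bodies: the disc is the gap restricted to the
    shared footprint of the two bodies."""
    shape = (70, 60, 80)
    lower = box(shape, (10, 40), (15, 45), (10, 35))
    upper = box(shape, (25, 55), (15, 45), (43, 68))
    got = sv.extract_disc(upper, lower, SP1, sv.MorphParams())
    oracle = box(shape, (25, 40), (15, 45), (35, 43))
    assert np.array_equal(got, oracle)


def test_disc_wide_gap_reports_empty():
    shape = (60, 60, 100)
    lower = box(shape, (15, 45), (15, 45), (5, 30))
    upper = box(shape, (15, 45), (15, 45), (60, 85))  # 30 mm gap
    got = sv.extract_disc(upper, lower, SP1, sv.MorphParams())
    assert not got.any()


def test_disc_overlapping_bodies_rejected():
    shape = (40, 40, 40)
    a = box(shape, (5, 20), (5, 20), (5, 20))
    with pytest.raises(sv.InvalidInputError):
        sv.extract_disc(a, a, SP1)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def test_segment_all_inventory(default_vois):
    assert default_vois.n_bodies == 5
    assert default_vois.n_discs == 4
    assert default_vois.n_facets == 10


def test_segment_all_invariants(default_phantom, default_vois):
    labels = default_phantom.labels
    all_bodies = np.zeros(labels.array.shape, bool)
    for m in default_vois.bodies.values():
        all_bodies |= m
    for name, disc in default_vois.discs.items():
        assert not (disc & all_bodies).any(), name
    for (pair, side), facet in default_vois.facets.items():
        up, lo = pair.split("-")
        union = labels.mask(labels.label_of(up))
        if lo != "S1":
            union = union | labels.mask(labels.label_of(lo))
        elif labels.label_of("sacrum") is not None:
            union = union | labels.mask(labels.label_of("sacrum"))
        assert not (facet & ~union).any(), (pair, side)


def test_segment_all_deterministic(small_phantom):
    a = sv.segment_all(small_phantom.labels)
    b = sv.segment_all(small_phantom.labels)
    for region in ("vertebral_bodies", "intervertebral_discs", "facet_joints"):
        ma, mb = a.region_masks(region), b.region_masks(region)
        assert ma.keys() == mb.keys()
        for k in ma:
            assert np.array_equal(ma[k], mb[k])


def test_segment_all_without_sacrum_still_ten_facets():
    res = sv.generate_spine_phantom(sv.PhantomConfig(sacrum=False, seed=7,
                                                     **SMALL_GRID))
    vois = sv.segment_all(res.labels)
    assert vois.n_facets == 10 and vois.n_discs == 4
    # the L5-S1 facets came from the lowest-facet rule on L5 alone
    l5 = res.labels.mask(res.labels.label_of("L5"))
    for side in ("left", "right"):
        m = vois.facets[("L5-S1", side)]
        assert m.any() and not (m & ~l5).any()


def test_segment_all_missing_level_raises(small_phantom):
    labels = small_phantom.labels
    broken = sv.LabeledVolume(labels.array, labels.spacing_mm,
                              {k: ("lumbar?" if v == "L3" else v)
                               for k, v in labels.legend.items()})
    with pytest.raises(sv.ConfigError, match="L3"):
        sv.segment_all(broken)


def test_scaling_equivariance_of_voi_volumes():
    """Halving the voxel spacing (1.5 mm -> 0.75 mm) with fixed mm
    parameters changes VOI volumes in mL by less than 10%."""
    p = sv.MorphParams()
    vols = {}
    for sp in (1.5, 0.75):
        n = int(round(120 / sp))
        shape = (n, n, n)
        spacing = (sp, sp, sp)

        def mm(c):  # toy coordinates are multiples of 3 mm, exact on both grids
            return int(round(c / sp))

        def vert(zb):
            v = box(shape, (mm(39), mm(81)), (mm(9), mm(39)),
                    (mm(zb), mm(zb + 27)))
            for x0, x1 in ((30, 39), (81, 90)):
                v |= box(shape, (mm(x0), mm(x1)), (mm(39), mm(48)),
                         (mm(zb - 6), mm(zb + 24)))
            return v

        lower, upper = vert(21), vert(57)
        lb = sv.extract_vertebral_body(lower, spacing, p)
        ub = sv.extract_vertebral_body(upper, spacing, p)
        disc = sv.extract_disc(ub, lb, spacing, p)
        left, right = sv.extract_facet_joints(upper, lower, ub, lb, spacing, p)
        vml = sp ** 3 / 1000.0
        vols[sp] = {"body": lb.sum() * vml, "disc": disc.sum() * vml,
                    "facet": (left.sum() + right.sum()) * vml}
    for key in vols[1.5]:
        a, b = vols[1.5][key], vols[0.75][key]
        assert a > 0 and b > 0
        assert abs(a - b) / b < 0.10, (key, a, b)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(11, 16), st.integers(11, 16), st.integers(11, 16),
       st.floats(1.0, 6.0))
def test_erosion_dilation_sandwich_property(wx, wy, wz, r):
    """erode(m, r) is a subset of m, m is a subset of dilate(m, r), and both
    are monotone in r, for random box masks and radii."""
    m = box((30, 30, 30), (8, 8 + wx), (8, 8 + wy), (8, 8 + wz))
    er = voi.erode_mm(m, r, SP1)
    di = voi.dilate_mm(m, r, SP1)
    assert not (er & ~m).any()
    assert not (m & ~di).any()
    er2 = voi.erode_mm(m, r + 1.0, SP1)
    di2 = voi.dilate_mm(m, r + 1.0, SP1)
    assert not (er2 & ~er).any()
    assert not (di & ~di2).any()
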