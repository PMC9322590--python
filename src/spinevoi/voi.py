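"""Morphological extraction of vertebral-body, facet-joint and disc VOIs.

Input is an integer-labelled vertebra mask (one label per lumbar vertebra,
optional sacrum).  Three recipes derive the volumes of interest:

* **Vertebral body** -- erode the vertebra by 10 mm (which removes the thin
  posterior elements), keep the largest component, re-dilate it slightly more
  than 10 mm in every direction except posteriorly (toward the pedicles,
  capped at 10 mm), and intersect with the original vertebra.
* **Facet joints** -- take the posterior elements (vertebra minus its body),
  dilate those of both neighbouring vertebrae along the cranio-caudal axis
  and intersect to get the inter-level contact area; grow that contact area
  geodesically inside the two vertebrae, keep the two largest components, and
  discard any component whose centroid lies too close to the sagittal
  midline (this removes spurious spinous-process contacts).
* **Lowest facets (L5-S1)** -- no inter-vertebral contact is available, so
  the inferior slab of the posterior elements of L5 seeds the same geodesic
  refinement (within L5 plus the sacrum when present).
* **Intervertebral disc** -- dilate the two adjacent vertebral bodies toward
  each other along the cranio-caudal axis and intersect; remove "forbidden"
  rims obtained by in-plane (axial slice-wise) dilation of each body, and
  remove the bodies themselves.

Morphology contract: "erode/dilate by d mm" uses a metric ball of radius d
realised through the voxel spacing (Euclidean distance transform threshold),
so anisotropic grids are handled by construction.  "Dilate along axis A" uses
a 1-D segment of half-length d.  "Geodesic dilation within M" is iterated
one-voxel dilation intersected with M.  Everything is deterministic: ties in
"largest component" break by voxel count, then inferior-most centroid, then
component id.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve

from .errors import ConfigError, DegenerateGeometryError, InvalidInputError
from .phantom import LabeledVolume

logger = logging.getLogger("spinevoi.voi")

__all__ = [
    "MorphParams",
    "VoiSet",
    "erode_mm",
    "dilate_mm",
    "dilate_axis_mm",
    "geodesic_dilate_mm",
    "extract_vertebral_body",
    "extract_facet_joints",
    "extract_lowest_facets",
    "extract_disc",
    "segment_all",
]

_EPS = 1e-7


@dataclass(frozen=True)
class MorphParams:
    """Physical-distance parameters of the three VOI recipes (all mm)."""

    body_erosion_mm: float = 10.0
    body_dilation_mm: float = 12.0
    body_dilation_posterior_mm: float = 10.0
    facet_contact_dilation_mm: float = 5.0   # cranio-caudal
    facet_refine_dilation_mm: float = 3.0    # geodesic
    centerline_exclusion_mm: float = 5.0
    lowest_facet_slab_mm: float = 10.0
    disc_dilation_mm: float = 10.0           # cranio-caudal
    disc_forbidden_dilation_mm: float = 3.0  # in the transverse plane
    connectivity: int = 26

    def validate(self) -> None:
        dists = (self.body_erosion_mm, self.body_dilation_mm,
                 self.body_dilation_posterior_mm, self.facet_contact_dilation_mm,
                 self.facet_refine_dilation_mm, self.centerline_exclusion_mm,
                 self.lowest_facet_slab_mm, self.disc_dilation_mm,
                 self.disc_forbidden_dilation_mm)
        if any(d < 0 for d in dists):
            raise ConfigError("all morphological distances must be >= 0")
        if self.body_dilation_mm <= self.body_erosion_mm:
            raise ConfigError("body_dilation_mm must exceed body_erosion_mm")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")

    @property
    def structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)


# ---------------------------------------------------------------------------
# Low-level metric morphology (bounding-box cropped for speed)
# ---------------------------------------------------------------------------

def _crop(mask: np.ndarray, pad_vox: tuple[int, int, int]):
    """Bounding-box slices of ``mask`` grown by ``pad_vox``, clipped to grid."""
    idx = np.nonzero(mask)
    if idx[0].size == 0:
        return None
    sls = tuple(slice(max(int(ax.min()) - p, 0),
                      min(int(ax.max()) + p + 1, n))
                for ax, p, n in zip(idx, pad_vox, mask.shape))
    return sls


def erode_mm(mask: np.ndarray, radius_mm: float,
             spacing_mm: tuple[float, float, float]) -> np.ndarray:
    """Metric erosion: keep voxels farther than ``radius_mm`` from background."""
    if radius_mm <= 0:
        return mask.copy()
    sls = _crop(mask, (1, 1, 1))
    out = np.zeros_like(mask, dtype=bool)
    if sls is None:
        return out
    sub = np.pad(mask[sls], 1)  # treat outside-grid as background
    dist = ndimage.distance_transform_edt(sub, sampling=spacing_mm)
    out[sls] = dist[1:-1, 1:-1, 1:-1] > radius_mm + _EPS
    return out


def dilate_mm(mask: np.ndarray, radius_mm: float,
              spacing_mm: tuple[float, float, float]) -> np.ndarray:
    """Metric dilation: all voxels within ``radius_mm`` of the mask."""
    if radius_mm <= 0:
        return mask.copy()
    pad = tuple(math.ceil(radius_mm / s) + 1 for s in spacing_mm)
    sls = _crop(mask, pad)
    out = np.zeros_like(mask, dtype=bool)
    if sls is None:
        return out
    dist = ndimage.distance_transform_edt(~mask[sls], sampling=spacing_mm)
    out[sls] = dist <= radius_mm + _EPS
    return out


def dilate_axis_mm(mask: np.ndarray, half_length_mm: float, axis: int,
                   spacing_mm: tuple[float, float, float]) -> np.ndarray:
    """Dilation with a 1-D segment of half-length ``half_length_mm`` along ``axis``."""
    k = int(math.floor(half_length_mm / spacing_mm[axis] + _EPS))
    if k <= 0:
        return mask.copy()
    pad = [0, 0, 0]
    pad[axis] = k + 1
    sls = _crop(mask, tuple(pad))
    out = np.zeros_like(mask, dtype=bool)
    if sls is None:
        return out
    shape = [1, 1, 1]
    shape[axis] = 2 * k + 1
    out[sls] = ndimage.binary_dilation(mask[sls], structure=np.ones(shape, bool))
    return out


def _capped_box_footprint(radius_mm: float, cap_mm: float, cap_axis: int,
                          spacing_mm) -> np.ndarray:
    """Per-axis box of half-extent ``radius_mm``, truncated at offset
    <= ``cap_mm`` along the +cap_axis direction.

    A box rather than a metric ball: "dilate by d mm in all directions" here
    means reaching d mm along every axis independently, so that a structure
    eroded by r < d and re-dilated recovers its corners.
    """
    radii = [int(math.floor(radius_mm / s + _EPS)) for s in spacing_mm]
    grids = np.meshgrid(*(np.arange(-r, r + 1) * s
                          for r, s in zip(radii, spacing_mm)), indexing="ij")
    fp = np.ones(grids[0].shape, dtype=bool)
    fp &= grids[cap_axis] <= cap_mm + _EPS
    return fp


def dilate_capped_mm(mask: np.ndarray, radius_mm: float, cap_mm: float,
                     cap_axis: int, spacing_mm) -> np.ndarray:
    """Box dilation of half-extent ``radius_mm``, capped at ``cap_mm`` toward +axis."""
    fp = _capped_box_footprint(radius_mm, cap_mm, cap_axis, spacing_mm)
    pad = tuple((n + 1) // 2 for n in fp.shape)
    sls = _crop(mask, pad)
    out = np.zeros_like(mask, dtype=bool)
    if sls is None:
        return out
    conv = fftconvolve(mask[sls].astype(np.float32), fp.astype(np.float32),
                       mode="same")
    out[sls] = conv > 0.5
    return out


def dilate_inplane_mm(mask: np.ndarray, radius_mm: float,
                      spacing_mm) -> np.ndarray:
    """Slice-wise dilation with a 2-D metric disc in the transverse (x-y) plane."""
    rx = int(math.ceil(radius_mm / spacing_mm[0]))
    ry = int(math.ceil(radius_mm / spacing_mm[1]))
    gx, gy = np.meshgrid(np.arange(-rx, rx + 1) * spacing_mm[0],
                         np.arange(-ry, ry + 1) * spacing_mm[1], indexing="ij")
    fp = (gx ** 2 + gy ** 2 <= (radius_mm + _EPS) ** 2)[..., None]
    sls = _crop(mask, (rx + 1, ry + 1, 0))
    out = np.zeros_like(mask, dtype=bool)
    if sls is None:
        return out
    out[sls] = ndimage.binary_dilation(mask[sls], structure=fp)
    return out


def geodesic_dilate_mm(seed: np.ndarray, within: np.ndarray, dist_mm: float,
                       spacing_mm) -> np.ndarray:
    """Grow ``seed`` by iterated one-voxel dilation constrained to
    ``within`` (plus the seed itself) and return the grown set clipped to
    ``within``.

    The seed may lie partly outside ``within`` -- e.g. a contact area in the
    gap between two vertebrae that is dilated into the neighbouring bone --
    but growth can never crawl across background that belongs to neither,
    because every step is clipped to ``within | seed``.  The number of
    iterations is ``ceil(dist_mm / min(spacing))``, so the growth reaches at
    least ``dist_mm`` along the best-resolved axis.
    """
    n_iter = int(math.ceil(dist_mm / min(spacing_mm) - _EPS))
    if n_iter <= 0 or not seed.any():
        return seed & within
    region = within | seed
    sls = _crop(region, (1, 1, 1))
    sub_region = region[sls]
    sub_within = within[sls]
    sub = seed[sls]
    struct = ndimage.generate_binary_structure(3, 3)
    for _ in range(n_iter):
        sub = ndimage.binary_dilation(sub, structure=struct) & sub_region
    out = np.zeros_like(seed, dtype=bool)
    out[sls] = sub & sub_within
    return out


def _components(mask: np.ndarray, params: MorphParams):
    lbl, n = ndimage.label(mask, structure=params.structure)
    return lbl, n


def _largest_components(mask: np.ndarray, k: int, params: MorphParams,
                        spacing_mm) -> list[np.ndarray]:
    """Up to ``k`` largest connected components, deterministically ordered."""
    lbl, n = _components(mask, params)
    if n == 0:
        return []
    counts = ndimage.sum_labels(np.ones_like(lbl), lbl, index=range(1, n + 1))
    centroids = ndimage.center_of_mass(mask, lbl, index=range(1, n + 1))
    order = sorted(range(n), key=lambda i: (-counts[i],
                                            centroids[i][2] * spacing_mm[2], i))
    return [lbl == i + 1 for i in order[:k]]


def _centroid_mm(mask: np.ndarray, spacing_mm) -> tuple[float, float, float]:
    c = ndimage.center_of_mass(mask)
    return tuple((ci + 0.5) * s for ci, s in zip(c, spacing_mm))


# ---------------------------------------------------------------------------
# VOI recipes
# ---------------------------------------------------------------------------

def extract_vertebral_body(vertebra_mask: np.ndarray, spacing_mm,
                           params: MorphParams | None = None,
                           name: str = "vertebra") -> np.ndarray:
    """Vertebral-body VOI: erode, keep largest component, re-dilate, intersect.

    The re-dilation radius is ``body_dilation_mm`` in all directions except
    posteriorly (+y, toward the pedicles) where it is capped at
    ``body_dilation_posterior_mm``; the final intersection with the input
    guarantees the result is a subset of the vertebra.
    """
    p = params or MorphParams()
    p.validate()
    if not vertebra_mask.any():
        raise InvalidInputError(f"{name}: empty vertebra mask")
    eroded = erode_mm(vertebra_mask, p.body_erosion_mm, spacing_mm)
    if not eroded.any():
        raise DegenerateGeometryError(
            f"{name}: erosion at {p.body_erosion_mm} mm annihilated the mask "
            f"(structure thinner than {2 * p.body_erosion_mm} mm)")
    core = _largest_components(eroded, 1, p, spacing_mm)[0]
    dilated = dilate_capped_mm(core, p.body_dilation_mm,
                               p.body_dilation_posterior_mm, cap_axis=1,
                               spacing_mm=spacing_mm)
    return dilated & vertebra_mask


def _refine_facet_candidates(initial: np.ndarray, within: np.ndarray,
                             bodies_union: np.ndarray, spacing_mm,
                             params: MorphParams,
                             context: str) -> tuple[np.ndarray, np.ndarray]:
    """Shared facet refinement: geodesic growth, two largest components,
    centerline removal, left/right assignment."""
    empty = np.zeros_like(initial, dtype=bool)
    if not initial.any():
        logger.warning("%s: empty facet seed; returning empty masks", context)
        return empty, empty.copy()
    cand = geodesic_dilate_mm(initial, within, params.facet_refine_dilation_mm,
                              spacing_mm)
    comps = _largest_components(cand, 2, params, spacing_mm)
    ref = bodies_union if bodies_union.any() else within
    xs = np.nonzero(ref)[0]
    midline = (np.median(xs) + 0.5) * spacing_mm[0]
    kept = []
    for comp in comps:
        cx = _centroid_mm(comp, spacing_mm)[0]
        if abs(cx - midline) < params.centerline_exclusion_mm:
            logger.info("%s: dropped component near the sagittal midline "
                        "(centroid %.1f mm, midline %.1f mm)", context, cx, midline)
            continue
        kept.append((cx, comp))
    if not kept:
        logger.warning("%s: no facet component survived refinement", context)
        return empty, empty.copy()
    if len(kept) == 1:
        logger.warning("%s: only one facet component survived (asymmetry)", context)
        cx, comp = kept[0]
        return (comp, empty.copy()) if cx < midline else (empty, comp)
    kept.sort(key=lambda t: t[0])
    return kept[0][1], kept[1][1]


def extract_facet_joints(upper: np.ndarray, lower: np.ndarray,
                         upper_body: np.ndarray, lower_body: np.ndarray,
                         spacing_mm, params: MorphParams | None = None,
                         context: str = "facet") -> tuple[np.ndarray, np.ndarray]:
    """Facet-joint VOIs between two adjacent vertebrae (left, right)."""
    p = params or MorphParams()
    p.validate()
    if not upper.any() or not lower.any():
        raise InvalidInputError(f"{context}: empty vertebra mask")
    post_u = upper & ~upper_body
    post_l = lower & ~lower_body
    contact = (dilate_axis_mm(post_u, p.facet_contact_dilation_mm, 2, spacing_mm)
               & dilate_axis_mm(post_l, p.facet_contact_dilation_mm, 2, spacing_mm))
    return _refine_facet_candidates(contact, upper | lower,
                                    upper_body | lower_body, spacing_mm, p,
                                    context)


def extract_lowest_facets(l5: np.ndarray, l5_body: np.ndarray,
                          sacrum: np.ndarray | None, spacing_mm,
                          params: MorphParams | None = None,
                          context: str = "facet L5-S1"
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Lowest facet VOIs, seeded by the inferior slab of the L5 posterior elements."""
    p = params or MorphParams()
    p.validate()
    if not l5.any():
        raise InvalidInputError(f"{context}: empty L5 mask")
    post = l5 & ~l5_body
    zs = np.nonzero(l5)[2]
    z_inferior = zs.min() * spacing_mm[2]  # inferior edge of the lowest voxel row
    z_coord = (np.arange(l5.shape[2]) + 0.5) * spacing_mm[2]
    slab = z_coord < z_inferior + p.lowest_facet_slab_mm - _EPS
    initial = post & slab[None, None, :]
    if not initial.any():
        raise DegenerateGeometryError(
            f"{context}: inferior slab of {p.lowest_facet_slab_mm} mm contains "
            "no posterior-element voxels")
    within = l5 | sacrum if sacrum is not None else l5
    return _refine_facet_candidates(initial, within, l5_body, spacing_mm, p,
                                    context)


def extract_disc(upper_body: np.ndarray, lower_body: np.ndarray, spacing_mm,
                 params: MorphParams | None = None,
                 context: str = "disc") -> np.ndarray:
    """Intervertebral-disc VOI between two adjacent vertebral bodies.

    The initial estimate is the overlap of the two bodies dilated toward each
    other along the cranio-caudal axis; lateral "forbidden" rims (in-plane
    dilation of each body minus its own axial footprint column) and the
    bodies themselves are removed.  A gap wider than twice the dilation
    distance yields an empty disc, which is logged as a missing VOI.
    """
    p = params or MorphParams()
    p.validate()
    if not upper_body.any() or not lower_body.any():
        raise InvalidInputError(f"{context}: empty body mask")
    if (upper_body & lower_body).any():
        raise InvalidInputError(f"{context}: body masks overlap")
    initial = (dilate_axis_mm(upper_body, p.disc_dilation_mm, 2, spacing_mm)
               & dilate_axis_mm(lower_body, p.disc_dilation_mm, 2, spacing_mm))
    if not initial.any():
        logger.warning("%s: dilated bodies do not meet (gap too wide); "
                       "missing VOI", context)
        return np.zeros_like(upper_body, dtype=bool)
    out = initial
    for body in (upper_body, lower_body):
        column = body.any(axis=2)[:, :, None]
        forbidden = dilate_inplane_mm(body, p.disc_forbidden_dilation_mm,
                                      spacing_mm) & ~column
        out = out & ~forbidden
    out = out & ~upper_body & ~lower_body
    if not out.any():
        logger.warning("%s: disc VOI empty after forbidden-region removal", context)
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class VoiSet:
    """Named binary VOI masks on a common grid.

    ``facets`` is keyed by ``(level_pair, side)``, e.g. ``("L4-L5", "left")``.
    Counts (``n_bodies`` etc.) refer to non-empty masks only.
    """

    spacing_mm: tuple[float, float, float]
    bodies: dict[str, np.ndarray] = field(default_factory=dict)
    discs: dict[str, np.ndarray] = field(default_factory=dict)
    facets: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def n_bodies(self) -> int:
        return sum(1 for m in self.bodies.values() if m.any())

    @property
    def n_discs(self) -> int:
        return sum(1 for m in self.discs.values() if m.any())

    @property
    def n_facets(self) -> int:
        return sum(1 for m in self.facets.values() if m.any())

    def region_masks(self, region: str) -> dict[str, np.ndarray]:
        if region == "vertebral_bodies":
            return dict(self.bodies)
        if region == "intervertebral_discs":
            return dict(self.discs)
        if region == "facet_joints":
            return {f"{pair}_{side}": m for (pair, side), m in self.facets.items()}
        raise KeyError(f"unknown region {region!r}")

    def summary(self) -> pd.DataFrame:
        voxel_ml = float(np.prod(self.spacing_mm)) / 1000.0
        rows = []
        for region in ("vertebral_bodies", "intervertebral_discs", "facet_joints"):
            for name, m in self.region_masks(region).items():
                n = int(m.sum())
                rows.append((region, name, n, n * voxel_ml))
        return pd.DataFrame(rows, columns=["region", "voi", "voxels", "volume_ml"])


def segment_all(labels: LabeledVolume,
                params: MorphParams | None = None) -> VoiSet:
    """Run all three VOI recipes over every lumbar level of a label map.

    Requires L1..L5 in the legend (sacrum optional).  A complete lumbar input
    yields 5 body, 4 disc and 10 facet VOIs; the L5-S1 facets always use the
    lowest-facet rule (seeded on L5 alone, refined within L5 plus the sacrum
    when present).  The procedure contains no randomness.
    """
    p = params or MorphParams()
    p.validate()
    labels.validate()
    sp = labels.spacing_mm
    level_labels = {}
    for name in ("L1", "L2", "L3", "L4", "L5"):
        lab = labels.label_of(name)
        if lab is None:
            missing = [n for n in ("L1", "L2", "L3", "L4", "L5")
                       if labels.label_of(n) is None]
            raise ConfigError(f"label map is missing lumbar levels: {missing}")
        level_labels[name] = lab
    sacrum_lab = labels.label_of("sacrum")

    verts = {name: labels.mask(lab) for name, lab in level_labels.items()}
    vois = VoiSet(spacing_mm=sp)
    for name, mask in verts.items():
        vois.bodies[name] = extract_vertebral_body(mask, sp, p, name=name)

    order = ("L1", "L2", "L3", "L4", "L5")
    for up, lo in zip(order[:-1], order[1:]):
        pair = f"{up}-{lo}"
        vois.discs[pair] = extract_disc(vois.bodies[up], vois.bodies[lo], sp, p,
                                        context=f"disc {pair}")
        left, right = extract_facet_joints(verts[up], verts[lo],
                                           vois.bodies[up], vois.bodies[lo],
                                           sp, p, context=f"facet {pair}")
        vois.facets[(pair, "left")] = left
        vois.facets[(pair, "right")] = right

    sac = labels.mask(sacrum_lab) if sacrum_lab is not None else None
    left, right = extract_lowest_facets(verts["L5"], vois.bodies["L5"], sac, sp, p)
    vois.facets[("L5-S1", "left")] = left
    vois.facets[("L5-S1", "right")] = right

    for _, row in vois.summary().iterrows():
        logger.info("VOI %s/%s: %d voxels (%.1f mL)", row.region, row.voi,
                    row.voxels, row.volume_ml)
    return vois
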