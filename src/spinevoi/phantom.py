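"""Synthetic lumbar-spine phantoms and paired case-control cohorts.

The phantom is a stylised block-geometry lumbar spine: each vertebra is a
vertebral-body box with bilateral pedicles, bilateral articular columns that
overhang toward the neighbouring level (so that facet-joint contact areas
exist), midline laminae and a spinous process; an optional sacrum block sits
below L5.  Adjacent bodies are separated by a disc-height gap.  The geometry
is intentionally non-anatomical -- the downstream VOI-extraction algorithm
consumes only binary masks, so rectangular structures with the right physical
dimensions and adjacencies exercise every branch of the method while keeping
every ground-truth mask exactly known.

Coordinate convention (fixed package-wide): arrays are indexed ``[x, y, z]``
with x = left-right, y = anterior-posterior (posterior = +y, toward the
pedicles), z = inferior-superior.  Voxel ``i`` along an axis with spacing
``s`` covers ``[i*s, (i+1)*s)`` mm and has its centre at ``(i + 0.5)*s``.

Intensity channels: tissue means and SDs default to the published control
group region summaries (see :mod:`spinevoi.reference`); per-voxel noise is
i.i.d. Gaussian and SUV channels are clipped at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import reference
from .errors import ConfigError, SizingError

__all__ = [
    "CHANNELS",
    "TISSUES",
    "PhantomConfig",
    "LabeledVolume",
    "IntensityVolume",
    "SubjectRecord",
    "PhantomResult",
    "CohortSpec",
    "GroupDistribution",
    "default_tissue_uptake",
    "case_tissue_uptake",
    "default_cohort_distributions",
    "generate_spine_phantom",
    "paint_intensities",
    "generate_cohort",
]

CHANNELS = ("PET_NaF", "PET_FDG", "CT_HU")

#: Channel key -> IntensityVolume.channel tag.
CHANNEL_TAGS = {"PET_FDG": "SUV_FDG", "PET_NaF": "SUV_NaF", "CT_HU": "HU"}

#: Painting order is fixed so that a given seed always yields the same field.
TISSUES = ("background", "vertebral_body", "posterior_elements", "disc", "sacrum")

_LUMBAR_NAMES = ("L1", "L2", "L3", "L4", "L5")
_SACRUM_LABEL = 6


def default_tissue_uptake() -> dict[str, dict[str, tuple[float, float]]]:
    """Control-group tissue (mean, SD) per channel.

    Vertebral-body and sacrum values come from the vertebral-body SUVmean/HUmean
    summaries, posterior elements from the facet-joint row, discs from the
    disc row.  Background levels are typical paraspinal soft tissue.
    """
    def c(region):  # control centre/SD per channel for a region's "mean" row
        return {ch: (reference.get(ch, region, "mean").control_center,
                     reference.get(ch, region, "mean").control_sd)
                for ch in CHANNELS}

    body, facet, disc = (c("vertebral_bodies"), c("facet_joints"),
                         c("intervertebral_discs"))
    bg = {"PET_NaF": (0.5, 0.2), "PET_FDG": (0.3, 0.1), "CT_HU": (40.0, 15.0)}
    return {ch: {"vertebral_body": body[ch],
                 "sacrum": body[ch],
                 "posterior_elements": facet[ch],
                 "disc": disc[ch],
                 "background": bg[ch]} for ch in CHANNELS}


def case_tissue_uptake() -> dict[str, dict[str, tuple[float, float]]]:
    """As :func:`default_tissue_uptake` but with case-group centres/SDs."""
    out = default_tissue_uptake()
    region_of = {"vertebral_body": "vertebral_bodies", "sacrum": "vertebral_bodies",
                 "posterior_elements": "facet_joints", "disc": "intervertebral_discs"}
    for ch in CHANNELS:
        for tissue, region in region_of.items():
            row = reference.get(ch, region, "mean")
            out[ch][tissue] = (row.case_center, row.case_sd)
    return out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LabeledVolume:
    """3-D integer vertebra label map with physical voxel spacing.

    ``legend`` maps each nonzero label to a structure name (1..5 = L1..L5,
    6 = sacrum).  Axis order and orientation follow the package convention
    documented in the module docstring.
    """

    array: np.ndarray
    spacing_mm: tuple[float, float, float]
    legend: dict[int, str]

    def validate(self) -> None:
        if self.array.ndim != 3:
            raise ConfigError("label map must be 3-D")
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigError("voxel spacings must be positive")
        present = set(np.unique(self.array)) - {0}
        if (self.array < 0).any():
            raise ConfigError("labels must be non-negative")
        missing = present - set(self.legend)
        if missing:
            raise ConfigError(f"legend missing labels: {sorted(missing)}")

    def mask(self, label: int) -> np.ndarray:
        return self.array == label

    def label_of(self, name: str) -> int | None:
        for lab, nm in self.legend.items():
            if nm == name:
                return int(lab)
        return None


@dataclass
class IntensityVolume:
    """3-D scalar field (SUV or HU) co-registered with a label map."""

    array: np.ndarray
    spacing_mm: tuple[float, float, float]
    channel: str  # SUV_FDG | SUV_NaF | HU


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    pair_id: str
    group: str  # "case" | "control"
    age_years: int
    sex: str
    weight_kg: float


@dataclass
class PhantomResult:
    """A generated phantom plus the ground truth used to paint it.

    ``tissue_masks`` holds the painted tissue classes; ``truth_vois`` holds
    the per-structure ground-truth masks (bodies per level, disc gaps per
    level pair) so downstream stages can be scored against known truth.
    """

    labels: LabeledVolume
    intensities: dict[str, IntensityVolume]
    tissue_masks: dict[str, np.ndarray]
    truth_vois: dict[str, dict[str, np.ndarray]]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PhantomConfig:
    """Parameters of the synthetic spine.

    Defaults give a 128 x 128 x 192 grid at 1.5 mm isotropic spacing holding
    five lumbar vertebrae (34 x 30 x 28 mm bodies) plus a sacrum, with 8 mm
    disc gaps and a 10 mm body-to-articular-column posterior offset.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 192)
    voxel_spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    n_vertebrae: int = 5
    sacrum: bool = True
    body_size_mm: tuple[float, float, float] = (34.0, 30.0, 28.0)
    disc_height_mm: float = 8.0
    posterior_offset_mm: float = 10.0
    channels: tuple[str, ...] = CHANNELS
    tissue_uptake: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=default_tissue_uptake)
    background_uptake: dict[str, tuple[float, float]] | None = None
    smooth_fwhm_mm: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ConfigError("voxel spacings must be positive")
        if any(n <= 0 for n in self.grid_shape):
            raise ConfigError("grid shape must be positive")
        if any(s <= 0 for s in self.body_size_mm) or self.disc_height_mm <= 0 \
                or self.posterior_offset_mm <= 0:
            raise ConfigError("all size parameters must be positive")
        if self.disc_height_mm >= self.body_size_mm[2]:
            raise ConfigError("disc_height_mm must be smaller than body height")
        if not 1 <= self.n_vertebrae <= 5:
            raise ConfigError("n_vertebrae must be between 1 and 5")
        uptake = self.effective_uptake()
        for ch in self.channels:
            if ch not in CHANNELS:
                raise ConfigError(f"unknown channel {ch!r}")
            table = uptake.get(ch, {})
            for tissue in TISSUES:
                if tissue == "sacrum" and not self.sacrum:
                    continue
                if tissue not in table:
                    raise ConfigError(
                        f"missing uptake entry for tissue {tissue!r}, channel {ch!r}")
                mean, sd = table[tissue]
                if sd < 0:
                    raise ConfigError("uptake SDs must be non-negative")

    def effective_uptake(self) -> dict[str, dict[str, tuple[float, float]]]:
        """Tissue uptake with any separate ``background_uptake`` merged in."""
        table = {ch: dict(v) for ch, v in self.tissue_uptake.items()}
        if self.background_uptake:
            for ch, ms in self.background_uptake.items():
                table.setdefault(ch, {})["background"] = ms
        return table


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _idx_range(lo: float, hi: float, sp: float) -> tuple[int, int]:
    """Half-open voxel index range whose centres fall in [lo, hi) mm."""
    a = math.ceil(lo / sp - 0.5 - 1e-9)
    b = math.ceil(hi / sp - 0.5 - 1e-9)
    return a, b


class _Painter:
    def __init__(self, shape, spacing, extent_mm):
        self.labels = np.zeros(shape, dtype=np.int16)
        self.spacing = spacing
        self.extent = extent_mm
        self.tissue: dict[str, np.ndarray] = {}

    def box(self, x0, x1, y0, y1, z0, z1, label: int, tissue: str,
            record: np.ndarray | None = None) -> np.ndarray:
        lo = (x0, y0, z0)
        hi = (x1, y1, z1)
        for l, h, ext in zip(lo, hi, self.extent):
            if l < 0 or h > ext - 10.0:  # 10 mm margin requirement
                raise SizingError(
                    f"structure [{lo} .. {hi}] mm does not fit the grid "
                    f"(extent {self.extent} mm with a 10 mm margin)")
        sls = tuple(slice(*_idx_range(l, h, s))
                    for l, h, s in zip(lo, hi, self.spacing))
        if label:
            self.labels[sls] = label
        m = self.tissue.setdefault(tissue, np.zeros_like(self.labels, dtype=bool))
        m[sls] = True
        if record is not None:
            record[sls] = True
        return m


def _build_geometry(cfg: PhantomConfig):
    sp = cfg.voxel_spacing_mm
    shape = cfg.grid_shape
    extent = tuple(n * s for n, s in zip(shape, sp))
    w, d, h = cfg.body_size_mm
    g = cfg.disc_height_mm
    po = cfg.posterior_offset_mm
    pitch = h + g

    xc = extent[0] / 2.0
    y0 = 0.3 * extent[1]          # anterior face of the bodies
    yb = y0 + d                   # posterior face of the bodies
    z_base = 10.0 + (30.0 + g if cfg.sacrum else 2.0)  # bottom of the L5 body

    painter = _Painter(shape, sp, extent)
    names = _LUMBAR_NAMES[5 - cfg.n_vertebrae:]          # e.g. 2 -> (L4, L5)
    legend = {i + 1 + (5 - cfg.n_vertebrae): nm for i, nm in enumerate(names)}
    body_truth: dict[str, np.ndarray] = {}
    disc_truth: dict[str, np.ndarray] = {}

    def z_bottom(name: str) -> float:
        rank = 5 - int(name[1])   # L5 -> 0 (lowest), L1 -> 4
        return z_base + rank * pitch

    for lab, nm in legend.items():
        zb = z_bottom(nm)
        rec = np.zeros(shape, dtype=bool)
        # vertebral body
        painter.box(xc - w / 2, xc + w / 2, y0, yb, zb, zb + h,
                    lab, "vertebral_body", record=rec)
        body_truth[nm] = rec
        # bilateral pedicles (8 mm cranio-caudal thickness, centred on the body)
        pz0, pz1 = zb + (h - 8) / 2, zb + (h + 8) / 2
        for sgn in (-1, 1):
            px = sorted((sgn * (w / 2 - 9), sgn * (w / 2 - 2)))
            painter.box(xc + px[0], xc + px[1], yb, yb + po, pz0, pz1,
                        lab, "posterior_elements")
        # bilateral articular columns, overhanging g-2 mm below the body and
        # stopping 2 mm short of its top (=> 4 mm inter-level column gap)
        for sgn in (-1, 1):
            cx = sorted((sgn * (w / 2 - 3), sgn * (w / 2 + 5)))
            painter.box(xc + cx[0], xc + cx[1], yb + po, yb + po + 8,
                        zb - (g - 2), zb + h - 2, lab, "posterior_elements")
        # laminae bridging columns to the spinous process
        painter.box(xc - (w / 2 - 1), xc + (w / 2 - 1), yb + po + 6, yb + po + 12,
                    pz0, pz1, lab, "posterior_elements")
        # midline spinous process
        painter.box(xc - 4, xc + 4, yb + po + 8, yb + po + 22,
                    zb + 4, zb + h - 4, lab, "posterior_elements")

    # disc gaps between adjacent lumbar bodies (shared footprint)
    for upper, lower in zip(names[:-1], names[1:]):
        zb_u = z_bottom(upper)
        rec = np.zeros(shape, dtype=bool)
        painter.box(xc - w / 2, xc + w / 2, y0, yb, zb_u - g, zb_u, 0,
                    "disc", record=rec)
        disc_truth[f"{upper}-{lower}"] = rec

    if cfg.sacrum:
        legend[_SACRUM_LABEL] = "sacrum"
        painter.box(xc - (w / 2 + 3), xc + (w / 2 + 3), y0, yb, 10.0, 40.0,
                    _SACRUM_LABEL, "sacrum")
        if "L5" in names:
            rec = np.zeros(shape, dtype=bool)
            painter.box(xc - w / 2, xc + w / 2, y0, yb, 40.0, z_base, 0,
                        "disc", record=rec)
            disc_truth["L5-S1"] = rec

    tissue = painter.tissue
    tissue.setdefault("disc", np.zeros(shape, dtype=bool))
    occupied = np.zeros(shape, dtype=bool)
    for m in tissue.values():
        occupied |= m
    tissue["background"] = ~occupied

    labels = LabeledVolume(painter.labels, sp, legend)
    labels.validate()
    structure = np.ones((3, 3, 3), dtype=bool)
    for lab in legend:
        _, n = ndimage.label(labels.array == lab, structure=structure)
        if n != 1:
            raise SizingError(
                f"label {legend[lab]} split into {n} components; geometry invalid")
    return labels, tissue, {"body": body_truth, "disc": disc_truth}


# ---------------------------------------------------------------------------
# Intensity painting
# ---------------------------------------------------------------------------

def paint_intensities(
    tissue_masks: dict[str, np.ndarray],
    uptake: dict[str, dict[str, tuple[float, float]]],
    channels: tuple[str, ...],
    spacing_mm: tuple[float, float, float],
    seed: int | np.random.SeedSequence,
    smooth_fwhm_mm: float | None = None,
) -> dict[str, IntensityVolume]:
    """Draw i.i.d. Gaussian intensity fields over the tissue masks.

    One child random stream per channel (derived from ``seed``), so adding a
    channel never perturbs the others.  SUV channels are clipped at zero.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    streams = ss.spawn(len(channels))
    shape = next(iter(tissue_masks.values())).shape
    out: dict[str, IntensityVolume] = {}
    for ch, child in zip(channels, streams):
        rng = np.random.default_rng(child)
        mean, sd = uptake[ch]["background"]
        arr = rng.normal(mean, sd, size=shape)
        for tissue in TISSUES:
            if tissue == "background" or tissue not in tissue_masks:
                continue
            m = tissue_masks[tissue]
            n = int(m.sum())
            if n == 0:
                continue
            if tissue not in uptake[ch]:
                raise ConfigError(
                    f"missing uptake entry for tissue {tissue!r}, channel {ch!r}")
            mu, s = uptake[ch][tissue]
            arr[m] = rng.normal(mu, s, size=n)
        if smooth_fwhm_mm:
            sigma = [smooth_fwhm_mm / 2.3548 / s for s in spacing_mm]
            arr = ndimage.gaussian_filter(arr, sigma=sigma)
        if ch != "CT_HU":
            np.clip(arr, 0.0, None, out=arr)
        out[ch] = IntensityVolume(arr.astype(np.float32), spacing_mm,
                                  CHANNEL_TAGS[ch])
    return out


def generate_spine_phantom(config: PhantomConfig | None = None) -> PhantomResult:
    """Build the labelled spine geometry and one intensity volume per channel."""
    cfg = config or PhantomConfig()
    cfg.validate()
    labels, tissue, truth = _build_geometry(cfg)
    intensities = paint_intensities(tissue, cfg.effective_uptake(), cfg.channels,
                                    cfg.voxel_spacing_mm, cfg.seed,
                                    cfg.smooth_fwhm_mm)
    return PhantomResult(labels, intensities, tissue, truth)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupDistribution:
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float


def default_cohort_distributions() -> dict[tuple[str, str, str], GroupDistribution]:
    """Per (channel, region, metric) group Gaussians from the published table."""
    return {key: GroupDistribution(r.case_center, r.case_sd,
                                   r.control_center, r.control_sd)
            for key, r in reference.PUBLISHED_COMPARISONS.items()}


#: Region volumes (mL) implied by the published control totals / means.
_REGION_VOLUME_ML = {
    "intervertebral_discs": 28.7,
    "facet_joints": 47.4,
    "vertebral_bodies": 207.3,
}

#: Sex assignment cycle reproducing a 7 male / 5 female split per 12 pairs.
_SEX_CYCLE = ("M", "M", "F", "M", "F", "M", "F", "M", "M", "F", "M", "F")


@dataclass
class CohortSpec:
    """Specification of a matched case-control cohort of region metrics."""

    n_pairs: int = 12
    distributions: dict[tuple[str, str, str], GroupDistribution] = field(
        default_factory=default_cohort_distributions)
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ConfigError("n_pairs must be >= 2")
        if not self.distributions:
            raise ConfigError("no metric distributions specified")
        for key, d in self.distributions.items():
            if len(key) != 3:
                raise ConfigError(f"malformed distribution key {key!r}")
            if d.case_sd < 0 or d.control_sd < 0:
                raise ConfigError(f"negative SD for {key!r}")


def _demographics(n_pairs: int,
                  rng: np.random.Generator) -> list[SubjectRecord]:
    records = []
    for j in range(n_pairs):
        pair = f"P{j + 1:02d}"
        sex = _SEX_CYCLE[j % len(_SEX_CYCLE)]
        case_age = int(np.clip(round(rng.normal(45.0, 13.0)), 20, 78))
        control_age = int(np.clip(case_age + rng.integers(-3, 4), 18, 81))
        records.append(SubjectRecord(f"case-{j + 1:02d}", pair, "case",
                                     case_age, sex,
                                     float(np.clip(rng.normal(83.0, 12.8), 45, 130))))
        records.append(SubjectRecord(f"ctrl-{j + 1:02d}", pair, "control",
                                     control_age, sex,
                                     float(np.clip(rng.normal(76.3, 13.6), 45, 130))))
    return records


def generate_cohort(spec: CohortSpec | None = None
                    ) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Draw a balanced paired cohort of per-subject region metrics.

    Values are drawn independently per subject from the configured case or
    control Gaussian for each (channel, region, metric) cell; one child
    random stream per cell keeps cells independent of the key set ordering.
    Returns the subject manifest and a tidy metrics table with columns
    ``subject_id, pair_id, group, channel, region, metric, value, volume_ml``.
    """
    spec = spec or CohortSpec()
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    demo_stream, cells_stream = ss.spawn(2)
    subjects = _demographics(spec.n_pairs, np.random.default_rng(demo_stream))

    keys = sorted(spec.distributions)
    rows = []
    for key, child in zip(keys, cells_stream.spawn(len(keys))):
        channel, region, metric = key
        d = spec.distributions[key]
        rng = np.random.default_rng(child)
        case_vals = rng.normal(d.case_mean, d.case_sd, spec.n_pairs)
        ctrl_vals = rng.normal(d.control_mean, d.control_sd, spec.n_pairs)
        vol = _REGION_VOLUME_ML.get(region, float("nan"))
        for j in range(spec.n_pairs):
            rows.append((f"case-{j + 1:02d}", f"P{j + 1:02d}", "case",
                         channel, region, metric, float(case_vals[j]), vol))
            rows.append((f"ctrl-{j + 1:02d}", f"P{j + 1:02d}", "control",
                         channel, region, metric, float(ctrl_vals[j]), vol))
    table = pd.DataFrame(rows, columns=["subject_id", "pair_id", "group",
                                        "channel", "region", "metric",
                                        "value", "volume_ml"])
    return subjects, table
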