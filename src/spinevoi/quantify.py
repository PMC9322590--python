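"""SUV / HU summary metrics per VOI and pooled per region.

For a VOI the three metrics are: the maximum voxel value, the arithmetic
mean over the VOI, and the total (mean multiplied by the VOI volume in mL,
units value*mL).  Region summaries pool the member VOIs at the voxel level
by default (volume-weighted mean, global max, summed total), which matches
the magnitude of published per-region totals; averaging of per-VOI metrics
is available via ``pooling="per_voi"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingVoiError, ParameterError
from .phantom import IntensityVolume
from .voi import VoiSet

__all__ = [
    "VoiMetrics",
    "RegionMetrics",
    "voi_metrics",
    "region_metrics",
    "suv_from_activity",
    "quantify_subject",
]

REGION_NAMES = ("vertebral_bodies", "intervertebral_discs", "facet_joints")


@dataclass(frozen=True)
class VoiMetrics:
    voi_id: str
    channel: str
    max: float
    mean: float
    total: float      # mean * volume_ml (value * mL)
    volume_ml: float


@dataclass(frozen=True)
class RegionMetrics:
    region: str
    channel: str
    max: float
    mean: float
    total: float
    volume_ml: float


def voi_metrics(intensity: IntensityVolume, mask: np.ndarray,
                spacing_mm=None, voi_id: str = "voi") -> VoiMetrics:
    """Max, mean, total and volume of one VOI mask over an intensity field."""
    sp = spacing_mm or intensity.spacing_mm
    if intensity.array.shape != mask.shape:
        raise ParameterError("intensity and mask shapes differ")
    if spacing_mm is not None and tuple(spacing_mm) != tuple(intensity.spacing_mm):
        raise ParameterError("intensity and mask spacings differ")
    vals = intensity.array[mask]
    if vals.size == 0:
        raise MissingVoiError(f"{voi_id}: empty VOI mask")
    volume_ml = float(vals.size) * float(np.prod(sp)) / 1000.0
    mean = float(vals.mean(dtype=np.float64))  # float64: pooling must be exact
    return VoiMetrics(voi_id, intensity.channel, float(vals.max()), mean,
                      mean * volume_ml, volume_ml)


def region_metrics(members: list[VoiMetrics], region: str,
                   pooling: str = "voxel") -> RegionMetrics:
    """Pool per-VOI metrics into one region summary.

    ``pooling="voxel"`` (default): volume-weighted mean, max of maxes, summed
    totals and volumes -- identical to computing the metrics over the union of
    the member masks.  ``pooling="per_voi"``: unweighted average of per-VOI
    means and maxes (totals and volumes still sum).
    """
    members = [m for m in members if m.volume_ml > 0]
    if not members:
        raise MissingVoiError(f"region {region!r}: all member VOIs are empty")
    channels = {m.channel for m in members}
    if len(channels) != 1:
        raise ParameterError(f"region {region!r}: mixed channels {channels}")
    total = sum(m.total for m in members)
    volume = sum(m.volume_ml for m in members)
    if pooling == "voxel":
        mean = total / volume
        mx = max(m.max for m in members)
    elif pooling == "per_voi":
        mean = float(np.mean([m.mean for m in members]))
        mx = float(np.mean([m.max for m in members]))
    else:
        raise ParameterError(f"unknown pooling {pooling!r}")
    return RegionMetrics(region, members[0].channel, mx, mean, total, volume)


def suv_from_activity(concentration: np.ndarray | IntensityVolume,
                      injected_dose_kbq: float, body_weight_g: float,
                      spacing_mm=None, channel: str = "SUV") -> IntensityVolume:
    """Body-weight SUV from an activity-concentration volume (kBq/mL).

    SUV = concentration / (injected dose / body weight), voxel-wise; under
    the 1 g ~ 1 mL tissue convention the result is dimensionless.
    """
    if injected_dose_kbq <= 0 or body_weight_g <= 0:
        raise ParameterError("dose and body weight must be positive")
    if isinstance(concentration, IntensityVolume):
        arr, sp = concentration.array, concentration.spacing_mm
    else:
        arr, sp = np.asarray(concentration, dtype=np.float64), spacing_mm
    if (arr < 0).any():
        raise ParameterError("activity concentration must be non-negative")
    suv = arr / (injected_dose_kbq / body_weight_g)
    return IntensityVolume(suv.astype(np.float32), sp, channel)


def quantify_subject(intensities: dict[str, IntensityVolume], vois: VoiSet,
                     subject_id: str = "subject", pair_id: str = "",
                     group: str = "", pooling: str = "voxel") -> pd.DataFrame:
    """Tidy per-region metric rows for one subject across all channels.

    Returns one row per (channel, region, metric) with columns matching the
    cohort metrics schema; empty VOIs are skipped from pooling, and a region
    whose VOIs are all empty raises :class:`MissingVoiError`.
    """
    rows = []
    for ch_key, vol in intensities.items():
        for region in REGION_NAMES:
            members = [voi_metrics(vol, m, voi_id=name)
                       for name, m in vois.region_masks(region).items()
                       if m.any()]
            rm = region_metrics(members, region, pooling=pooling)
            for metric in ("max", "mean", "total"):
                rows.append((subject_id, pair_id, group, ch_key, region, metric,
                             getattr(rm, metric), rm.volume_ml))
    return pd.DataFrame(rows, columns=["subject_id", "pair_id", "group",
                                       "channel", "region", "metric",
                                       "value", "volume_ml"])
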