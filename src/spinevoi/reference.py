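"""Published group-summary statistics for lumbar PET/CT uptake.

These are the case/control region summaries (12 age/sex-matched pairs) from a
pilot FDG/NaF PET/CT study of low back pain.  They serve two purposes here:

* default distribution parameters for the synthetic cohort generator
  (:func:`spinevoi.phantom.generate_cohort`) and phantom tissue uptake, and
* inputs to the worked-example helpers below, which recompute the printed
  group differences and relative differences from the group centres.

Rows whose published summary is a median (minimum-maximum) carry the median as
``*_center`` and the range-based proxy ``(max - min) / 4`` as ``*_sd``; rows
summarised as mean +/- SD carry those directly.  ``difference``, ``ci_low``,
``ci_high`` and ``p`` are the published paired-comparison columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Canonical orderings used throughout the package.
CHANNELS = ("PET_NaF", "PET_FDG", "CT_HU")
REGIONS = ("intervertebral_discs", "facet_joints", "vertebral_bodies")
METRICS = ("max", "mean", "total")


@dataclass(frozen=True)
class PublishedComparison:
    channel: str
    region: str
    metric: str
    case_center: float
    case_sd: float
    control_center: float
    control_sd: float
    summary: str            # "mean_sd" or "median_range"
    difference: float       # published case - control difference
    ci_low: float
    ci_high: float
    p: float
    wilcoxon: bool          # True where the published row used Wilcoxon


def _rng_sd(lo: float, hi: float) -> float:
    """SD proxy for a median (min-max) summary: quarter of the range."""
    return (hi - lo) / 4.0


_ROWS = [
    # NaF
    PublishedComparison("PET_NaF", "intervertebral_discs", "max",
                        11.63, 3.29, 9.45, 1.32, "mean_sd",
                        2.18, 0.15, 4.21, 0.038, False),
    PublishedComparison("PET_NaF", "intervertebral_discs", "mean",
                        2.75, _rng_sd(1.82, 7.02), 2.55, _rng_sd(1.88, 3.45),
                        "median_range", 0.64, -0.35, 1.64, 0.21, True),
    PublishedComparison("PET_NaF", "intervertebral_discs", "total",
                        76.73, 31.02, 73.21, 22.60, "mean_sd",
                        3.51, -16.88, 23.91, 0.71, False),
    PublishedComparison("PET_NaF", "facet_joints", "max",
                        13.5, _rng_sd(7.23, 33.98), 9.17, _rng_sd(8.25, 17.69),
                        "median_range", 4.38, 1.08, 7.68, 0.015, True),
    PublishedComparison("PET_NaF", "facet_joints", "mean",
                        5.04, _rng_sd(3.53, 7.8), 4.15, _rng_sd(3.42, 7.21),
                        "median_range", 0.47, -0.53, 1.47, 0.41, True),
    PublishedComparison("PET_NaF", "facet_joints", "total",
                        203.0, 48.60, 196.92, 46.01, "mean_sd",
                        6.07, -30.61, 42.76, 0.72, False),
    PublishedComparison("PET_NaF", "vertebral_bodies", "max",
                        14.67, 4.17, 12.72, 1.96, "mean_sd",
                        1.95, -0.71, 4.61, 0.13, False),
    PublishedComparison("PET_NaF", "vertebral_bodies", "mean",
                        7.80, 1.98, 7.29, 0.78, "mean_sd",
                        0.51, -0.72, 1.74, 0.38, False),
    PublishedComparison("PET_NaF", "vertebral_bodies", "total",
                        1660.03, 503.91, 1511.30, 205.81, "mean_sd",
                        148.74, -101.88, 399.35, 0.21, False),
    # FDG
    PublishedComparison("PET_FDG", "intervertebral_discs", "max",
                        2.83, 1.04, 2.26, 0.57, "mean_sd",
                        0.57, -0.07, 1.21, 0.08, False),
    PublishedComparison("PET_FDG", "intervertebral_discs", "mean",
                        0.96, 0.34, 0.69, 0.15, "mean_sd",
                        0.27, 0.05, 0.49, 0.021, False),
    PublishedComparison("PET_FDG", "intervertebral_discs", "total",
                        21.72, 7.76, 19.82, 7.68, "mean_sd",
                        1.9, -5.69, 9.49, 0.59, False),
    PublishedComparison("PET_FDG", "facet_joints", "max",
                        2.47, _rng_sd(1.96, 4.87), 2.84, _rng_sd(1.75, 4.88),
                        "median_range", -0.34, -1.2, 0.52, 0.35, True),
    PublishedComparison("PET_FDG", "facet_joints", "mean",
                        0.99, 0.26, 0.96, 0.20, "mean_sd",
                        0.03, -0.19, 0.26, 0.74, False),
    PublishedComparison("PET_FDG", "facet_joints", "total",
                        38.41, 4.79, 42.18, 12.96, "mean_sd",
                        -3.77, -13.12, 5.58, 0.39, False),
    PublishedComparison("PET_FDG", "vertebral_bodies", "max",
                        3.77, 0.90, 3.47, 1.06, "mean_sd",
                        0.3, -0.6, 1.2, 0.48, False),
    PublishedComparison("PET_FDG", "vertebral_bodies", "mean",
                        1.75, 0.40, 1.69, 0.40, "mean_sd",
                        0.06, -0.3, 0.43, 0.7, False),
    PublishedComparison("PET_FDG", "vertebral_bodies", "total",
                        385.77, 137.84, 359.15, 118.67, "mean_sd",
                        26.62, -70.53, 123.79, 0.55, False),
    # CT
    PublishedComparison("CT_HU", "intervertebral_discs", "max",
                        651.13, 100.20, 606.85, 155.77, "mean_sd",
                        44.28, -67.54, 156.11, 0.4, False),
    PublishedComparison("CT_HU", "intervertebral_discs", "mean",
                        121.72, 13.50, 117.58, 10.13, "mean_sd",
                        4.15, -6.6, 14.89, 0.41, False),
    PublishedComparison("CT_HU", "intervertebral_discs", "total",
                        3165.69, 1181.62, 3339.46, 922.39, "mean_sd",
                        -173.77, -190.39, 562.85, 0.61, False),
    PublishedComparison("CT_HU", "facet_joints", "max",
                        1220.69, 65.24, 1248.34, 51.10, "mean_sd",
                        -27.66, -70.74, 15.43, 0.18, False),
    PublishedComparison("CT_HU", "facet_joints", "mean",
                        536.28, 114.54, 498.93, 79.76, "mean_sd",
                        37.36, -27.2, 101.91, 0.23, False),
    PublishedComparison("CT_HU", "facet_joints", "total",
                        21926.61, 5984.90, 22191.24, 6600.23, "mean_sd",
                        -264.63, -5397.5, 4868.24, 0.91, False),
    PublishedComparison("CT_HU", "vertebral_bodies", "max",
                        1039.48, 109.10, 1026.57, 90.90, "mean_sd",
                        12.9, -77.67, 103.47, 0.76, False),
    PublishedComparison("CT_HU", "vertebral_bodies", "mean",
                        238.84, 56.93, 235.39, 33.95, "mean_sd",
                        3.45, -26.57, 33.47, 0.8, False),
    PublishedComparison("CT_HU", "vertebral_bodies", "total",
                        50974.52, 14722.54, 49505.45, 10925.34, "mean_sd",
                        1469.07, -6255.32, 9193.47, 0.68, False),
]

PUBLISHED_COMPARISONS: dict[tuple[str, str, str], PublishedComparison] = {
    (r.channel, r.region, r.metric): r for r in _ROWS
}


def published_table() -> pd.DataFrame:
    """All published comparison rows as a tidy DataFrame (27 rows)."""
    return pd.DataFrame([vars(r) for r in _ROWS])


def get(channel: str, region: str, metric: str) -> PublishedComparison:
    try:
        return PUBLISHED_COMPARISONS[(channel, region, metric)]
    except KeyError:
        raise KeyError(f"no published row for ({channel}, {region}, {metric})")


def group_difference(channel: str, region: str, metric: str) -> float:
    """Case minus control group centre, recomputed from the group summaries."""
    row = get(channel, region, metric)
    return row.case_center - row.control_center


def relative_difference_pct(channel: str, region: str, metric: str) -> float:
    """Published group difference as a percentage of the control centre.

    Uses the published paired difference (not centre-minus-centre) in the
    numerator: for mean +/- SD rows the two coincide, while for median rows
    the paired difference is the published quantity of interest.
    """
    row = get(channel, region, metric)
    return 100.0 * row.difference / row.control_center
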