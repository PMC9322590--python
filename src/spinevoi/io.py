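"""NIfTI/CSV/JSON/YAML I/O and the end-to-end pipeline orchestrator.

The pipeline has two modes.  In *phantom* mode a synthetic spine geometry is
generated once, segmented into VOIs, and per-subject intensity volumes are
drawn for a matched case-control cohort: each subject's tissue means are the
group means plus a between-subject Gaussian effect, on top of per-voxel
noise.  Region metrics are quantified per subject and the paired comparison
table (with Holm-Bonferroni decisions) is written.  In *files* mode a
user-supplied label map and co-registered intensity volumes are segmented
and quantified (single subject; statistics are run separately on a cohort
metrics CSV).

All outputs are plain text (CSV/JSON) plus NIfTI masks; a provenance JSON
records the configuration hash, seed, every morphological parameter actually
used and per-stage warnings, so a rerun with the same config and seed
reproduces byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .errors import ConfigError, VolumeFormatError
from .phantom import (CHANNELS, IntensityVolume, LabeledVolume, PhantomConfig,
                      _build_geometry, case_tissue_uptake,
                      default_tissue_uptake, _demographics, paint_intensities)
from .quantify import quantify_subject
from .stats import build_comparison_table
from .voi import MorphParams, VoiSet, segment_all

logger = logging.getLogger("spinevoi.io")

__all__ = [
    "read_volume",
    "write_volume",
    "read_legend",
    "write_legend",
    "PipelineConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

def _check_3d(arr: np.ndarray, path) -> None:
    if arr.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D volume, got {arr.ndim}-D")


def _spacing_from(img, path) -> tuple[float, float, float]:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeFormatError(f"{path}: missing or non-positive voxel spacing")
    return zooms


def read_volume(path, legend: dict[int, str] | None = None,
                channel: str = "intensity"):
    """Read a NIfTI volume as a :class:`LabeledVolume` (integer data) or
    :class:`IntensityVolume` (floating point)."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    _check_3d(arr, path)
    spacing = _spacing_from(img, path)
    if np.issubdtype(arr.dtype, np.integer):
        if legend is None:
            legend_path = _legend_sidecar(path)
            legend = read_legend(legend_path) if legend_path.exists() else {
                int(v): f"label{int(v)}" for v in np.unique(arr) if v != 0}
        vol = LabeledVolume(arr.astype(np.int16), spacing, legend)
        vol.validate()
        return vol
    return IntensityVolume(arr.astype(np.float32), spacing, channel)


def write_volume(vol, path) -> Path:
    """Write a volume as NIfTI: labels as unsigned integers, intensities as
    float32, spacing stored in the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, LabeledVolume):
        data = vol.array.astype(np.uint16)
    elif isinstance(vol, IntensityVolume):
        data = vol.array.astype(np.float32)
    else:  # raw binary mask
        data = np.asarray(vol).astype(np.uint8)
    spacing = getattr(vol, "spacing_mm", None) or (1.0, 1.0, 1.0)
    affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))
    if isinstance(vol, LabeledVolume):
        write_legend(vol.legend, _legend_sidecar(path))
    return path


def _legend_sidecar(path) -> Path:
    p = Path(path)
    name = p.name.removesuffix(".gz").removesuffix(".nii")
    return p.with_name(name + ".legend.json")


def read_legend(path) -> dict[int, str]:
    with open(path) as fh:
        raw = json.load(fh)
    return {int(k): str(v) for k, v in raw.items()}


def write_legend(legend: dict[int, str], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({str(k): v for k, v in sorted(legend.items())}, fh, indent=1)
    return path


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; round-trips through YAML."""

    out_dir: str = "spinevoi_out"
    mode: str = "phantom"                 # "phantom" | "files"
    seed: int = 0
    n_pairs: int = 12
    channels: tuple[str, ...] = CHANNELS
    alpha: float = 0.05
    holm_variant: str = "standard"
    pooling: str = "voxel"
    write_masks: bool = True
    log_level: str = "INFO"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    morph: MorphParams = field(default_factory=MorphParams)
    # files mode
    labels_path: str | None = None
    legend_path: str | None = None
    intensity_paths: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.mode not in ("phantom", "files"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "phantom":
            if self.n_pairs < 2:
                raise ConfigError("n_pairs must be >= 2")
            self.phantom.validate()
        else:
            if not self.labels_path:
                raise ConfigError("files mode requires labels_path")
            for p in [self.labels_path, self.legend_path,
                      *self.intensity_paths.values()]:
                if p and not Path(p).exists():
                    raise ConfigError(f"input path does not exist: {p}")
        self.morph.validate()
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=_jsonify))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = dict(d["phantom"])
            for key in ("grid_shape", "voxel_spacing_mm", "body_size_mm",
                        "channels"):
                if key in ph and isinstance(ph[key], list):
                    ph[key] = tuple(ph[key])
            if "tissue_uptake" in ph:
                ph["tissue_uptake"] = {
                    ch: {t: tuple(ms) for t, ms in table.items()}
                    for ch, table in ph["tissue_uptake"].items()}
            d["phantom"] = PhantomConfig(**ph)
        if "morph" in d and isinstance(d["morph"], dict):
            d["morph"] = MorphParams(**d["morph"])
        if isinstance(d.get("channels"), list):
            d["channels"] = tuple(d["channels"])
        return cls(**d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _jsonify(obj):
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"cannot serialise {type(obj)}")


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    out_dir: Path
    metrics_path: Path | None
    comparison_path: Path | None
    manifest_path: Path | None
    provenance_path: Path
    vois: VoiSet
    comparison: pd.DataFrame | None


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(self.format(record))


def _subject_uptake(group: str, rng: np.random.Generator,
                    channels) -> dict[str, dict[str, tuple[float, float]]]:
    """Subject-level tissue table: group mean + between-subject effect.

    The between-subject SD reuses the published group SDs (the same values
    that drive the per-voxel noise); draw order is fixed by the sorted
    channel/tissue iteration so a subject's field never depends on which
    other subjects exist.
    """
    base = case_tissue_uptake() if group == "case" else default_tissue_uptake()
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for ch in channels:
        out[ch] = {}
        for tissue in sorted(base[ch]):
            mean, sd = base[ch][tissue]
            shifted = mean + rng.normal(0.0, sd)
            if ch != "CT_HU":
                shifted = max(shifted, 0.05 * mean)
            out[ch][tissue] = (shifted, sd)
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run phantom -> segmentation -> quantification -> statistics -> report."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    root = logging.getLogger("spinevoi")
    root.setLevel(config.log_level)
    collector = _WarningCollector()
    log_path = out_dir / "run.log"
    file_handler = logging.FileHandler(log_path, mode="w")
    file_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root.addHandler(collector)
    root.addHandler(file_handler)
    try:
        return _run(config, out_dir, collector)
    finally:
        root.removeHandler(collector)
        root.removeHandler(file_handler)
        file_handler.close()


def _run(config: PipelineConfig, out_dir: Path,
         collector: _WarningCollector) -> PipelineResult:
    logger.info("spinevoi %s pipeline, mode=%s, seed=%d",
                _pkg_version, config.mode, config.seed)
    manifest_path = comparison_path = None
    comparison = None

    if config.mode == "phantom":
        ph = dataclasses.replace(config.phantom, seed=config.seed,
                                 channels=tuple(config.channels))
        ph.validate()
        labels, tissue_masks, _ = _build_geometry(ph)
        vois = segment_all(labels, config.morph)

        ss = np.random.SeedSequence(config.seed)
        demo_stream, *subj_streams = ss.spawn(1 + 2 * config.n_pairs)
        subjects = _demographics(config.n_pairs,
                                 np.random.default_rng(demo_stream))
        frames = []
        for subj, stream in zip(subjects, subj_streams):
            eff_stream, noise_stream = stream.spawn(2)
            uptake = _subject_uptake(subj.group,
                                     np.random.default_rng(eff_stream),
                                     config.channels)
            intensities = paint_intensities(tissue_masks, uptake,
                                            tuple(config.channels),
                                            ph.voxel_spacing_mm, noise_stream,
                                            ph.smooth_fwhm_mm)
            frames.append(quantify_subject(intensities, vois, subj.subject_id,
                                           subj.pair_id, subj.group,
                                           pooling=config.pooling))
        metrics = pd.concat(frames, ignore_index=True)
        comparison, holm = build_comparison_table(metrics, alpha=config.alpha,
                                                  variant=config.holm_variant)
        manifest_path = out_dir / "subjects.csv"
        pd.DataFrame([dataclasses.asdict(s) for s in subjects]).to_csv(
            manifest_path, index=False)
        comparison_path = out_dir / "comparison.csv"
        comparison.to_csv(comparison_path, index=False)
        if config.write_masks:
            write_volume(labels, out_dir / "labels.nii.gz")
            _write_voi_masks(vois, out_dir / "vois")
    else:
        labels = read_volume(config.labels_path,
                             legend=read_legend(config.legend_path)
                             if config.legend_path else None)
        vois = segment_all(labels, config.morph)
        intensities = {ch: read_volume(p, channel=ch)
                       for ch, p in config.intensity_paths.items()}
        for ch, vol in intensities.items():
            if vol.array.shape != labels.array.shape:
                raise ConfigError(f"intensity {ch} not on the label grid")
        metrics = (quantify_subject(intensities, vois, pooling=config.pooling)
                   if intensities else vois.summary())
        if config.write_masks:
            _write_voi_masks(vois, out_dir / "vois")

    metrics_path = out_dir / "metrics.csv"
    metrics.to_csv(metrics_path, index=False)
    vois.summary().to_csv(out_dir / "voi_report.csv", index=False)

    provenance = {
        "package_version": _pkg_version,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "config": config.to_dict(),
        "morph_params": dataclasses.asdict(config.morph),
        "voi_voxel_counts": {f"{r.region}/{r.voi}": int(r.voxels)
                             for r in vois.summary().itertuples()},
        "warnings": list(collector.messages),
    }
    provenance_path = out_dir / "provenance.json"
    with open(provenance_path, "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete; outputs in %s", out_dir)
    return PipelineResult(out_dir, metrics_path, comparison_path,
                          manifest_path, provenance_path, vois, comparison)


def _write_voi_masks(vois: VoiSet, voi_dir: Path) -> None:
    voi_dir.mkdir(parents=True, exist_ok=True)
    for region in ("vertebral_bodies", "intervertebral_discs", "facet_joints"):
        for name, mask in vois.region_masks(region).items():
            path = voi_dir / f"{region}_{name}.nii.gz"
            img = nib.Nifti1Image(mask.astype(np.uint8),
                                  np.diag([*vois.spacing_mm, 1.0]))
            img.header.set_zooms(vois.spacing_mm)
            nib.save(img, str(path))
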