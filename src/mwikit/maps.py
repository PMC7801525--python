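"""Volume-scale fitting and voxel-wise atlas aggregation.

``fit_volume`` applies the per-voxel spectrum fit across a 4D multi-echo
volume inside a brain mask, producing MWF, IET2 and flip-angle maps.
``build_atlas`` aggregates co-aligned subject maps into voxel-wise mean,
median and sample-SD volumes, excluding any voxel not covered (valid) in
every subject — group statistics are only meaningful where all subjects
contribute.

Maps are exchanged as NIfTI-1; invalid voxels are encoded as NaN and volumes
are written float32. Registration is out of scope: inputs must already share
a common grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .epg import SequenceParams
from .fit import FitConfig, fit_voxel
from .metrics import MetricWindows, compute_iet2, compute_mwf

__all__ = ["EchoVolume", "MetricVolume", "AtlasSet", "FitSummary",
           "fit_volume", "build_atlas", "load_echo_volume", "load_mask",
           "load_metric_volume", "save_metric_volume", "save_atlas"]

log = logging.getLogger(__name__)


@dataclass
class EchoVolume:
    """4D multi-echo magnitude volume; echoes along the 4th axis."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("echo volume must be 4-D (x, y, z, echo)")

    @property
    def n_echoes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class MetricVolume:
    """3D scalar metric map; NaN marks invalid voxels."""

    data: np.ndarray
    metric: str
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("metric volume must be 3-D")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.data)


@dataclass
class AtlasSet:
    """Voxel-wise group statistics over co-aligned subject maps."""

    mean: MetricVolume
    median: MetricVolume
    sd: MetricVolume
    coverage: np.ndarray  # per-voxel count of subjects with a valid value
    n_subjects: int


@dataclass
class FitSummary:
    n_fitted: int
    n_degenerate: int
    n_masked: int


def fit_volume(vol: EchoVolume, mask: np.ndarray,
               cfg: FitConfig = FitConfig(),
               seq: SequenceParams = SequenceParams(),
               windows: MetricWindows = MetricWindows(),
               ) -> tuple[MetricVolume, MetricVolume, MetricVolume, FitSummary]:
    """Fit every masked voxel and reduce spectra to metric maps.

    Returns (mwf, iet2, flip) maps plus a summary of fitted and degenerate
    voxel counts. Voxels outside the mask, or with degenerate decays, are NaN.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    if vol.n_echoes != seq.n_echoes:
        raise ValueError(
            f"volume has {vol.n_echoes} echoes, sequence expects {seq.n_echoes}")

    mwf = np.full(vol.shape, np.nan)
    iet2 = np.full(vol.shape, np.nan)
    flip = np.full(vol.shape, np.nan)
    n_deg = 0
    idx = np.argwhere(mask)
    for (i, j, k) in idx:
        spectrum = fit_voxel(vol.data[i, j, k, :], cfg, seq)
        if spectrum.degenerate:
            n_deg += 1
            continue
        mwf[i, j, k] = compute_mwf(spectrum, windows)
        iet2[i, j, k] = compute_iet2(spectrum, windows)
        flip[i, j, k] = spectrum.flip_angle_estimate

    summary = FitSummary(n_fitted=len(idx) - n_deg, n_degenerate=n_deg,
                         n_masked=len(idx))
    log.info("fit_volume[%s]: %d fitted, %d degenerate of %d masked voxels",
             vol.subject_id, summary.n_fitted, summary.n_degenerate,
             summary.n_masked)
    sid, aff = vol.subject_id, vol.affine
    return (MetricVolume(mwf, "MWF", aff, sid),
            MetricVolume(iet2, "IET2", aff, sid),
            MetricVolume(flip, "FLIP", aff, sid),
            summary)


def build_atlas(maps: list[MetricVolume]) -> AtlasSet:
    """Voxel-wise mean, median and sample SD across co-aligned subject maps.

    A voxel enters the atlas only where every subject has a valid (finite)
    value; elsewhere all three statistics are NaN. SD uses the n-1
    denominator. Permutation-invariant in subject order.
    """
    if len(maps) < 2:
        raise ValueError("atlas needs at least 2 subject maps")
    shape = maps[0].data.shape
    metric = maps[0].metric
    for m in maps[1:]:
        if m.data.shape != shape:
            raise ValueError("subject maps are not on a common grid")

    stack = np.stack([m.data for m in maps], axis=0)
    coverage = np.isfinite(stack).sum(axis=0)
    full = coverage == len(maps)

    mean = np.full(shape, np.nan)
    median = np.full(shape, np.nan)
    sd = np.full(shape, np.nan)
    if np.any(full):
        vals = stack[:, full]
        mean[full] = vals.mean(axis=0)
        median[full] = np.median(vals, axis=0)
        sd[full] = vals.std(axis=0, ddof=1)

    aff = maps[0].affine
    return AtlasSet(mean=MetricVolume(mean, metric, aff),
                    median=MetricVolume(median, metric, aff),
                    sd=MetricVolume(sd, metric, aff),
                    coverage=coverage, n_subjects=len(maps))


# ---------------------------------------------------------------------------
# NIfTI-1 I/O

def load_echo_volume(path, subject_id: str = "") -> EchoVolume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    return EchoVolume(data=data, affine=img.affine, subject_id=subject_id)


def load_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0


def load_metric_volume(path, metric: str = "", subject_id: str = "") -> MetricVolume:
    img = nib.load(str(path))
    return MetricVolume(np.asarray(img.get_fdata(), dtype=float), metric,
                        img.affine, subject_id)


def save_metric_volume(vol: MetricVolume, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))


def save_atlas(atlas: AtlasSet, prefix) -> list[str]:
    """Write atlas statistics as ``<prefix>_{mean,median,sd,coverage}.nii``."""
    out = []
    for name, vol in (("mean", atlas.mean), ("median", atlas.median),
                      ("sd", atlas.sd)):
        p = f"{prefix}_{name}.nii"
        save_metric_volume(vol, p)
        out.append(p)
    p = f"{prefix}_coverage.nii"
    nib.save(nib.Nifti1Image(atlas.coverage.astype(np.float32),
                             atlas.mean.affine), p)
    out.append(p)
    return out
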