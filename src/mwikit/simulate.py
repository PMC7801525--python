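"""Synthetic cohorts with known ground truth for end-to-end validation.

No individual-subject imaging data are publicly available for this kind of
study, so every pipeline stage is exercised on simulated cohorts instead.
The generator produces:

* a block-layout digital phantom whose ROI labels stand in for white-matter
  tracts (genu/body/splenium-like, internal-capsule-like, SLF-like) plus a
  gray-matter-like compartment — no anatomical realism is claimed;
* per-ROI three-pool tissue truth (myelin water at T2 = 20 ms, an
  intra-/extra-cellular pool at 60-90 ms depending on ROI, and a small
  CSF-like pool at 1500 ms), with the myelin water fraction following a
  per-ROI inverted-U quadratic trajectory in age plus between-subject
  variation;
* a smooth spatial refocusing flip-angle field emulating B1 inhomogeneity;
* 48-echo GRASE-like magnitude decays (echo spacing 8 ms) synthesized with
  the EPG forward model, plus Gaussian (optionally Rician) noise at a stated
  first-echo SNR.

Everything is reproducible from a master seed; per-subject seeds are derived
by counter and recorded in the demographics table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .epg import SequenceParams, _epg_echo_train
from .maps import EchoVolume, MetricVolume, save_metric_volume

__all__ = ["RoiTissue", "PhantomSpec", "AgeModel", "SubjectData",
           "generate_subject", "generate_cohort", "generate_roi_cohort",
           "subject_seed", "DEFAULT_ROI_TISSUE", "DEFAULT_TRAJECTORIES",
           "COMBINE_LR"]


@dataclass(frozen=True)
class RoiTissue:
    """Static tissue truth of one ROI (myelin fraction comes from AgeModel)."""

    label: int
    ie_t2: float          # intra-/extra-cellular pool T2, ms
    csf_fraction: float   # long-T2 pool fraction
    myelin_t2: float = 20.0
    csf_t2: float = 1500.0


# ROI scheme name-mapped to common white-matter tract labels; the *_L/_R
# internal-capsule pair exercises left/right pooling.
DEFAULT_ROI_TISSUE: dict[str, RoiTissue] = {
    "genu_cc": RoiTissue(1, ie_t2=70.0, csf_fraction=0.02),
    "body_cc": RoiTissue(2, ie_t2=75.0, csf_fraction=0.02),
    "splenium_cc": RoiTissue(3, ie_t2=80.0, csf_fraction=0.02),
    "internal_capsule_L": RoiTissue(4, ie_t2=85.0, csf_fraction=0.01),
    "internal_capsule_R": RoiTissue(5, ie_t2=85.0, csf_fraction=0.01),
    "slf": RoiTissue(6, ie_t2=75.0, csf_fraction=0.02),
    "gray_matter": RoiTissue(7, ie_t2=90.0, csf_fraction=0.05),
}

COMBINE_LR: dict[str, tuple[int, int]] = {"internal_capsule": (4, 5)}


def quadratic_from_peak(peak_value: float, peak_age: float,
                        rise_20_to_peak: float) -> tuple[float, float, float]:
    """Coefficients (level, linear, quadratic) of an inverted-U trajectory.

    Parametrized by the peak value, the age of the peak, and the total rise
    between age 20 and the peak.
    """
    c = rise_20_to_peak / (peak_age - 20.0) ** 2
    return (peak_value - c * peak_age ** 2, 2.0 * c * peak_age, -c)


# Inverted-U MWF trajectories: rapid increase during the third decade, peak
# near the fifth decade, later decline. Peak values span the white-matter
# range reported for these tracts; the GM-like compartment is low-myelin.
# Rise of 0.025 between ages 20 and 50 with between-subject SD 0.012 gives
# age-effect strength comparable to in-vivo cohorts of ~100 adults.
DEFAULT_RISE = 0.025
DEFAULT_TRAJECTORIES: dict[str, tuple[float, float, float]] = {
    "genu_cc": quadratic_from_peak(0.155, 50.0, DEFAULT_RISE),
    "body_cc": quadratic_from_peak(0.170, 50.0, DEFAULT_RISE),
    "splenium_cc": quadratic_from_peak(0.195, 50.0, DEFAULT_RISE),
    "internal_capsule_L": quadratic_from_peak(0.180, 50.0, DEFAULT_RISE),
    "internal_capsule_R": quadratic_from_peak(0.180, 50.0, DEFAULT_RISE),
    "slf": quadratic_from_peak(0.140, 50.0, DEFAULT_RISE),
    "gray_matter": quadratic_from_peak(0.060, 50.0, 0.010),
}


@dataclass(frozen=True)
class AgeModel:
    """Per-ROI quadratic MWF-versus-age trajectories plus subject variation.

    ``trajectories[roi] = (b0, b1, b2)`` gives the population-mean myelin
    water fraction ``b0 + b1*age + b2*age^2``. Each subject's ROI truth adds
    a draw from N(0, between_subject_sd). ``sex_effect`` (added to male
    truth) defaults to zero — adult cohorts show no sex difference — and
    exists only for power studies.
    """

    trajectories: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORIES))
    between_subject_sd: float = 0.012
    sex_effect: float = 0.0
    age_range: tuple[float, float] = (20.0, 78.0)

    def population_mwf(self, roi: str, age: float) -> float:
        b0, b1, b2 = self.trajectories[roi]
        return b0 + b1 * age + b2 * age * age

    def subject_mwf(self, roi: str, age: float, sex: str,
                    rng: np.random.Generator) -> float:
        v = self.population_mwf(roi, age)
        v += rng.normal(0.0, self.between_subject_sd)
        if sex == "M":
            v += self.sex_effect
        return float(np.clip(v, 0.005, 0.5))

    def null(self) -> "AgeModel":
        """Same ROI levels but zero age dependence (for calibration tests)."""
        flat = {roi: (self.population_mwf(roi, 49.0), 0.0, 0.0)
                for roi in self.trajectories}
        return replace(self, trajectories=flat)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue truth, flip-angle field and noise of the phantom."""

    shape: tuple[int, int, int] = (12, 12, 4)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.5)
    rois: dict[str, RoiTissue] = field(
        default_factory=lambda: dict(DEFAULT_ROI_TISSUE))
    flip_range: tuple[float, float] = (130.0, 170.0)
    snr: float = 100.0  # first-echo WM signal over noise SD; inf = noiseless
    noise_model: str = "gaussian"  # or "rician"

    def __post_init__(self) -> None:
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        lo, hi = self.flip_range
        if not (90.0 <= lo <= hi <= 180.0):
            raise ValueError("flip_range must lie within [90, 180]")

    def label_volume(self) -> np.ndarray:
        """Block layout: ROIs tile the x axis in label order, full y/z extent."""
        nx, ny, nz = self.shape
        labels = np.zeros(self.shape, dtype=np.int16)
        names = list(self.rois)
        edges = np.linspace(0, nx, len(names) + 1).astype(int)
        for i, name in enumerate(names):
            labels[edges[i]:edges[i + 1], :, :] = self.rois[name].label
        return labels

    def flip_field(self) -> np.ndarray:
        """Smooth spatial flip-angle map: quadratic bowl across the x-y plane."""
        nx, ny, nz = self.shape
        x = np.linspace(-1.0, 1.0, nx)[:, None, None]
        y = np.linspace(-1.0, 1.0, ny)[None, :, None]
        bowl = 1.0 - 0.5 * (x ** 2 + y ** 2)  # in [0, 1]
        lo, hi = self.flip_range
        return np.broadcast_to(lo + (hi - lo) * bowl, self.shape).copy()

    def validate_fractions(self, age_model: AgeModel) -> None:
        """Reject specs whose pool fractions cannot sum to 1 over the age range."""
        for roi, tissue in self.rois.items():
            for age in np.linspace(*age_model.age_range, 30):
                mwf = age_model.population_mwf(roi, age)
                ie = 1.0 - mwf - tissue.csf_fraction
                if not (0 < mwf < 1 and ie > 0):
                    raise ValueError(
                        f"ROI '{roi}': pool fractions invalid at age {age:.0f} "
                        f"(myelin={mwf:.3f}, csf={tissue.csf_fraction})")


@dataclass
class SubjectData:
    """One simulated subject: noisy echoes plus all ground truth."""

    echo: EchoVolume
    mask: np.ndarray
    labels: np.ndarray
    truth_mwf: MetricVolume
    truth_iet2: MetricVolume
    truth_flip: MetricVolume
    roi_truth_mwf: dict[str, float]
    age: float
    sex: str
    seed: int


def subject_seed(master_seed: int, index: int) -> int:
    """Counter-based per-subject seed derivation (stable, < 2**31)."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_subject(spec: PhantomSpec, age_model: AgeModel, age: float,
                     sex: str, seed: int,
                     seq: SequenceParams = SequenceParams(),
                     subject_id: str = "") -> SubjectData:
    """Synthesize one subject's noisy multi-echo volume and ground truth.

    Per voxel the noiseless signal is the fraction-weighted sum of EPG decay
    curves of the three pools at the voxel's local flip angle. Ground-truth
    MWF equals the myelin pool fraction (pool fractions sum to 1) and
    ground-truth IET2 equals the ROI's IE pool T2.
    """
    lo, hi = age_model.age_range
    if not (lo <= age <= hi):
        raise ValueError(f"age {age} outside model range [{lo}, {hi}]")
    spec.validate_fractions(age_model)
    rng = np.random.default_rng(seed)

    labels = spec.label_volume()
    flip = spec.flip_field()
    mask = labels > 0

    echoes = np.zeros(spec.shape + (seq.n_echoes,))
    truth_mwf = np.full(spec.shape, np.nan)
    truth_iet2 = np.full(spec.shape, np.nan)
    roi_truth: dict[str, float] = {}

    for roi, tissue in spec.rois.items():
        mwf = age_model.subject_mwf(roi, age, sex, rng)
        csf = tissue.csf_fraction
        fractions = np.array([mwf, 1.0 - mwf - csf, csf])
        t2s = np.array([tissue.myelin_t2, tissue.ie_t2, tissue.csf_t2])
        roi_truth[roi] = mwf
        sel = np.argwhere(labels == tissue.label)
        for (i, j, k) in sel:
            curves = _epg_echo_train(t2s, float(flip[i, j, k]), seq)
            echoes[i, j, k, :] = curves @ fractions
            truth_mwf[i, j, k] = mwf
            truth_iet2[i, j, k] = tissue.ie_t2

    if np.isfinite(spec.snr):
        # reference signal: mean first echo over the phantom
        s_ref = float(echoes[mask, 0].mean())
        sigma = s_ref / spec.snr
        if spec.noise_model == "gaussian":
            echoes[mask] += rng.normal(0.0, sigma, echoes[mask].shape)
            np.abs(echoes, out=echoes)
        else:  # rician: magnitude of complex signal + complex noise
            re = echoes[mask] + rng.normal(0.0, sigma, echoes[mask].shape)
            im = rng.normal(0.0, sigma, echoes[mask].shape)
            echoes[mask] = np.hypot(re, im)

    truth_flip = np.where(mask, flip, np.nan)
    aff = np.diag(list(spec.spacing) + [1.0])
    return SubjectData(
        echo=EchoVolume(echoes, aff, subject_id),
        mask=mask, labels=labels,
        truth_mwf=MetricVolume(truth_mwf, "MWF", aff, subject_id),
        truth_iet2=MetricVolume(truth_iet2, "IET2", aff, subject_id),
        truth_flip=MetricVolume(truth_flip, "FLIP", aff, subject_id),
        roi_truth_mwf=roi_truth, age=age, sex=sex, seed=seed)


def _sample_ages(n: int, age_range: tuple[float, float],
                 rng: np.random.Generator) -> np.ndarray:
    """Stratified-uniform ages: subjects spread evenly across decade bins."""
    lo, hi = age_range
    edges = [e for e in (20, 30, 40, 50, 60, 70, 80) if lo < e < hi]
    edges = [lo] + edges + [hi]
    n_bins = len(edges) - 1
    if n < n_bins:
        return rng.uniform(lo, hi, n)  # too few for stratification
    counts = np.full(n_bins, n // n_bins)
    counts[:n % n_bins] += 1
    ages = np.concatenate([rng.uniform(edges[b], edges[b + 1], counts[b])
                           for b in range(n_bins)])
    rng.shuffle(ages)
    return ages


def _assign_sexes(n: int, sex_ratio: tuple[int, int],
                  rng: np.random.Generator) -> list[str]:
    """Exact deterministic F/M counts from the ratio; order shuffled."""
    f, m = sex_ratio
    n_f = int(round(n * f / (f + m)))
    sexes = ["F"] * n_f + ["M"] * (n - n_f)
    rng.shuffle(sexes)
    return sexes


def generate_cohort(spec: PhantomSpec, age_model: AgeModel, n: int,
                    master_seed: int, out_dir: str | Path,
                    sex_ratio: tuple[int, int] = (58, 42),
                    seq: SequenceParams = SequenceParams()) -> pd.DataFrame:
    """Generate ``n`` subjects on disk plus a demographics table.

    Writes per-subject NIfTI volumes (echoes, mask, labels, ground-truth
    maps) under ``out_dir/<id>/`` and ``out_dir/demographics.csv`` with
    columns id, age, sex, seed. Ages are stratified-uniform across decade
    bins; sex counts follow ``sex_ratio`` exactly.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_rng = np.random.default_rng(subject_seed(master_seed, 0))
    ages = _sample_ages(n, age_model.age_range, meta_rng)
    sexes = _assign_sexes(n, sex_ratio, meta_rng)

    rows = []
    for i in range(n):
        sid = f"sub{i + 1:03d}"
        seed_i = subject_seed(master_seed, i + 1)
        subj = generate_subject(spec, age_model, float(ages[i]), sexes[i],
                                seed_i, seq, subject_id=sid)
        sdir = out_dir / sid
        sdir.mkdir(exist_ok=True)
        aff = subj.echo.affine
        nib.save(nib.Nifti1Image(subj.echo.data.astype(np.float32), aff),
                 str(sdir / "echoes.nii"))
        nib.save(nib.Nifti1Image(subj.mask.astype(np.uint8), aff),
                 str(sdir / "mask.nii"))
        nib.save(nib.Nifti1Image(subj.labels.astype(np.int16), aff),
                 str(sdir / "labels.nii"))
        save_metric_volume(subj.truth_mwf, sdir / "truth_mwf.nii")
        save_metric_volume(subj.truth_iet2, sdir / "truth_iet2.nii")
        save_metric_volume(subj.truth_flip, sdir / "truth_flip.nii")
        rows.append({"id": sid, "age": round(float(ages[i]), 2),
                     "sex": sexes[i], "seed": seed_i})

    demo = pd.DataFrame(rows)
    demo.to_csv(out_dir / "demographics.csv", index=False,
                quoting=csv.QUOTE_MINIMAL)
    return demo


def generate_roi_cohort(age_model: AgeModel, n: int, master_seed: int,
                        rois: list[str] | None = None,
                        sex_ratio: tuple[int, int] = (58, 42),
                        metric: str = "MWF") -> pd.DataFrame:
    """ROI-mean-level cohort draws: trajectory truth plus subject noise.

    Skips the imaging chain entirely — each subject x ROI value is the
    population trajectory at the subject's age plus an N(0, sd) draw. Used
    for replicate-heavy statistical validation where fitting thousands of
    phantoms would add nothing: the imaging chain's fidelity is established
    separately by the recovery suite.

    Returns a cohort table with columns subject_id, roi, metric, value,
    age, sex.
    """
    rois = list(age_model.trajectories) if rois is None else rois
    meta_rng = np.random.default_rng(subject_seed(master_seed, 0))
    ages = _sample_ages(n, age_model.age_range, meta_rng)
    sexes = _assign_sexes(n, sex_ratio, meta_rng)
    rows = []
    for i in range(n):
        rng = np.random.default_rng(subject_seed(master_seed, i + 1))
        sid = f"sub{i + 1:03d}"
        for roi in rois:
            rows.append({"subject_id": sid, "roi": roi, "metric": metric,
                         "value": age_model.subject_mwf(roi, float(ages[i]),
                                                        sexes[i], rng),
                         "age": float(ages[i]), "sex": sexes[i]})
    return pd.DataFrame(rows)
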