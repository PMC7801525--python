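"""ROI extraction and age/sex statistics for quantitative metric maps.

Mirrors the standard region-of-interest analysis of aging studies of myelin
water imaging: per-subject ROI means (left/right label pairs pooled at the
voxel level), Pearson correlation of each ROI mean with age, quadratic
multiple regression (metric ~ age + age^2 [+ sex]) with an adjusted r-value,
and decade-binned group summaries with ROI rankings.

Conventions:

* Significance threshold P < 0.01, two-sided; no multiple-testing correction
  across ROIs.
* Age and age^2 enter untransformed (no centering). The terms are collinear,
  which inflates per-term standard errors but does not affect the fit itself.
* Adjusted r is sqrt(max(0, adjusted R^2)) with
  adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1).
* Sex is coded F = 0, M = 1; inference is invariant to the coding.
* Decade bins are [20, 30), [30, 40), ..., [70, 80), labelled third..eighth
  decade of life.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .maps import MetricVolume

__all__ = ["RegressionResult", "DecadeSummary", "extract_roi_means",
           "build_cohort_table", "pearson_age_correlation",
           "quadratic_age_regression", "decade_summaries",
           "P_THRESHOLD", "DECADE_EDGES", "DECADE_LABELS"]

P_THRESHOLD = 0.01
DECADE_EDGES = [20, 30, 40, 50, 60, 70, 80]
DECADE_LABELS = ["third", "fourth", "fifth", "sixth", "seventh", "eighth"]


@dataclass
class RegressionResult:
    roi: str
    metric: str
    n: int
    pearson_r: float = np.nan
    pearson_p: float = np.nan
    significant: bool = False
    adj_r: float = np.nan
    r2: float = np.nan
    coef_age: float = np.nan
    coef_age2: float = np.nan
    coef_sex: float = np.nan
    p_age: float = np.nan
    p_age2: float = np.nan
    p_sex: float = np.nan
    flag: str = ""


@dataclass
class DecadeSummary:
    roi: str
    metric: str
    decade: str
    mean: float
    sd: float
    n: int
    rank: int


def extract_roi_means(vol: MetricVolume, labels: np.ndarray,
                      roi_names: dict[int, str],
                      combine_lr: dict[str, tuple[int, int]] | None = None,
                      ) -> pd.DataFrame:
    """Mean metric value over the valid voxels of each ROI.

    ``roi_names`` maps label integers to ROI names. ``combine_lr`` maps a
    combined ROI name to a (left, right) label pair; the pair's voxels are
    pooled before averaging, so each voxel carries equal weight regardless of
    which hemisphere is larger. ROIs with no valid voxels are returned with a
    NaN mean and counted in the ``n_voxels`` column as 0.
    """
    labels = np.asarray(labels)
    if labels.shape != vol.data.shape:
        raise ValueError("label volume not aligned with metric map")
    valid = vol.valid
    rows = []

    def roi_mean(sel: np.ndarray) -> tuple[float, int]:
        sel = sel & valid
        n = int(sel.sum())
        return (float(vol.data[sel].mean()) if n else float("nan")), n

    combined_ids = set()
    if combine_lr:
        for name, (l, r) in combine_lr.items():
            combined_ids.update((l, r))
            m, n = roi_mean((labels == l) | (labels == r))
            rows.append({"roi": name, "metric": vol.metric, "value": m,
                         "n_voxels": n})
    for lab, name in roi_names.items():
        if lab in combined_ids:
            continue
        m, n = roi_mean(labels == lab)
        rows.append({"roi": name, "metric": vol.metric, "value": m,
                     "n_voxels": n})
    df = pd.DataFrame(rows)
    df.insert(0, "subject_id", vol.subject_id)
    return df


def build_cohort_table(roi_rows: pd.DataFrame,
                       demographics: pd.DataFrame) -> pd.DataFrame:
    """Join per-subject ROI means with demographics (id, age, sex)."""
    required = {"id", "age", "sex"}
    missing = required - set(demographics.columns)
    if missing:
        raise ValueError(f"demographics missing column(s): {sorted(missing)}")
    bad_sex = set(demographics["sex"].unique()) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"sex must be 'M' or 'F', got {sorted(bad_sex)}")
    merged = roi_rows.merge(demographics.rename(columns={"id": "subject_id"}),
                            on="subject_id", how="left")
    if merged["age"].isna().any():
        orphans = merged.loc[merged["age"].isna(), "subject_id"].unique()
        raise ValueError(f"subjects missing demographics: {list(orphans)}")
    return merged


def _roi_series(table: pd.DataFrame, roi: str, metric: str) -> pd.DataFrame:
    sel = table[(table["roi"] == roi) & (table["metric"] == metric)]
    return sel.dropna(subset=["value"])


def pearson_age_correlation(table: pd.DataFrame, roi: str,
                            metric: str) -> RegressionResult:
    """Pearson correlation between age and the ROI's mean metric value.

    Two-sided p-value; flagged significant at P < 0.01. Zero variance in
    either variable yields an undefined correlation with a flag.
    """
    sel = _roi_series(table, roi, metric)
    n = len(sel)
    if n < 3:
        return RegressionResult(roi, metric, n, flag="insufficient_n")
    age = sel["age"].to_numpy(float)
    val = sel["value"].to_numpy(float)
    if np.ptp(age) == 0 or np.ptp(val) == 0:
        return RegressionResult(roi, metric, n, flag="zero_variance")
    r, p = sps.pearsonr(age, val)
    return RegressionResult(roi, metric, n, pearson_r=float(r),
                            pearson_p=float(p),
                            significant=bool(p < P_THRESHOLD))


def quadratic_age_regression(table: pd.DataFrame, roi: str, metric: str,
                             include_sex: bool = False,
                             include_quadratic: bool = True) -> RegressionResult:
    """OLS of the ROI metric on age and age^2, optionally with binarized sex.

    Reports per-term two-sided p-values and the adjusted r-value
    sqrt(max(0, adjusted R^2)). ``include_quadratic=False`` gives the plain
    linear model (useful for consistency checks against the Pearson route).
    """
    sel = _roi_series(table, roi, metric)
    n = len(sel)
    if n < 5:
        return RegressionResult(roi, metric, n, flag="insufficient_n")
    age = sel["age"].to_numpy(float)
    val = sel["value"].to_numpy(float)
    cols = [age]
    names = ["age"]
    if include_quadratic:
        cols.append(age ** 2)
        names.append("age2")
    if include_sex:
        cols.append((sel["sex"].to_numpy() == "M").astype(float))
        names.append("sex")
    x = sm.add_constant(np.column_stack(cols), has_constant="add")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        return RegressionResult(roi, metric, n, flag="degenerate_design")
    res = sm.OLS(val, x).fit()

    p = x.shape[1] - 1
    adj_r2 = 1.0 - (1.0 - res.rsquared) * (n - 1) / (n - p - 1)
    out = RegressionResult(roi, metric, n, r2=float(res.rsquared),
                           adj_r=float(np.sqrt(max(0.0, adj_r2))))
    for i, name in enumerate(names, start=1):
        setattr(out, f"coef_{name}", float(res.params[i]))
        setattr(out, f"p_{name}", float(res.pvalues[i]))
    out.significant = bool(include_quadratic and out.p_age2 < P_THRESHOLD)
    return out


def assign_decade(age: float) -> str | None:
    """Decade-of-life label for an age, or None outside [20, 80)."""
    for lo, hi, lab in zip(DECADE_EDGES[:-1], DECADE_EDGES[1:], DECADE_LABELS):
        if lo <= age < hi:
            return lab
    return None


def decade_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Group means, sample SDs and ROI rankings per decade-of-age bin.

    Within each (metric, decade) the ROIs are densely ranked by descending
    group mean (rank 1 = highest). Bins with a single subject report SD as
    NaN; empty bins are omitted.
    """
    t = table.copy()
    t["decade"] = t["age"].map(assign_decade)
    t = t.dropna(subset=["decade", "value"])
    rows = []
    for (metric, decade), g in t.groupby(["metric", "decade"], sort=False):
        per_roi = g.groupby("roi")["value"].agg(["mean", "std", "count"])
        per_roi["rank"] = per_roi["mean"].rank(ascending=False,
                                               method="dense").astype(int)
        for roi, row in per_roi.iterrows():
            rows.append(DecadeSummary(roi=roi, metric=metric, decade=decade,
                                      mean=float(row["mean"]),
                                      sd=float(row["std"]),
                                      n=int(row["count"]),
                                      rank=int(row["rank"])))
    return pd.DataFrame([vars(r) for r in rows])
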