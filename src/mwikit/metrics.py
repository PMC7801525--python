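"""Scalar metrics derived from a fitted T2 spectrum.

Two metrics summarize the multi-component T2 distribution of brain tissue:

* **MWF** (myelin water fraction): the fraction of total spectrum amplitude
  with 15 ms <= T2 < 40 ms. Water trapped between myelin bilayers relaxes
  fast; this window isolates it from intra-/extra-cellular water.
* **IET2**: the amplitude-weighted geometric mean T2 of components with
  40 ms <= T2 < 200 ms, characterizing the intra-/extra-cellular water pool.
  Sensitive to tissue water and iron content.

Both windows are half-open ``[lo, hi)``. The MWF denominator is the full
spectrum sum, including any long-T2 (CSF-like) amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fit import T2Spectrum

__all__ = ["MetricWindows", "VoxelMetrics", "compute_mwf", "compute_iet2",
           "window_fractions", "compute_metrics"]


@dataclass(frozen=True)
class MetricWindows:
    """T2 window boundaries in ms; intervals are half-open ``[lo, hi)``."""

    myelin_lo: float = 15.0
    myelin_hi: float = 40.0
    ie_hi: float = 200.0

    def __post_init__(self) -> None:
        if not (0 < self.myelin_lo < self.myelin_hi < self.ie_hi):
            raise ValueError("window boundaries must be increasing and positive")

    @property
    def ie_lo(self) -> float:
        # IE window starts where the myelin window ends
        return self.myelin_hi


@dataclass(frozen=True)
class VoxelMetrics:
    mwf: float
    iet2: float
    valid: bool


def compute_mwf(spectrum: T2Spectrum,
                windows: MetricWindows = MetricWindows()) -> float:
    """Myelin water fraction: short-T2 amplitude over total amplitude.

    Returns NaN for degenerate spectra or zero total amplitude. Invariant
    under global rescaling of the spectrum.
    """
    s = np.asarray(spectrum.amplitudes, dtype=float)
    t2 = spectrum.grid.values
    total = s.sum()
    if spectrum.degenerate or total <= 0:
        return float("nan")
    myelin = s[(t2 >= windows.myelin_lo) & (t2 < windows.myelin_hi)].sum()
    return float(myelin / total)


def compute_iet2(spectrum: T2Spectrum,
                 windows: MetricWindows = MetricWindows()) -> float:
    """Amplitude-weighted geometric mean T2 over the intra-/extra-cellular
    window, ``exp(sum_j s_j ln T2_j / sum_j s_j)`` for T2_j in [40, 200) ms.

    Returns NaN when no amplitude falls inside the window.
    """
    s = np.asarray(spectrum.amplitudes, dtype=float)
    t2 = spectrum.grid.values
    sel = (t2 >= windows.ie_lo) & (t2 < windows.ie_hi)
    w = s[sel]
    if spectrum.degenerate or w.sum() <= 0:
        return float("nan")
    return float(np.exp(np.sum(w * np.log(t2[sel])) / w.sum()))


def window_fractions(spectrum: T2Spectrum,
                     windows: MetricWindows = MetricWindows()) -> dict[str, float]:
    """Fractions of total amplitude in the myelin, IE and long-T2 windows.

    The three fractions partition the spectrum below/at/above the window
    boundaries and sum to 1 for any valid spectrum.
    """
    s = np.asarray(spectrum.amplitudes, dtype=float)
    t2 = spectrum.grid.values
    total = s.sum()
    if total <= 0:
        return {"myelin": float("nan"), "ie": float("nan"), "long": float("nan")}
    myelin = s[(t2 >= windows.myelin_lo) & (t2 < windows.myelin_hi)].sum()
    ie = s[(t2 >= windows.ie_lo) & (t2 < windows.ie_hi)].sum()
    lo = s[t2 < windows.myelin_lo].sum()
    long_ = s[t2 >= windows.ie_hi].sum() + lo
    return {"myelin": float(myelin / total), "ie": float(ie / total),
            "long": float(long_ / total)}


def compute_metrics(spectrum: T2Spectrum,
                    windows: MetricWindows = MetricWindows()) -> VoxelMetrics:
    """Both scalar metrics for one voxel, with a joint validity flag."""
    mwf = compute_mwf(spectrum, windows)
    iet2 = compute_iet2(spectrum, windows)
    return VoxelMetrics(mwf=mwf, iet2=iet2, valid=np.isfinite(mwf))
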