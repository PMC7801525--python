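"""Stimulated-echo-corrected, regularized NNLS T2-spectrum fitting.

Each voxel's multi-echo decay is decomposed onto a dictionary of EPG decay
curves, one per T2 grid point, by non-negative least squares. Two refinements
make the estimate robust in practice:

* **Stimulated echo correction** — the effective refocusing flip angle is
  estimated per voxel by scanning a small set of candidate angles, computing
  the unregularized NNLS misfit at each, and minimizing a cubic-spline
  interpolant of the misfit-versus-angle profile. The final spectrum is fitted
  with the basis built at the estimated angle, so T2 estimates are unbiased by
  B1 imperfection.
* **Chi-squared-constrained Tikhonov regularization** — a minimum-energy
  penalty ``mu * ||s||^2`` is added and ``mu`` tuned (bisection on log mu
  against the monotone misfit curve) so the data misfit equals
  ``chi2_factor`` times the unregularized minimum. The default factor 1.02
  trades a 2% misfit increase for substantially smoother, more stable spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import nnls as _scipy_nnls

from .epg import SequenceParams, T2Grid, build_basis

__all__ = [
    "FitConfig",
    "T2Spectrum",
    "FlipEstimate",
    "nnls_fit",
    "regularized_nnls_fit",
    "estimate_flip_angle",
    "fit_voxel",
]

DEFAULT_FLIP_CANDIDATES = tuple(np.linspace(90.0, 180.0, 8))


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the voxel-wise spectrum fit.

    Defaults follow the reference protocol: a 40-point log grid from 15 to
    2000 ms, 8 candidate refocusing flip angles spanning 90–180°, and a
    chi-squared regularization factor of 1.02.
    """

    grid: T2Grid = field(default_factory=T2Grid.log_spaced)
    flip_candidates: tuple[float, ...] = DEFAULT_FLIP_CANDIDATES
    chi2_factor: float = 1.02
    mu_search_tolerance: float = 1e-3
    max_search_iterations: int = 100

    def __post_init__(self) -> None:
        if self.chi2_factor < 1:
            raise ValueError("chi2_factor must be >= 1")
        fc = np.asarray(self.flip_candidates, dtype=float)
        if fc.size < 1 or np.any(fc <= 0) or np.any(fc > 180):
            raise ValueError("flip_candidates must lie in (0, 180]")


@dataclass
class T2Spectrum:
    """Fitted non-negative T2 spectrum for one voxel.

    Attributes
    ----------
    amplitudes : numpy.ndarray
        Non-negative weight at each grid T2 (signal units).
    grid : T2Grid
    flip_angle_estimate : float
        Estimated refocusing flip angle in degrees (NaN if not estimated).
    chi2_min : float
        Squared residual norm of the unregularized fit.
    chi2_reg : float
        Squared residual norm (data term only) of the returned fit.
    mu : float
        Tikhonov weight achieved by the chi-squared search.
    degenerate : bool
        True for voxels whose decay could not be fit (all-zero or non-finite
        input); amplitudes are all zero in that case.
    converged : bool
        False when the mu search hit its iteration cap before reaching the
        target chi-squared ratio.
    """

    amplitudes: np.ndarray
    grid: T2Grid
    flip_angle_estimate: float = np.nan
    chi2_min: float = np.nan
    chi2_reg: float = np.nan
    mu: float = 0.0
    degenerate: bool = False
    converged: bool = True


@dataclass
class FlipEstimate:
    """Result of per-voxel flip-angle estimation."""

    angle: float
    candidate_angles: np.ndarray
    candidate_misfits: np.ndarray
    flat_profile: bool = False


def nnls_fit(decay: np.ndarray, basis: np.ndarray) -> tuple[np.ndarray, float]:
    """Non-negative least squares: minimize ``||basis @ s - decay||^2, s >= 0``.

    Returns the amplitude vector and the squared residual norm (chi2).
    An all-zero decay yields all-zero amplitudes with chi2 = 0.
    """
    decay = np.asarray(decay, dtype=float)
    basis = np.asarray(basis, dtype=float)
    if basis.shape[0] != decay.shape[0]:
        raise ValueError(
            f"basis has {basis.shape[0]} rows but decay has {decay.shape[0]} echoes")
    if not np.any(decay):
        return np.zeros(basis.shape[1]), 0.0
    s, rnorm = _scipy_nnls(basis, decay)
    return s, float(rnorm ** 2)


def _misfit(basis: np.ndarray, decay: np.ndarray, s: np.ndarray) -> float:
    r = basis @ s - decay
    return float(r @ r)


def _regularized_solve(basis: np.ndarray, decay: np.ndarray,
                       mu: float) -> np.ndarray:
    n_cols = basis.shape[1]
    a = np.vstack([basis, np.sqrt(mu) * np.eye(n_cols)])
    b = np.concatenate([decay, np.zeros(n_cols)])
    s, _ = _scipy_nnls(a, b)
    return s

def regularized_nnls_fit(decay: np.ndarray, basis: np.ndarray,
                         cfg: FitConfig) -> T2Spectrum:
    """Chi-squared-constrained Tikhonov-regularized NNLS fit.

    Solves ``min ||basis s - y||^2 + mu ||s||^2, s >= 0`` with ``mu`` chosen
    so the data misfit equals ``cfg.chi2_factor`` times the unregularized
    minimum, within ``cfg.mu_search_tolerance`` (relative, on the ratio).
    ``chi2_factor == 1`` returns the plain NNLS solution with ``mu = 0``.
    The misfit is monotone non-decreasing in ``mu``, so the target is located
    by geometric bracketing followed by bisection on ``log mu``.
    """
    decay = np.asarray(decay, dtype=float)
    s0, chi2_min = nnls_fit(decay, basis)
    if chi2_min == 0.0 and not np.any(decay):
        return T2Spectrum(np.zeros(basis.shape[1]), grid=None,
                          chi2_min=0.0, chi2_reg=0.0, degenerate=True)

    yy = float(decay @ decay)
    if cfg.chi2_factor == 1.0 or chi2_min <= 1e-12 * yy:
        # exact-fit regime: any mu > 0 overshoots a (near-)zero target
        return T2Spectrum(s0, grid=None, chi2_min=chi2_min, chi2_reg=chi2_min,
                          mu=0.0, converged=True)

    target = cfg.chi2_factor * chi2_min
    tol = cfg.mu_search_tolerance

    mu = 1e-8 * float(np.max(np.abs(basis.T @ decay)))
    s = _regularized_solve(basis, decay, mu)
    chi2 = _misfit(basis, decay, s)
    iters = 0
    # expand upward until the target misfit is bracketed
    mu_lo, chi_lo = 0.0, chi2_min
    while chi2 < target and iters < cfg.max_search_iterations:
        mu_lo, chi_lo = mu, chi2
        mu *= 10.0
        s = _regularized_solve(basis, decay, mu)
        chi2 = _misfit(basis, decay, s)
        iters += 1
    mu_hi, chi_hi, s_hi = mu, chi2, s

    best_s, best_mu, best_chi2 = s_hi, mu_hi, chi_hi
    converged = abs(chi_hi / target - 1.0) <= tol
    while not converged and iters < cfg.max_search_iterations:
        mu_mid = np.sqrt(mu_lo * mu_hi) if mu_lo > 0 else mu_hi / 10.0
        s = _regularized_solve(basis, decay, mu_mid)
        chi2 = _misfit(basis, decay, s)
        iters += 1
        if abs(chi2 - target) < abs(best_chi2 - target):
            best_s, best_mu, best_chi2 = s, mu_mid, chi2
        if abs(chi2 / target - 1.0) <= tol:
            converged = True
            break
        if chi2 < target:
            mu_lo = mu_mid
        else:
            mu_hi = mu_mid

    return T2Spectrum(best_s, grid=None, chi2_min=chi2_min, chi2_reg=best_chi2,
                      mu=best_mu, converged=converged)


def estimate_flip_angle(decay: np.ndarray, cfg: FitConfig,
                        seq: SequenceParams) -> FlipEstimate:
    """Estimate the effective refocusing flip angle of one voxel.

    Computes the unregularized NNLS misfit at each candidate angle, minimizes
    a cubic-spline interpolant of the misfit-versus-angle profile over the
    candidate range, then verifies the interpolated minimizer by evaluating
    its true misfit: the best sampled candidate is kept instead whenever the
    spline minimum does not genuinely improve on it (the spline can ring
    where the profile drops sharply, e.g. toward an exact 180-degree optimum).

    A flat misfit profile marks a voxel without usable flip information
    (pure-noise profiles vary by only a few percent across candidates,
    genuine tissue decays by an order of magnitude); the minimum sampled
    angle is then returned with a low-confidence flag.
    """
    angles = np.asarray(cfg.flip_candidates, dtype=float)
    misfits = np.empty_like(angles)
    for i, ang in enumerate(angles):
        basis = build_basis(cfg.grid, float(ang), seq)
        _, misfits[i] = nnls_fit(decay, basis)

    i_best = int(np.argmin(misfits))
    spread = misfits.max() - misfits.min()
    if misfits.max() <= 0 or spread / misfits.max() < 0.2:
        return FlipEstimate(float(angles[i_best]), angles, misfits,
                            flat_profile=True)
    if angles.size < 4:
        return FlipEstimate(float(angles[i_best]), angles, misfits)

    spline = CubicSpline(angles, misfits)
    fine = np.arange(angles[0], angles[-1] + 1e-9, 0.05)
    cand = float(fine[np.argmin(spline(fine))])
    _, cand_misfit = nnls_fit(decay, build_basis(cfg.grid, cand, seq))
    if cand_misfit >= misfits[i_best]:
        cand = float(angles[i_best])
    return FlipEstimate(cand, angles, misfits)


def fit_voxel(decay: np.ndarray, cfg: FitConfig = FitConfig(),
              seq: SequenceParams = SequenceParams()) -> T2Spectrum:
    """Full per-voxel pipeline: flip estimation, basis build, regularized fit.

    Degenerate decays (all zero, or containing non-finite values) return a
    flagged all-zero spectrum rather than raising, so whole-volume fitting is
    total.
    """
    decay = np.asarray(decay, dtype=float)
    if decay.shape[0] != seq.n_echoes:
        raise ValueError(
            f"decay has {decay.shape[0]} echoes, sequence expects {seq.n_echoes}")
    if not np.all(np.isfinite(decay)) or not np.any(decay):
        return T2Spectrum(np.zeros(cfg.grid.n_points), grid=cfg.grid,
                          degenerate=True, chi2_min=0.0, chi2_reg=0.0)

    flip = estimate_flip_angle(decay, cfg, seq)
    basis = build_basis(cfg.grid, flip.angle, seq)
    spectrum = regularized_nnls_fit(decay, basis, cfg)
    spectrum.grid = cfg.grid
    spectrum.flip_angle_estimate = flip.angle
    return spectrum
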