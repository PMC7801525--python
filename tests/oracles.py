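"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the isochromat
simulator integrates the Bloch equations over a brute-force ensemble of
dephased spins, and the NNLS oracle enumerates every active set of a small
problem. They exist to cross-check the EPG recursion and the NNLS solver
route, so they must stay independent of `mwikit.epg` / `mwikit.fit`.
"""

from __future__ import annotations

import itertools

import numpy as np


def isochromat_decay(t2: float, flip_deg: float, n_echoes: int,
                     delta_te: float, t1: float,
                     n_spins: int = 2000) -> np.ndarray:
    """Brute-force Bloch simulation of a CPMG echo train.

    An ensemble of spins with dephasing angles uniform on [0, 2pi) models the
    idealized crusher gradients: each half inter-echo interval every spin
    precesses by its own angle (equal gradient areas on both sides of each
    pulse). Excitation is 90deg about y (magnetization to +x), refocusing is
    about x (CPMG condition). Longitudinal regrowth is neglected. The echo
    amplitude is the magnitude of the complex ensemble mean.
    """
    a = np.deg2rad(flip_deg)
    rot_x = np.array([[1.0, 0.0, 0.0],
                      [0.0, np.cos(a), -np.sin(a)],
                      [0.0, np.sin(a), np.cos(a)]])
    theta = 2.0 * np.pi * np.arange(n_spins) / n_spins
    ct, st = np.cos(theta), np.sin(theta)
    e2 = np.exp(-delta_te / 2.0 / t2)
    e1 = np.exp(-delta_te / 2.0 / t1)

    m = np.zeros((n_spins, 3))
    m[:, 0] = 1.0  # after ideal 90deg_y excitation

    def dephase(mm):
        x, y = mm[:, 0].copy(), mm[:, 1].copy()
        mm[:, 0] = ct * x - st * y
        mm[:, 1] = st * x + ct * y

    out = np.empty(n_echoes)
    for n in range(n_echoes):
        m[:, :2] *= e2
        m[:, 2] *= e1
        dephase(m)
        m = m @ rot_x.T
        dephase(m)
        m[:, :2] *= e2
        m[:, 2] *= e1
        out[n] = np.abs(np.mean(m[:, 0] + 1j * m[:, 1]))
    return out


def nnls_by_enumeration(a: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact NNLS by exhaustive enumeration of active sets.

    For every support set S, solve the unconstrained least squares restricted
    to S; keep candidates whose solution is non-negative and whose KKT
    multipliers for the zeroed variables are non-negative; return the
    feasible candidate with the smallest residual. Exponential in the number
    of columns — small instances only.
    """
    n = a.shape[1]
    best, best_r = np.zeros(n), float(y @ y)
    for k in range(1, n + 1):
        for support in itertools.combinations(range(n), k):
            s_sub, *_ = np.linalg.lstsq(a[:, support], y, rcond=None)
            if np.any(s_sub < -1e-12):
                continue
            s = np.zeros(n)
            s[list(support)] = np.clip(s_sub, 0.0, None)
            resid = a @ s - y
            grad = a.T @ resid
            off = [i for i in range(n) if i not in support]
            if off and np.any(grad[off] < -1e-8):
                continue
            r = float(resid @ resid)
            if r < best_r - 1e-15:
                best, best_r = s, r
    return best


def pearson_by_arithmetic(x, y) -> float:
    """Textbook Pearson r evaluated by explicit sums (no library call)."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(u * v for u, v in zip(x, y))
    num = n * sxy - sx * sy
    den = ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5
    return num / den
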