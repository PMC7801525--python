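"""Pipeline configuration: a single YAML file of defaults for every stage.

The file mirrors the reference acquisition and analysis protocol: 48 echoes
at 8 ms spacing, a 40-point log-spaced 15-2000 ms T2 grid, 8 candidate
refocusing flip angles spanning 90-180°, a chi-squared regularization factor
of 1.02, and metric windows at 15/40/200 ms. Unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .epg import SequenceParams, T2Grid
from .fit import FitConfig
from .metrics import MetricWindows

__all__ = ["PipelineConfig", "load_config"]

_SEQ_KEYS = {"n_echoes", "delta_te", "t1_assumed", "excitation_flip"}
_FIT_KEYS = {"t2_min", "t2_max", "n_t2", "n_flip_candidates", "chi2_factor",
             "mu_search_tolerance", "max_search_iterations"}
_WIN_KEYS = {"myelin_lo", "myelin_hi", "ie_hi"}
_TOP_KEYS = {"sequence", "fit", "windows", "seed", "verbose"}


@dataclass
class PipelineConfig:
    sequence: SequenceParams = field(default_factory=SequenceParams)
    fit: FitConfig = field(default_factory=FitConfig)
    windows: MetricWindows = field(default_factory=MetricWindows)
    seed: int = 0
    verbose: bool = False


def _check_keys(section: dict, allowed: set[str], name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in '{name}': {sorted(unknown)}")


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML pipeline config; ``None`` returns protocol defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    _check_keys(raw, _TOP_KEYS, "top level")

    seq_raw = raw.get("sequence", {})
    _check_keys(seq_raw, _SEQ_KEYS, "sequence")
    seq = SequenceParams(**seq_raw)

    fit_raw = dict(raw.get("fit", {}))
    _check_keys(fit_raw, _FIT_KEYS, "fit")
    grid = T2Grid.log_spaced(fit_raw.pop("t2_min", 15.0),
                             fit_raw.pop("t2_max", 2000.0),
                             fit_raw.pop("n_t2", 40))
    n_flip = fit_raw.pop("n_flip_candidates", 8)
    import numpy as np
    flips = tuple(np.linspace(90.0, 180.0, n_flip))
    fit = FitConfig(grid=grid, flip_candidates=flips, **fit_raw)

    win_raw = raw.get("windows", {})
    _check_keys(win_raw, _WIN_KEYS, "windows")
    windows = MetricWindows(**win_raw)

    return PipelineConfig(sequence=seq, fit=fit, windows=windows,
                          seed=int(raw.get("seed", 0)),
                          verbose=bool(raw.get("verbose", False)))
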