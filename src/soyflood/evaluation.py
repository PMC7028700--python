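"""Goodness-of-fit metrics and control-normalised penalty summaries."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "rrmse",
    "modelling_efficiency",
    "r_squared",
    "normalize_to_control",
    "yield_penalty_percent",
]


def _pairs(observed, simulated) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and simulated must be 1-D, equal length >= 2")
    return obs, sim


def rrmse(observed, simulated) -> float:
    """Relative root mean square error, percent of the observed mean."""
    obs, sim = _pairs(observed, simulated)
    m = obs.mean()
    if m == 0:
        raise ValueError("mean(observed) must be nonzero for RRMSE")
    return float(100.0 * np.sqrt(np.mean((sim - obs) ** 2)) / m)


def modelling_efficiency(observed, simulated) -> float:
    """Nash-Sutcliffe modelling efficiency: 1 - SSE / SStot; 1 is perfect,
    0 matches the observed-mean predictor."""
    obs, sim = _pairs(observed, simulated)
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    if sstot == 0:
        raise ValueError("observed series has zero variance")
    return float(1.0 - np.sum((sim - obs) ** 2) / sstot)


def r_squared(observed, simulated) -> float:
    """Squared Pearson correlation."""
    obs, sim = _pairs(observed, simulated)
    if np.std(obs) == 0 or np.std(sim) == 0:
        raise ValueError("both series must be non-constant")
    r, _ = stats.pearsonr(obs, sim)
    return float(r * r)


def normalize_to_control(values, control_value: float) -> np.ndarray:
    """Divide each value by its experiment's control value."""
    if control_value <= 0:
        raise ValueError("control_value must be positive")
    return np.asarray(values, dtype=float) / control_value


def yield_penalty_percent(treated: float, control: float) -> float:
    """Percent yield loss of a treated run relative to its paired control."""
    if control <= 0:
        raise ValueError("control must be positive")
    return float(100.0 * (control - treated) / control)
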