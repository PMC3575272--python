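"""Trajectory-fit validation metrics.

Two scalar metrics compare an experimental (reference) channel with a
simulated one over a 3-s window starting at perturbation onset
(onset sample included), both series on the experimental 100-Hz grid:

* average error — mean of the absolute instantaneous difference
  (deg for sway channels, cm for COP channels);
* cross-correlation value — the zero-lag normalized coefficient
  sum(exp*sim) / sqrt(sum(exp^2) sum(sim^2)).  No mean subtraction (the
  signals are deviations from upright, so zero is meaningful) and no lag
  search by default; a max-over-lags variant is available behind a flag.

The module also ships the published validation table (15 cells per
metric block) and recomputes its block means.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MetricsResult", "average_error", "cross_correlation",
           "load_table1", "table1_summary", "window_slice"]


@dataclass(frozen=True)
class MetricsResult:
    """Both metrics for one channel over one window."""
    channel: str
    average_error: float
    cross_correlation: float
    window: float


def window_slice(t: np.ndarray, onset: float, window: float) -> np.ndarray:
    """Boolean mask for [onset, onset + window], onset inclusive."""
    return (t >= onset - 1e-9) & (t <= onset + window + 1e-9)


def _check_pair(exp, sim):
    exp = np.asarray(exp, float)
    sim = np.asarray(sim, float)
    if exp.shape != sim.shape or exp.ndim != 1:
        raise ValueError("series must be 1-D and equally sampled")
    return exp, sim


def average_error(exp, sim) -> float:
    """Mean absolute instantaneous difference over the (pre-windowed)
    series; units follow the channel (deg or cm)."""
    exp, sim = _check_pair(exp, sim)
    return float(np.mean(np.abs(exp - sim)))


def cross_correlation(exp, sim, max_lags: int = 0) -> float:
    """Normalized cross-correlation between two (pre-windowed) series.

    With ``max_lags`` = 0 (default) the zero-lag coefficient is
    returned; otherwise the maximum coefficient over integer lags up to
    ±``max_lags`` samples.
    """
    exp, sim = _check_pair(exp, sim)
    if not (np.any(exp) or np.any(sim)):
        raise ValueError("cross-correlation undefined for two zero series")

    def _cc(a, b):
        den = np.sqrt(np.sum(a * a) * np.sum(b * b))
        if den == 0:
            return 0.0
        return float(np.sum(a * b) / den)

    if max_lags == 0:
        return _cc(exp, sim)
    best = -np.inf
    n = len(exp)
    for lag in range(-max_lags, max_lags + 1):
        if lag >= 0:
            c = _cc(exp[lag:], sim[:n - lag])
        else:
            c = _cc(exp[:n + lag], sim[-lag:])
        best = max(best, c)
    return best


_TABLE_CELLS_PER_BLOCK = 15


def load_table1() -> pd.DataFrame:
    """The packaged published validation table (long format)."""
    ref = importlib.resources.files("posturefb") / "data/table1_validation.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


def table1_summary(table: pd.DataFrame | None = None) -> dict[str, float]:
    """Arithmetic mean of each metric block, rounded to the printed
    precision (two decimals)."""
    df = load_table1() if table is None else table
    out = {}
    for metric, grp in df.groupby("metric"):
        if len(grp) != _TABLE_CELLS_PER_BLOCK:
            raise ValueError(
                f"block {metric!r} has {len(grp)} cells, "
                f"expected {_TABLE_CELLS_PER_BLOCK}")
        out[str(metric) + "_mean"] = round(float(grp["value"].mean()), 2)
    return out
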