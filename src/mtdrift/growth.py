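"""Growth kinetics: maximum specific growth rate from OD curves and
CFU-based relative growth.

The maximum specific growth rate mu_max (per minute) is the steepest slope
of ln(OD) versus time over a sliding window of consecutive measurements
(default 50 points at 5-minute sampling).  No OD-linearisation correction
is applied, so mu_max from dense batch cultures can be biased low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GrowthCurve", "mu_max", "doubling_time", "cfu_fold_change"]


@dataclass
class GrowthCurve:
    """One well's OD550 time series; OD must be positive (ln transform)."""

    time_min: np.ndarray
    od: np.ndarray
    well_id: str = ""

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time_min.shape != self.od.shape or self.time_min.ndim != 1:
            raise ValueError("time_min and od must be 1-D arrays of equal length")
        if self.time_min.size >= 2 and not np.all(np.diff(self.time_min) > 0):
            raise ValueError("time_min must be strictly increasing")
        if self.od.size and self.od.min() <= 0:
            raise ValueError("OD values must be positive for the ln transform")

    def __len__(self) -> int:
        return int(self.od.size)


def _window_slopes(t: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """OLS slope of y vs t in every contiguous window of `window` points."""
    tw = np.lib.stride_tricks.sliding_window_view(t, window)
    yw = np.lib.stride_tricks.sliding_window_view(y, window)
    tc = tw - tw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    return (tc * yc).sum(axis=1) / (tc * tc).sum(axis=1)


def mu_max(curve: GrowthCurve, window: int = 50) -> float:
    """Maximum specific growth rate (per minute): the largest sliding-window
    OLS slope of ln(OD) against time.

    The window slides one point at a time; the result can be <= 0 for a
    non-growing culture.
    """
    if window < 2:
        raise ValueError("window must contain at least 2 points")
    if len(curve) < window:
        raise ValueError(
            f"curve has {len(curve)} points, fewer than the window size {window}"
        )
    return float(_window_slopes(curve.time_min, np.log(curve.od), window).max())


def doubling_time(mu: float) -> float:
    """Population doubling time ln(2)/mu in minutes, for mu > 0 per minute."""
    if mu <= 0:
        raise ValueError("doubling time is undefined for mu <= 0")
    return float(np.log(2.0) / mu)


def cfu_fold_change(cfu_t0: float, cfu_t20: float) -> float:
    """Fold change in colony-forming units between the start and end of a
    crossing experiment (typically 0 h and 20 h)."""
    if cfu_t0 <= 0:
        raise ValueError("initial CFU count must be positive")
    if cfu_t20 < 0:
        raise ValueError("final CFU count must be non-negative")
    return cfu_t20 / cfu_t0
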