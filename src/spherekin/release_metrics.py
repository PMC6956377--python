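"""Gravimetric formulas and descriptive release-profile statistics.

Mass loss and water uptake of the hydrogel core system are computed from the
initial, wet and dry sample weights:

    mass loss (%)    = (W0 - Wd) / W0 * 100
    water uptake (%) = (Ww - Wd) / Wd * 100

Release-profile descriptors operate on cumulative released *amounts*
(e.g. ng of protein) versus time: the burst fraction is the fraction of the
loaded dose released within an early window (default 24 h), and the phase
rate is the least-squares slope of cumulative amount over a user-chosen
phase window, reported per day.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GravimetricSample",
    "CumulativeAmountCurve",
    "mass_loss_percent",
    "water_uptake_percent",
    "burst_fraction",
    "phase_rate",
    "SECONDS_PER_DAY",
    "DEFAULT_BURST_WINDOW_S",
]

SECONDS_PER_DAY = 86_400.0
DEFAULT_BURST_WINDOW_S = 24 * 3600.0


class InsufficientDataError(ValueError):
    """Too few observations to compute the requested descriptor."""


@dataclass(frozen=True)
class GravimetricSample:
    """Weights of one incubated sample: initial (w0), wet (ww), dry (wd), mg."""

    w0: float
    ww: float
    wd: float
    time: float = 0.0  # seconds since start of incubation

    def __post_init__(self) -> None:
        if min(self.w0, self.ww, self.wd) <= 0:
            raise ValueError("all weights must be > 0")
        if self.ww < self.wd:
            raise ValueError("wet weight must be >= dry weight")


@dataclass
class CumulativeAmountCurve:
    """Cumulative released amount over time, with the loaded dose.

    Amounts and dose share one unit (typically ng); times are seconds.
    """

    times: np.ndarray
    amounts: np.ndarray
    dose: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amounts = np.asarray(self.amounts, dtype=float)
        if self.times.shape != self.amounts.shape or self.times.ndim != 1:
            raise ValueError("times and amounts must be 1-D and equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.amounts < 0):
            raise ValueError("amounts must be non-negative")
        if self.dose <= 0:
            raise ValueError("dose must be > 0")


def mass_loss_percent(sample: GravimetricSample) -> float:
    """Percent mass lost since the start: (W0 - Wd) / W0 * 100.

    A dry weight exceeding the initial weight (possible with residual salts
    or weighing error) yields a negative loss, returned as-is with a warning
    rather than clipped.
    """
    loss = (sample.w0 - sample.wd) / sample.w0 * 100.0
    if loss < 0:
        warnings.warn(
            f"negative mass loss ({loss:.2f}%): dry weight exceeds initial weight",
            stacklevel=2,
        )
    return loss


def water_uptake_percent(sample: GravimetricSample) -> float:
    """Percent water uptake relative to the dry sample: (Ww - Wd) / Wd * 100."""
    return (sample.ww - sample.wd) / sample.wd * 100.0


def burst_fraction(
    curve: CumulativeAmountCurve, window: float = DEFAULT_BURST_WINDOW_S
) -> float:
    """Fraction of the loaded dose released within ``window`` seconds.

    The cumulative amount at the window boundary is linearly interpolated
    between the bracketing observations (exact when the boundary coincides
    with an observation).  The release is assumed zero at t = 0 unless an
    observation at t = 0 says otherwise.
    """
    if curve.times[0] > window:
        raise InsufficientDataError(
            f"burst window ({window:g} s) ends before the first observation "
            f"({curve.times[0]:g} s)"
        )
    t = curve.times
    a = curve.amounts
    if t[0] > 0:  # anchor at the origin for interpolation inside [0, t0]
        t = np.concatenate(([0.0], t))
        a = np.concatenate(([0.0], a))
    amount = float(np.interp(window, t, a))
    return amount / curve.dose


def phase_rate(
    curve: CumulativeAmountCurve, t_start: float, t_end: float
) -> float:
    """Least-squares release rate over [t_start, t_end], in amount units/day.

    Fits a straight line to cumulative amount vs time over the observations
    falling in the window and returns its slope converted from per-second to
    per-day.  Requires at least two observations in the window.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    mask = (curve.times >= t_start) & (curve.times <= t_end)
    if int(mask.sum()) < 2:
        raise InsufficientDataError(
            f"need >= 2 observations in [{t_start:g}, {t_end:g}] s, "
            f"found {int(mask.sum())}"
        )
    slope_per_s = np.polyfit(curve.times[mask], curve.amounts[mask], 1)[0]
    return float(slope_per_s * SECONDS_PER_DAY)
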