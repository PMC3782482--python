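"""Behavioral metrics derived from the 1-Hz chain-index time series.

The per-frame chain index is reported three ways: smoothed (non-overlapping
10-frame block means) for plotting; accumulated over named 60-s (or 150-s)
phase windows; and normalized into a per-fly chain probability, whose
arcsine-square-root ("angular") transform linearizes proportions near the
boundaries before rate computation.  Suppression, recovery and drop rates
are all the relative change ``(AC2 - AC1) / AC1`` between the angular
transforms of a pair of phase windows:

* suppression — playback onset of the continuous pulse song (5'11"-6'10")
  vs. the end of its first playback (23'51"-24'50");
* recovery — the minute before vs. after the shift from continuous to
  intermittent song at 25 min;
* drop — the minute before vs. after the shift back to continuous at 40 min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChainSeries",
    "PhaseWindow",
    "RateResult",
    "smooth_series",
    "cumulative_index",
    "chain_probability",
    "angular_transform",
    "rate_of_change",
    "protocol_windows",
    "suppression_recovery_drop",
]


class DomainError(ValueError):
    """Window falls outside the recorded series."""


class UndefinedRateError(ZeroDivisionError):
    """Rate of change is undefined because the baseline transform is zero."""


class DataIntegrityError(ValueError):
    """A probability left [0, 1]: the inputs are inconsistent."""


@dataclass
class ChainSeries:
    """Chain index per frame at 1 Hz.

    ``t0_playback`` is the second at which sound playback starts (the
    standard assay plays 5 min of silence first, so 300 s).
    """

    values: np.ndarray
    fps: float = 1.0
    t0_playback: float = 300.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("chain indices are non-negative")

    @property
    def duration(self) -> float:
        return len(self.values) / self.fps

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PhaseWindow:
    """Named half-open analysis window [start, end) in seconds."""

    name: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class RateResult:
    """Angular transforms of a window pair and their relative change."""

    AC1: float
    AC2: float
    rate: float


def smooth_series(s: ChainSeries, window: int = 10) -> np.ndarray:
    """Non-overlapping block means of ``window`` frames.

    The final partial block, if any, is averaged over the frames it actually
    contains.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    v = s.values
    n_full = len(v) // window
    out = []
    if n_full:
        out.extend(v[: n_full * window].reshape(n_full, window).mean(axis=1))
    if len(v) % window:
        out.append(v[n_full * window :].mean())
    return np.asarray(out)


def cumulative_index(s: ChainSeries, w: PhaseWindow) -> float:
    """Sum of per-frame chain indices over [start, end)."""
    i0 = int(round(w.start * s.fps))
    i1 = int(round(w.end * s.fps))
    if i0 < 0 or i1 > len(s.values) or i0 >= i1:
        raise DomainError(
            f"window [{w.start}, {w.end}) s outside series of {s.duration} s"
        )
    return float(s.values[i0:i1].sum())


def chain_probability(
    cum: float, n_flies: int, window_s: float, fps: float = 1.0
) -> float:
    """Mean probability that a fly is in a chain during a window.

    The cumulative chain index is normalized per fly and divided by the
    window's frame count (the per-fly maximum: 150 for a 2.5-min window at
    1 fps).  Result is in [0, 1].
    """
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    if window_s <= 0 or fps <= 0:
        raise ValueError("window_s and fps must be positive")
    p = cum / (n_flies * window_s * fps)
    if p < 0 or p > 1 + 1e-12:
        raise DataIntegrityError(
            f"chain probability {p:.3f} outside [0, 1]; inputs inconsistent"
        )
    return min(p, 1.0)


def angular_transform(p: float) -> float:
    """Arcsine-square-root transform of a proportion, in radians."""
    if not 0 <= p <= 1:
        raise ValueError("proportion must be in [0, 1]")
    return math.asin(math.sqrt(p))


def rate_of_change(AC1: float, AC2: float) -> RateResult:
    """Relative change (AC2 - AC1)/AC1 between two angular transforms."""
    if AC1 == 0:
        raise UndefinedRateError("rate undefined when the baseline AC1 is zero")
    return RateResult(AC1=AC1, AC2=AC2, rate=(AC2 - AC1) / AC1)


# Protocol timeline (seconds): silence 0-300, continuous pulse song from 300,
# shift to intermittent at 1500 (25 min), back to continuous at 2400 (40 min).
_SHIFT_INTERMITTENT = 25 * 60
_SHIFT_CONTINUOUS = 40 * 60
# printed suppression windows: 5'11"-6'10" and 23'51"-24'50", read as 60-s
# half-open intervals
_SUPPRESS_1 = 5 * 60 + 11
_SUPPRESS_2 = 23 * 60 + 51


def protocol_windows(protocol: str) -> list[PhaseWindow]:
    """Phase windows of the named assay protocol.

    ``suppression`` / ``recovery`` / ``drop`` return the window *pair* used
    for the corresponding rate; ``three-phase`` returns the silent /
    immediate / later trio of the 12-min assay; ``five-phase`` returns the
    five 1-min phases of the plasticity protocol in temporal order.
    """
    s1 = PhaseWindow("I", _SUPPRESS_1, _SUPPRESS_1 + 60)
    s2 = PhaseWindow("II", _SUPPRESS_2, _SUPPRESS_2 + 60)
    r1 = PhaseWindow("pre-shift-25min", _SHIFT_INTERMITTENT - 60, _SHIFT_INTERMITTENT)
    r2 = PhaseWindow("post-shift-25min", _SHIFT_INTERMITTENT, _SHIFT_INTERMITTENT + 60)
    d1 = PhaseWindow("pre-shift-40min", _SHIFT_CONTINUOUS - 60, _SHIFT_CONTINUOUS)
    d2 = PhaseWindow("post-shift-40min", _SHIFT_CONTINUOUS, _SHIFT_CONTINUOUS + 60)
    if protocol == "suppression":
        return [s1, s2]
    if protocol == "recovery":
        return [r1, r2]
    if protocol == "drop":
        return [d1, d2]
    if protocol == "three-phase":
        return [
            PhaseWindow("silent", 240, 300),
            PhaseWindow("immediate", _SUPPRESS_1, _SUPPRESS_1 + 60),
            PhaseWindow("later", 660, 720),
        ]
    if protocol == "five-phase":
        return [
            PhaseWindow("I", s1.start, s1.end),
            PhaseWindow("II", s2.start, s2.end),
            PhaseWindow("III", r2.start, r2.end),
            PhaseWindow("IV", d1.start, d1.end),
            PhaseWindow("V", d2.start, d2.end),
        ]
    raise ValueError(f"unknown protocol {protocol!r}")


def _window_rate(s: ChainSeries, pair: list[PhaseWindow], n_flies: int) -> RateResult:
    acs = []
    for w in pair:
        cum = cumulative_index(s, w)
        p = chain_probability(cum, n_flies, w.length, s.fps)
        acs.append(angular_transform(p))
    return rate_of_change(acs[0], acs[1])


def suppression_recovery_drop(
    s: ChainSeries, n_flies: int = 6
) -> dict[str, RateResult]:
    """All three plasticity rates of the standard protocol on one series."""
    return {
        name: _window_rate(s, protocol_windows(name), n_flies)
        for name in ("suppression", "recovery", "drop")
    }
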