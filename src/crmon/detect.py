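"""Triage-zone classification and early-decompensation detectors.

The fuel-gauge display bands the reserve percentage into green (>70), yellow
(40–69) and red (<40) zones; the boundary values 70 and 40 are assigned to
yellow (the published bands leave them unallocated — both are the
conservative choice and configurable).

Three detector families flag impending decompensation on the 1 Hz smoothed
reserve stream:

* threshold gates — flag once at least 45 of the most recent 60 predictions
  fall strictly below a zone boundary (yellow gate at 70, red gate at 40);
* slope trend — flag once an ordinary-least-squares line through the most
  recent 5 min of values projects a decline of at least 15 percent-units
  over the window.  The same rule is applied to MAP (falling) and HR
  (rising), each first rescaled to percent of its baseline-period mean.

Flags raised outside the chamber-active interval (baseline or post-release
recovery) are discarded; the first surviving flag defines the detection time
and its early-warning margin before the decompensation endpoint.  A method
that never validly flags scores a 0-min margin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ContractError, ParameterError
from .protocol import LBNPProtocol

Zone = Literal["green", "yellow", "red"]
ZONE_LABELS: tuple[Zone, ...] = ("green", "yellow", "red")


@dataclass(frozen=True)
class ZoneConfig:
    """Fuel-gauge band boundaries in reserve percent."""

    green_floor: float = 70.0
    red_ceiling: float = 40.0

    def __post_init__(self) -> None:
        if not 0 < self.red_ceiling < self.green_floor < 100:
            raise ParameterError("require 0 < red_ceiling < green_floor < 100")


@dataclass(frozen=True)
class GateConfig:
    """Threshold-gate detector: >= ``required_crossings`` of the last
    ``window_predictions`` 1 Hz values strictly below ``threshold``."""

    threshold: float
    window_predictions: int = 60
    required_crossings: int = 45

    def __post_init__(self) -> None:
        if not 0 < self.required_crossings <= self.window_predictions:
            raise ParameterError("require 0 < required_crossings <= window_predictions")


@dataclass(frozen=True)
class TrendConfig:
    """Slope-trend detector: OLS line over the trailing ``window_seconds``
    projecting a change of at least ``decline_threshold`` percent-units."""

    window_seconds: float = 300.0
    decline_threshold: float = 15.0
    direction: Literal["falling", "rising"] = "falling"

    def __post_init__(self) -> None:
        if self.window_seconds <= 0 or self.decline_threshold <= 0:
            raise ParameterError("window_seconds and decline_threshold must be positive")


@dataclass
class DetectionEvent:
    """First valid flag of one detector and its early-warning margin."""

    method: str
    flagged: bool
    flag_time: float | None
    early_minutes: float


# -- zone classification ----------------------------------------------------

def classify_zone(crm: float, zones: ZoneConfig = ZoneConfig()) -> Zone:
    """Green above ``green_floor``, red below ``red_ceiling``, yellow otherwise
    (both boundary values inclusive in yellow)."""
    if not np.isfinite(crm) or not 0 <= crm <= 100:
        raise ContractError(f"reserve value {crm!r} outside [0, 100]")
    if crm > zones.green_floor:
        return "green"
    if crm < zones.red_ceiling:
        return "red"
    return "yellow"


def zone_codes(values: np.ndarray, zones: ZoneConfig = ZoneConfig()) -> np.ndarray:
    """Vectorized zone indices (0 green, 1 yellow, 2 red); NaN maps to -1."""
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, 1, dtype=int)
    out[v > zones.green_floor] = 0
    out[v < zones.red_ceiling] = 2
    out[~np.isfinite(v)] = -1
    return out


# -- flag series ------------------------------------------------------------

def gate_flag_series(values: np.ndarray, gate: GateConfig) -> np.ndarray:
    """Boolean series: count of strictly-below-threshold predictions among the
    most recent ``min(window, available)`` ticks reaches ``required_crossings``.

    NaN (missing) ticks count as non-crossings but still occupy window slots.
    """
    v = np.asarray(values, dtype=float)
    below = (v < gate.threshold) & np.isfinite(v)
    counts = (pd.Series(below.astype(float))
              .rolling(gate.window_predictions, min_periods=1).sum().to_numpy())
    return counts >= gate.required_crossings


def trend_flag_series(times: np.ndarray, values: np.ndarray, trend: TrendConfig) -> np.ndarray:
    """Boolean series: OLS slope over the trailing window projects a change of
    at least ``decline_threshold`` in the configured direction.

    Evaluated only from the first full window onward; NaN values are dropped
    from each fit and a window with fewer than two distinct time points is
    skipped.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    n = len(t)
    out = np.zeros(n, dtype=bool)
    if n < 2:
        return out
    w = trend.window_seconds
    dt = t[1] - t[0]
    sign = -1.0 if trend.direction == "falling" else 1.0
    for i in range(n):
        if t[i] - t[0] < w - dt - 1e-9:
            continue  # series does not yet cover one full window
        j0 = int(np.searchsorted(t, t[i] - w, side="right"))
        tw, vw = t[j0:i + 1], v[j0:i + 1]
        good = np.isfinite(vw)
        if good.sum() < 2 or np.ptp(tw[good]) == 0:
            continue
        tg, vg = tw[good], vw[good]
        tc = tg - tg.mean()
        slope = float(np.dot(tc, vg - vg.mean()) / np.dot(tc, tc))
        # small tolerance so a ramp at exactly the threshold rate flags
        if sign * slope * w >= trend.decline_threshold - 1e-9:
            out[i] = True
    return out


def baseline_percent(times: np.ndarray, values: np.ndarray, baseline_end: float) -> np.ndarray:
    """Rescale a vital-sign series to percent of its baseline-period mean."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    base = v[(t < baseline_end) & np.isfinite(v)]
    if base.size == 0:
        raise ContractError("no baseline samples before baseline_end")
    return 100.0 * v / float(base.mean())


# -- scoring ----------------------------------------------------------------

def restrict_and_score(times: np.ndarray, flags: np.ndarray, protocol: LBNPProtocol,
                       method: str) -> DetectionEvent:
    """Discard flags outside the chamber-active interval and score the first one.

    ``early_minutes = (endpoint_time - flag_time) / 60``; a method with no
    surviving flag scores ``flagged = False`` and 0 min.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(flags, dtype=bool)
    lo, hi = protocol.chamber_interval
    in_interval = f & (t >= lo) & (t <= hi)
    idx = np.flatnonzero(in_interval)
    if idx.size == 0:
        return DetectionEvent(method=method, flagged=False, flag_time=None, early_minutes=0.0)
    flag_time = float(t[idx[0]])
    return DetectionEvent(method=method, flagged=True, flag_time=flag_time,
                          early_minutes=(protocol.endpoint_time - flag_time) / 60.0)


def gate_detector(times: np.ndarray, values: np.ndarray, gate: GateConfig,
                  protocol: LBNPProtocol, method: str = "gate") -> DetectionEvent:
    return restrict_and_score(times, gate_flag_series(values, gate), protocol, method)


def trend_detector(times: np.ndarray, values: np.ndarray, trend: TrendConfig,
                   protocol: LBNPProtocol, method: str = "trend") -> DetectionEvent:
    return restrict_and_score(times, trend_flag_series(times, values, trend), protocol, method)


# -- the standard five-method battery ---------------------------------------

def detect_all(crm_times: np.ndarray, crm_smoothed: np.ndarray,
               protocol: LBNPProtocol,
               vitals_times: np.ndarray | None = None,
               heart_rate: np.ndarray | None = None,
               mean_arterial_pressure: np.ndarray | None = None,
               zones: ZoneConfig = ZoneConfig(),
               gate_window: int = 60, gate_crossings: int = 45,
               trend: TrendConfig = TrendConfig()) -> list[DetectionEvent]:
    """Run the red/yellow gates and the CRM/MAP/HR trend detectors.

    MAP and HR trends are evaluated on percent-of-baseline-mean series, MAP
    falling and HR rising (heart rate climbs as hypovolemia progresses).
    """
    events = [
        gate_detector(crm_times, crm_smoothed,
                      GateConfig(zones.red_ceiling, gate_window, gate_crossings),
                      protocol, "red_gate"),
        gate_detector(crm_times, crm_smoothed,
                      GateConfig(zones.green_floor, gate_window, gate_crossings),
                      protocol, "yellow_gate"),
        trend_detector(crm_times, crm_smoothed, trend, protocol, "trend_crm"),
    ]
    if vitals_times is not None and mean_arterial_pressure is not None:
        map_pct = baseline_percent(vitals_times, mean_arterial_pressure,
                                   protocol.baseline_duration)
        events.append(trend_detector(vitals_times, map_pct, trend, protocol, "trend_map"))
    if vitals_times is not None and heart_rate is not None:
        hr_pct = baseline_percent(vitals_times, heart_rate, protocol.baseline_duration)
        rising = TrendConfig(trend.window_seconds, trend.decline_threshold, "rising")
        events.append(trend_detector(vitals_times, hr_pct, rising, protocol, "trend_hr"))
    return events
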