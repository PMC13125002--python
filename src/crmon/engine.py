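"""Reserve estimation engine: window normalization, prediction, causal smoothing.

Each 5-s / 500-sample window is min–max normalized to [0, 1]

    x' = (x_i - min(x)) / (max(x) - min(x)),

fed to a pluggable predictor that returns a reserve percentage in [0, 100],
and the resulting 1 Hz raw stream is stabilized with a causal trailing mean
over the 20 most recent emitted predictions (no output until 20 have
accumulated).  The trained convolutional network that produced the published
reserve estimates is proprietary; the :class:`SurrogatePredictor` here is a
documented, deterministic stand-in exposing the same interface so real
weights could be dropped in later, and :class:`OraclePredictor` returns the
protocol-derived reserve for plumbing and recovery tests.

Missing ticks (flat windows, undetectable beats) are represented as NaN —
explicitly distinct from 0, which is a meaningful reserve value — and do not
count toward the smoothing window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterator, Protocol, runtime_checkable

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ContractError
from .ingest import StreamWindowSpec, WaveformRecord, stream_windows_causal

log = logging.getLogger(__name__)

SMOOTH_WINDOW = 20  # trailing predictions per smoothed estimate (min periods = 20)


@dataclass
class NormalizedWindow:
    """One inference window scaled to [0, 1], labelled by its end time."""

    values: np.ndarray
    end_time: float
    valid: bool


@dataclass
class CRMSeries:
    """1 Hz raw and causally smoothed reserve estimates on the 0–100% scale.

    ``smoothed`` is NaN until 20 raw predictions have accumulated; raw NaNs
    mark ticks where no prediction could be made.
    """

    times: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        for arr in (self.raw, self.smoothed):
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 100):
                raise ContractError("reserve estimates must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "crm_raw": self.raw,
                             "crm_smoothed": self.smoothed})

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def read_crm_csv(path: str | Path, source_label: str = "") -> CRMSeries:
    frame = pd.read_csv(path)
    return CRMSeries(times=frame["time_s"].to_numpy(float),
                     raw=frame["crm_raw"].to_numpy(float),
                     smoothed=frame["crm_smoothed"].to_numpy(float),
                     source_label=source_label)


# -- normalization ----------------------------------------------------------

def minmax_normalize(window: np.ndarray, end_time: float,
                     expected_length: int = 500) -> NormalizedWindow:
    """Min–max normalize one raw window to [0, 1].

    A flat window (max = min) yields ``valid = False`` — no prediction is
    emitted for that tick rather than fabricating one.
    """
    window = np.asarray(window, dtype=float)
    if window.size != expected_length:
        raise ContractError(f"window must hold {expected_length} samples, got {window.size}")
    if not np.all(np.isfinite(window)):
        raise ContractError("window contains non-finite samples")
    lo, hi = window.min(), window.max()
    if hi <= lo:
        return NormalizedWindow(values=np.zeros_like(window), end_time=end_time, valid=False)
    return NormalizedWindow(values=(window - lo) / (hi - lo), end_time=end_time, valid=True)


# -- predictors -------------------------------------------------------------

@runtime_checkable
class PredictorInterface(Protocol):
    """Mapping from one normalized window (plus its raw samples) to reserve percent.

    ``predict`` returns a float in [0, 100], or NaN when no estimate can be
    made for the tick.  Implementations must be deterministic for a fixed
    input and internal state.
    """

    identifier: str

    def predict(self, window: NormalizedWindow, raw: np.ndarray) -> float: ...


@dataclass(frozen=True)
class SurrogateConfig:
    """Calibration of the morphology-based surrogate to the simulator defaults.

    ``amp_lo``/``amp_hi`` span the pulse amplitude from endpoint to baseline
    morphology and ``rate_lo``/``rate_hi`` the heart rate from baseline to
    endpoint, so baseline windows map to ~100% and endpoint windows to ~0%.
    """

    amp_lo: float = 0.2
    amp_hi: float = 1.0
    rate_lo: float = 65.0
    rate_hi: float = 100.0
    amp_weight: float = 0.7
    refractory_s: float = 0.3       # minimum beat separation for peak detection
    prominence_frac: float = 0.45   # peak prominence as a fraction of window range
                                    # (systolic ~1.0 of span, dicrotic ~0.2: rejects dicrotic)


class SurrogatePredictor:
    """Deterministic beat-morphology reserve estimate.

    Detects systolic peaks in the pre-normalization window (local maxima with
    a 0.3-s refractory period), measures the mean peak-to-trough pulse
    amplitude and the beat rate, maps each through a fixed affine ramp
    between its calibrated baseline and endpoint values, and combines them
    (amplitude-weighted) into a reserve percentage clipped to [0, 100].
    Windows with fewer than two detectable beats yield NaN.
    """

    def __init__(self, config: SurrogateConfig = SurrogateConfig(),
                 model_rate: float = 100.0) -> None:
        self.config = config
        self.model_rate = model_rate
        self.identifier = "surrogate"

    def beat_features(self, raw: np.ndarray) -> tuple[float, float] | None:
        """(mean peak-to-trough amplitude, beat rate in bpm) or None."""
        raw = np.asarray(raw, dtype=float)
        span = float(np.ptp(raw))
        if span <= 0:
            return None
        distance = max(1, int(round(self.config.refractory_s * self.model_rate)))
        peaks, _ = find_peaks(raw, distance=distance,
                              prominence=self.config.prominence_frac * span)
        if len(peaks) < 2:
            return None
        p2p = [raw[b] - raw[a:b].min() for a, b in zip(peaks[:-1], peaks[1:])]
        rate = 60.0 * self.model_rate / float(np.median(np.diff(peaks)))
        return float(np.mean(p2p)), rate

    def predict(self, window: NormalizedWindow, raw: np.ndarray) -> float:
        feats = self.beat_features(raw)
        if feats is None:
            return float("nan")
        amp, rate = feats
        c = self.config
        rev_amp = (amp - c.amp_lo) / (c.amp_hi - c.amp_lo)
        rev_rate = (c.rate_hi - rate) / (c.rate_hi - c.rate_lo)
        mix = c.amp_weight * rev_amp + (1.0 - c.amp_weight) * rev_rate
        return float(np.clip(100.0 * mix, 0.0, 100.0))


class OraclePredictor:
    """Returns the protocol-derived reserve at the window's end time.

    Used to test plumbing (the pipeline must reproduce the reserve staircase
    exactly) and evaluation parameter recovery; it sidesteps the waveform
    entirely.
    """

    def __init__(self, reserve_fn: Callable[[float], float]) -> None:
        self.reserve_fn = reserve_fn
        self.identifier = "oracle"

    def predict(self, window: NormalizedWindow, raw: np.ndarray) -> float:
        return float(np.clip(100.0 * float(np.asarray(self.reserve_fn(window.end_time)).ravel()[0]),
                             0.0, 100.0))


# -- smoothing --------------------------------------------------------------

def smooth_causal(raw: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Causal trailing mean over the ``window`` most recent emitted predictions.

    NaN raw ticks are skipped entirely: they neither produce a smoothed value
    nor count toward the warm-up, so the first smoothed estimate appears at
    the ``window``-th emitted prediction.
    """
    raw = np.asarray(raw, dtype=float)
    out = np.full(raw.shape, np.nan)
    valid: list[float] = []
    for i, v in enumerate(raw):
        if not np.isfinite(v):
            continue
        valid.append(float(v))
        if len(valid) >= window:
            out[i] = float(np.mean(valid[-window:]))
    return out


# -- pipeline ---------------------------------------------------------------

def stream_pipeline(record: WaveformRecord, predictor: PredictorInterface,
                    spec: StreamWindowSpec = StreamWindowSpec(),
                    smooth_window: int = SMOOTH_WINDOW,
                    ) -> Iterator[tuple[float, float, float]]:
    """Incremental (streaming) pipeline yielding ``(end_time, raw, smoothed)`` per tick.

    Each tick uses only the current and preceding samples; the smoothed value
    is the trailing mean over the most recent ``smooth_window`` emitted
    predictions, NaN until enough have accumulated.
    """
    valid: list[float] = []
    for end_time, window in stream_windows_causal(record, spec):
        norm = minmax_normalize(window, end_time, spec.window_samples)
        raw_pred = predictor.predict(norm, window) if norm.valid else float("nan")
        smoothed = float("nan")
        if np.isfinite(raw_pred):
            valid.append(float(raw_pred))
            if len(valid) >= smooth_window:
                smoothed = float(np.mean(valid[-smooth_window:]))
        else:
            log.debug("no prediction for window ending at %.1f s", end_time)
        yield end_time, raw_pred, smoothed


def run_pipeline(record: WaveformRecord, predictor: PredictorInterface,
                 spec: StreamWindowSpec = StreamWindowSpec(),
                 smooth_window: int = SMOOTH_WINDOW) -> CRMSeries:
    """Batch (whole-record) pipeline; numerically identical to streaming.

    Collects every causal window, normalizes and predicts per window, then
    applies :func:`smooth_causal` to the assembled raw series.
    """
    times: list[float] = []
    raw: list[float] = []
    for end_time, window in stream_windows_causal(record, spec):
        norm = minmax_normalize(window, end_time, spec.window_samples)
        times.append(end_time)
        raw.append(predictor.predict(norm, window) if norm.valid else float("nan"))
    raw_arr = np.asarray(raw, dtype=float)
    if raw_arr.size and not np.any(np.isfinite(raw_arr)):
        log.warning("all %d windows were invalid; returning an empty series", raw_arr.size)
        return CRMSeries(times=np.empty(0), raw=np.empty(0), smoothed=np.empty(0),
                         source_label=predictor.identifier)
    smoothed = smooth_causal(raw_arr, smooth_window)
    return CRMSeries(times=np.asarray(times), raw=raw_arr, smoothed=smoothed,
                     source_label=predictor.identifier)
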