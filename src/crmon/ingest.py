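"""PPG waveform I/O, rate conversion, and causal window streaming.

The downstream reserve model consumes 5-s windows of 500 samples at 100 Hz
with a 1-s stride.  Input recordings arrive at other rates — 31.25 Hz CSV
exports from the portable pulse oximeter, 1,000 Hz captures from the bedside
patient monitor — so this module owns the conversion to the model-rate
contract:

* portable (31.25 Hz): Fourier-method resampling.  In the causal streaming
  path the trailing 7 s of raw samples are resampled per 1-s tick and trimmed
  to the final 5 s, which bounds per-tick cost and suppresses the periodic-
  extension edge artifact of FFT resampling.
* monitor (1,000 Hz): every-10th-sample decimation, which is causal as-is.

Windows are labelled by their end time; window ``t`` covers the half-open
interval ``(t - 5, t]`` and never references a sample after ``t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.signal import resample as _fourier_resample

from .errors import ContractError, DialectError, EmptyRecordError, FormatError, ParameterError

#: nominal CSV sampling rates per source dialect (Hz); ``simulated`` accepts any rate
DIALECT_RATES: dict[str, float | None] = {"portable": 31.25, "monitor": 1000.0, "simulated": None}

RATE_TOLERANCE = 0.01  # relative tolerance when validating inferred vs nominal rate


@dataclass
class WaveformRecord:
    """Uniformly sampled PPG amplitude series.

    ``gaps`` lists intervals (in record-time seconds) where the source
    timestamps jumped by more than two sample periods; windows overlapping a
    gap are skipped rather than interpolated.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    source_label: str = "simulated"
    gaps: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise FormatError("waveform contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record span in seconds (n / rate)."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class StreamWindowSpec:
    """Fixed-length inference window contract: 5 s / 500 samples at 100 Hz, 1-s stride."""

    window_seconds: float = 5.0
    stride_seconds: float = 1.0
    model_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.stride_seconds <= 0 or self.window_seconds <= 0 or self.model_rate <= 0:
            raise ParameterError("window, stride and model rate must be positive")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_seconds * self.model_rate))

    @property
    def stride_samples(self) -> int:
        return int(round(self.stride_seconds * self.model_rate))


# -- CSV I/O ----------------------------------------------------------------

def read_ppg_csv(path: str | Path, dialect: str = "simulated") -> WaveformRecord:
    """Read a ``time_s,ppg`` CSV and validate it against the dialect's rate.

    The sampling rate is inferred from the median timestamp step and checked
    against the dialect's nominal rate within 1% (timestamps in exported
    files carry rounding).  Timestamp jumps larger than two sample periods
    are recorded as gaps.
    """
    if dialect not in DIALECT_RATES:
        raise DialectError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECT_RATES)}")
    frame = pd.read_csv(path)
    if list(frame.columns[:2]) != ["time_s", "ppg"]:
        raise FormatError(f"{path}: expected header 'time_s,ppg', got {list(frame.columns)}")
    if len(frame) == 0:
        raise EmptyRecordError(f"{path}: no samples")
    t = frame["time_s"].to_numpy(dtype=float)
    x = frame["ppg"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(frame) < 2:
        raise EmptyRecordError(f"{path}: need at least two samples to infer a rate")
    if np.any(dt <= 0):
        raise FormatError(f"{path}: timestamps are not strictly increasing")
    period = float(np.median(dt))
    rate = 1.0 / period
    nominal = DIALECT_RATES[dialect]
    if nominal is not None:
        if abs(rate - nominal) / nominal > RATE_TOLERANCE:
            raise DialectError(
                f"{path}: inferred rate {rate:.4g} Hz deviates >1% from the "
                f"{dialect} dialect's nominal {nominal} Hz"
            )
        rate = nominal
    gaps = []
    for i in np.flatnonzero(dt > 2.0 * period):
        # map the gap onto the uniform index-time axis of the returned record
        gaps.append((float(t[0] + i / rate), float(t[0] + (i + 1) / rate)))
    return WaveformRecord(samples=x, sampling_rate=rate, start_time=float(t[0]),
                          source_label=dialect, gaps=gaps)


def write_ppg_csv(record: WaveformRecord, path: str | Path) -> None:
    frame = pd.DataFrame({"time_s": record.times, "ppg": record.samples})
    frame.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


# -- rate conversion --------------------------------------------------------

def resample_fourier(record: WaveformRecord, target_rate: float) -> WaveformRecord:
    """Resample the whole record to ``target_rate`` with the Fourier method.

    Output length is ``round(n * target_rate / rate)``.  This is the
    retrospective (whole-file) conversion path; the causal streaming path
    resamples per-tick chunks instead (see :func:`stream_windows_causal`).
    """
    if target_rate <= 0:
        raise ParameterError("target_rate must be positive")
    if len(record) == 0:
        raise EmptyRecordError("cannot resample an empty record")
    n_out = int(round(len(record) * target_rate / record.sampling_rate))
    y = _fourier_resample(record.samples, n_out)
    return WaveformRecord(samples=y, sampling_rate=target_rate,
                          start_time=record.start_time, source_label=record.source_label,
                          gaps=list(record.gaps))


def decimate_stride(record: WaveformRecord, stride: int) -> WaveformRecord:
    """Keep samples at indices 0, stride, 2*stride, ... (new rate = rate/stride)."""
    if int(stride) != stride or stride < 1:
        raise ParameterError("stride must be an integer >= 1")
    stride = int(stride)
    return WaveformRecord(samples=record.samples[::stride],
                          sampling_rate=record.sampling_rate / stride,
                          start_time=record.start_time, source_label=record.source_label,
                          gaps=list(record.gaps))


# -- causal window streaming ------------------------------------------------

def _overlaps_gap(record: WaveformRecord, win_start: float, win_end: float) -> bool:
    return any(win_start < hi and win_end > lo for lo, hi in record.gaps)


def stream_windows(record: WaveformRecord,
                   spec: StreamWindowSpec = StreamWindowSpec()) -> Iterator[tuple[float, np.ndarray]]:
    """Yield ``(end_time, window)`` pairs from a record already at model rate.

    The first window ends ``window_seconds`` after record start and subsequent
    windows advance by ``stride_seconds``; each holds exactly
    ``window_samples`` of the most recent data.  A record shorter than one
    window yields nothing.
    """
    if abs(record.sampling_rate - spec.model_rate) / spec.model_rate > RATE_TOLERANCE:
        raise ContractError(
            f"record rate {record.sampling_rate} Hz is not the model rate {spec.model_rate} Hz"
        )
    w, s = spec.window_samples, spec.stride_samples
    for k in range(w, len(record) + 1, s):
        end_time = record.start_time + k / spec.model_rate
        if _overlaps_gap(record, end_time - spec.window_seconds, end_time):
            continue
        yield end_time, record.samples[k - w:k]


def stream_windows_causal(record: WaveformRecord,
                          spec: StreamWindowSpec = StreamWindowSpec(),
                          chunk_seconds: float = 7.0) -> Iterator[tuple[float, np.ndarray]]:
    """Causal model-rate window stream from a record at an arbitrary rate.

    Dispatch: already at model rate -> direct slicing; an integer multiple of
    the model rate -> every-Nth-sample decimation; otherwise per-tick Fourier
    resampling of the trailing ``chunk_seconds`` of raw samples, trimmed to
    the final window.  Every path uses only samples at or before each
    window's end time.
    """
    rate = record.sampling_rate
    if abs(rate - spec.model_rate) / spec.model_rate <= RATE_TOLERANCE:
        yield from stream_windows(record, spec)
        return
    ratio = rate / spec.model_rate
    if ratio > 1 and abs(ratio - round(ratio)) < 1e-9:
        yield from stream_windows(decimate_stride(record, int(round(ratio))), spec)
        return
    if chunk_seconds < spec.window_seconds:
        raise ParameterError("chunk_seconds must cover at least one window")
    w = spec.window_samples
    chunk_raw = math.ceil(chunk_seconds * rate)
    pad_raw = max(2, math.ceil(1.0 * rate))  # 1-s even-reflection tail pad
    duration = record.duration
    n_ticks = int(math.floor((duration - spec.window_seconds) / spec.stride_seconds + 1e-9)) + 1
    for i in range(max(0, n_ticks)):
        t_rel = spec.window_seconds + i * spec.stride_seconds
        end_time = record.start_time + t_rel
        # samples with time <= end_time: indices 0 .. floor(t_rel*rate)
        n_avail = min(int(math.floor(t_rel * rate + 1e-9)) + 1, len(record))
        chunk = record.samples[max(0, n_avail - chunk_raw):n_avail]
        n_out = int(round(len(chunk) * spec.model_rate / rate))
        if n_out >= w and not _overlaps_gap(record, end_time - spec.window_seconds, end_time):
            # reflect the tail so the FFT's periodic extension sees no jump at
            # the window end (uses only past samples, so still causal)
            pad = min(pad_raw, len(chunk) - 1)
            padded = np.concatenate([chunk, chunk[-2:-2 - pad:-1]])
            m_out = int(round(len(padded) * spec.model_rate / rate))
            resampled = _fourier_resample(padded, m_out)
            keep = int(round(len(chunk) * spec.model_rate / rate))
            window = resampled[:keep][-w:]
            yield end_time, window
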