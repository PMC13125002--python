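"""Live text-mode patient monitor.

Renders, once per prediction tick, the four display elements of the
monitoring application: a recent-waveform sparkline, a vitals panel, the
instantaneous smoothed reserve as a zone-colored fuel gauge, and a session
trend line.  ANSI color is used only when writing to a terminal, so captured
output stays plain text.  The session CSV written at shutdown is identical
to the batch prediction output for the same input and configuration.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np

from .detect import ZoneConfig, classify_zone
from .engine import CRMSeries, PredictorInterface, stream_pipeline
from .ingest import StreamWindowSpec, WaveformRecord
from .simulate import VitalsSeries

_SPARK = "▁▂▃▄▅▆▇█"
_ZONE_COLOR = {"green": "\x1b[32m", "yellow": "\x1b[33m", "red": "\x1b[31m"}
_RESET = "\x1b[0m"


def sparkline(values: np.ndarray, width: int = 40) -> str:
    """Downsample a series to ``width`` block characters."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return " " * width
    if v.size > width:
        edges = np.linspace(0, v.size, width + 1).astype(int)
        v = np.array([v[a:b].mean() if b > a else v[min(a, v.size - 1)]
                      for a, b in zip(edges[:-1], edges[1:])])
    lo, hi = v.min(), v.max()
    scaled = np.zeros_like(v) if hi <= lo else (v - lo) / (hi - lo)
    chars = "".join(_SPARK[int(round(s * (len(_SPARK) - 1)))] for s in scaled)
    return chars.ljust(width)


def fuel_gauge(crm: float, zones: ZoneConfig, width: int = 25, color: bool = False) -> str:
    """Zone-labelled gauge bar for one smoothed reserve value."""
    if not np.isfinite(crm):
        return "[" + "-" * width + "]  --%  (warming up)"
    filled = int(round(crm / 100.0 * width))
    zone = classify_zone(float(np.clip(crm, 0, 100)), zones)
    bar = "#" * filled + "-" * (width - filled)
    label = f"{crm:5.1f}%  {zone.upper()}"
    if color:
        label = _ZONE_COLOR[zone] + label + _RESET
    return f"[{bar}] {label}"


@dataclass
class MonitorSummary:
    ticks: int
    last_crm: float
    series: CRMSeries


def run_monitor(record: WaveformRecord, predictor: PredictorInterface,
                vitals: VitalsSeries | None = None,
                spec: StreamWindowSpec = StreamWindowSpec(),
                zones: ZoneConfig = ZoneConfig(),
                out_csv: str | Path | None = None,
                stream: IO[str] | None = None,
                follow: bool = False) -> MonitorSummary:
    """Consume the causal pipeline tick by tick and render each frame.

    ``follow=True`` sleeps one stride between frames (real-time pacing);
    otherwise frames are emitted as fast as the source allows.  On source
    exhaustion a summary frame is printed and the session CSV (identical to
    the batch ``predict`` output) is written.
    """
    out = stream if stream is not None else sys.stdout
    color = hasattr(out, "isatty") and out.isatty()
    times: list[float] = []
    raw: list[float] = []
    smoothed: list[float] = []
    window_tail = int(spec.model_rate * spec.stride_seconds)
    for end_time, r, s in stream_pipeline(record, predictor, spec):
        times.append(end_time)
        raw.append(r)
        smoothed.append(s)
        k = int(round((end_time - record.start_time) * record.sampling_rate))
        wave = record.samples[max(0, k - 5 * int(record.sampling_rate)):k]
        lines = [f"t={end_time:7.1f}s", f"PPG   {sparkline(wave)}"]
        if vitals is not None:
            i = min(int(np.searchsorted(vitals.times, end_time)), len(vitals.times) - 1)
            lines.append(f"HR {vitals.heart_rate[i]:5.1f} bpm   "
                         f"MAP {vitals.mean_arterial_pressure[i]:5.1f} mmHg   "
                         f"SpO2 {vitals.spo2[i]:5.1f}%")
        lines.append(f"CRM   {fuel_gauge(s, zones, color=color)}")
        lines.append(f"trend {sparkline(np.asarray(smoothed))}")
        out.write("\n".join(lines) + "\n\n")
        if follow:
            time.sleep(spec.stride_seconds)
    series = CRMSeries(times=np.asarray(times), raw=np.asarray(raw),
                       smoothed=np.asarray(smoothed), source_label=predictor.identifier)
    finite = series.smoothed[np.isfinite(series.smoothed)]
    last = float(finite[-1]) if finite.size else float("nan")
    out.write(f"session ended: {len(series)} ticks, last CRM "
              f"{last:.1f}%\n" if np.isfinite(last) else
              f"session ended: {len(series)} ticks, no CRM emitted\n")
    if out_csv is not None:
        series.write_csv(out_csv)
    return MonitorSummary(ticks=len(series), last_crm=last, series=series)
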