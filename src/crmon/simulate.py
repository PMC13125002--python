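"""Synthetic LBNP hypovolemia subjects: PPG waveform, vitals, protocol, reserve.

Emulates the stepped lower-body negative pressure experiment used to develop
and evaluate compensatory-reserve monitors: a 5-min supine baseline, suction
stages of -15, -30, -45, -60, -70, -80, -90, -100 mmHg lasting 5 min each, an
inter-subject decompensation endpoint somewhere in the -60 to -100 mmHg
range, immediate release, and a 10-min recovery.

The generator is intentionally phenomenological (no hemodynamic ODEs, no
syncope physiology):

* a latent reserve fraction declines from 1 at rest to 0 at the endpoint;
  vitals and PPG morphology are monotone functions of a continuous
  (within-stage interpolated) version of it, with exponential relaxation back
  to baseline after chamber release;
* heart rate rises convexly with volume loss (late acceleration), pulse
  amplitude falls linearly, mean arterial pressure holds near baseline until
  the reserve drops below a knee and then declines toward a floor — the
  classic picture of compensated hemorrhage where pressure is the last vital
  to move;
* the PPG beat is a two-component template (systolic peak plus a smaller
  dicrotic wave) driven by a phase accumulator, so instantaneous beat rate
  follows the heart-rate series exactly; additive white noise on top.

One integer seed drives every stochastic draw through a single generator in a
fixed order (tolerance stage, endpoint placement, baseline HR, baseline MAP,
HR noise, MAP noise, SpO2 noise, PPG noise), so identical (config, seed)
reproduce a subject bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyRecordError
from .ingest import WaveformRecord, write_ppg_csv
from .protocol import (DEFAULT_STAGE_PRESSURES, LBNPProtocol, reserve_fraction,
                       save_protocol)

__all__ = [
    "SimulatorConfig", "VitalsSeries", "SubjectDataset",
    "beat_template", "synth_ppg_segment", "latent_reserve_trajectory",
    "simulate_subject", "export_subject", "read_vitals_csv",
]


@dataclass(frozen=True)
class SimulatorConfig:
    """Study conditions for one synthetic subject.

    Defaults mirror the stepped-LBNP experiment: 31.25 Hz portable-oximeter
    waveform export (1,000 Hz for the monitor dialect), 1 Hz vitals, and a
    tolerance distribution concentrated on the -60 to -80 mmHg stages so
    every subject reaches at least 60 mmHg before decompensating.
    """

    sampling_rate: float = 31.25            # PPG export rate, Hz
    vitals_rate: float = 1.0                # vitals rate, Hz
    baseline_duration: float = 300.0        # s
    stage_pressures: tuple[float, ...] = DEFAULT_STAGE_PRESSURES
    stage_duration: float = 300.0           # s
    recovery_duration: float = 600.0        # s
    #: probability of decompensating in each stage (indices follow stage_pressures)
    stage_tolerance_probs: tuple[float, ...] = (0.0, 0.0, 0.0, 0.25, 0.30, 0.25, 0.12, 0.08)
    hr_baseline_mean: float = 65.0          # bpm
    hr_baseline_sd: float = 3.0
    hr_rise_frac: float = 0.55              # fractional HR rise at zero reserve
    hr_shape: float = 2.0                   # convexity of HR vs volume loss
    amp_baseline: float = 1.0               # pulse amplitude at full reserve, a.u.
    amp_endpoint: float = 0.2               # pulse amplitude at zero reserve, a.u.
    map_baseline_mean: float = 90.0         # mmHg
    map_baseline_sd: float = 4.0
    map_floor: float = 58.0                 # mmHg at zero reserve (SBP<80 stop-criterion analog)
    map_knee: float = 0.3                   # reserve below which MAP starts declining
    spo2_baseline: float = 98.0             # percent
    spo2_drop: float = 3.0                  # percent drop at zero reserve
    ppg_noise_sd: float = 0.02              # additive white noise on the waveform, a.u.
    ppg_offset: float = 10.0                # raw-sensor DC offset, a.u.
    vital_noise_ar: float = 0.95            # AR(1) coefficient of vitals noise
    hr_noise_sd: float = 0.8                # marginal SD, bpm
    map_noise_sd: float = 1.0               # mmHg
    spo2_noise_sd: float = 0.15             # percent
    recovery_tau: float = 120.0             # s, relaxation back to baseline after release

    def validate(self) -> None:
        positive = ("sampling_rate", "vitals_rate", "baseline_duration", "stage_duration",
                    "recovery_duration", "hr_baseline_mean", "amp_baseline", "recovery_tau")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        probs = np.asarray(self.stage_tolerance_probs, dtype=float)
        if len(probs) != len(self.stage_pressures) or np.any(probs < 0) or probs.sum() <= 0:
            raise ConfigurationError("stage_tolerance_probs must be non-negative, one per stage")
        if not 0 <= self.amp_endpoint < self.amp_baseline:
            raise ConfigurationError("require 0 <= amp_endpoint < amp_baseline")


@dataclass
class VitalsSeries:
    """HR / MAP / SpO2 on a shared time axis (seconds from record start)."""

    times: np.ndarray
    heart_rate: np.ndarray
    mean_arterial_pressure: np.ndarray
    spo2: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.heart_rate) == len(self.mean_arterial_pressure) == len(self.spo2) == n):
            raise ConfigurationError("all vitals series must share the times axis")
        if np.any(self.heart_rate <= 0):
            raise ConfigurationError("heart_rate must be positive")
        if np.any((self.spo2 <= 0) | (self.spo2 > 100)):
            raise ConfigurationError("spo2 must lie in (0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times, "hr_bpm": self.heart_rate,
            "map_mmHg": self.mean_arterial_pressure, "spo2_pct": self.spo2,
        })


@dataclass
class SubjectDataset:
    """One simulated participant record (stands in for a consented human run)."""

    subject_id: str
    ppg: WaveformRecord
    vitals: VitalsSeries
    protocol: LBNPProtocol
    latent_times: np.ndarray
    latent_reserve: np.ndarray
    seed: int

    def reserve_at(self, times: np.ndarray | float) -> np.ndarray:
        """Exact staircase reserve fraction at arbitrary times (oracle hook)."""
        return reserve_fraction(self.protocol, times, interpolate=False)


# -- beat morphology --------------------------------------------------------

_SYS_CENTER, _SYS_WIDTH = 0.30, 0.08
_DIC_CENTER, _DIC_WIDTH, _DIC_FRAC = 0.65, 0.10, 0.35


def beat_template(phase: np.ndarray) -> np.ndarray:
    """Unit-amplitude pulse shape over beat phase in [0, 1).

    A systolic Gaussian peak at 30% of the beat plus a smaller dicrotic
    component at 65%; widths chosen so the fundamental dominates the
    spectrum while the beat still shows the two-bump arterial shape.
    """
    u = np.mod(phase, 1.0)
    return (np.exp(-0.5 * ((u - _SYS_CENTER) / _SYS_WIDTH) ** 2)
            + _DIC_FRAC * np.exp(-0.5 * ((u - _DIC_CENTER) / _DIC_WIDTH) ** 2))


def synth_ppg_segment(heart_rate: float, pulse_amplitude: float, duration: float,
                      fs: float, noise_sd: float = 0.0,
                      rng: np.random.Generator | None = None) -> WaveformRecord:
    """Quasi-periodic pulse train at a constant rate and amplitude.

    Beat count is ``duration * heart_rate / 60``; with ``noise_sd = 0`` and
    60 bpm the systolic peaks repeat at exactly 1-s spacing.
    """
    if heart_rate <= 0 or fs <= 0:
        raise ConfigurationError("heart_rate and fs must be positive")
    if duration <= 0:
        raise EmptyRecordError("duration must be positive")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = pulse_amplitude * beat_template(heart_rate / 60.0 * t)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        x = x + rng.normal(0.0, noise_sd, n)
    return WaveformRecord(samples=x, sampling_rate=fs, source_label="simulated")


def latent_reserve_trajectory(protocol: LBNPProtocol, times: np.ndarray,
                              interpolate: bool = False) -> np.ndarray:
    """Reserve fraction ``1 - P(t)/P_endpoint`` on the protocol, clipped to [0, 1]."""
    return reserve_fraction(protocol, times, interpolate=interpolate)


# -- subject synthesis ------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """AR(1) noise with marginal standard deviation ``sd``."""
    z = rng.normal(0.0, 1.0, n)
    out = np.empty(n)
    innov = sd * np.sqrt(1.0 - phi * phi)
    acc = 0.0
    for i in range(n):
        acc = phi * acc + innov * z[i]
        out[i] = acc
    return out


def _physiological_reserve(protocol: LBNPProtocol, times: np.ndarray, tau: float) -> np.ndarray:
    """Continuous reserve driving vitals/PPG: interpolated decline, exponential recovery."""
    r = reserve_fraction(protocol, times, interpolate=True)
    ep = protocol.endpoint_time
    r_ep = float(reserve_fraction(protocol, ep, interpolate=True)[0])
    rec = times > ep
    r[rec] = 1.0 - (1.0 - r_ep) * np.exp(-(times[rec] - ep) / tau)
    return r


def simulate_subject(config: SimulatorConfig = SimulatorConfig(), seed: int = 0,
                     subject_id: str | None = None) -> SubjectDataset:
    """Generate one seeded synthetic LBNP subject under ``config``.

    The decompensation stage is drawn from ``stage_tolerance_probs`` and the
    endpoint placed uniformly within the interior (10%-95%) of that stage;
    heart rate rises and pulse amplitude falls with reserve loss, MAP stays
    near baseline until the reserve knee and then declines toward the floor,
    and pressure is released at the endpoint with relaxation to baseline.
    """
    config.validate()
    rng = np.random.default_rng(seed)

    probs = np.asarray(config.stage_tolerance_probs, dtype=float)
    probs = probs / probs.sum()
    stage_idx = int(rng.choice(len(config.stage_pressures), p=probs))
    frac = rng.uniform(0.10, 0.95)
    endpoint = config.baseline_duration + (stage_idx + frac) * config.stage_duration
    protocol = LBNPProtocol(
        endpoint_time=endpoint,
        baseline_duration=config.baseline_duration,
        stage_pressures=tuple(config.stage_pressures),
        stage_duration=config.stage_duration,
        recovery_duration=config.recovery_duration,
    )

    total = protocol.total_duration
    vt = np.arange(0.0, np.floor(total) + 0.5, 1.0 / config.vitals_rate)
    r_phys = _physiological_reserve(protocol, vt, config.recovery_tau)
    loss = 1.0 - r_phys

    hr0 = rng.normal(config.hr_baseline_mean, config.hr_baseline_sd)
    map0 = rng.normal(config.map_baseline_mean, config.map_baseline_sd)
    hr = hr0 * (1.0 + config.hr_rise_frac * loss ** config.hr_shape)
    map_clean = np.where(
        r_phys >= config.map_knee, map0,
        config.map_floor + (map0 - config.map_floor) * r_phys / config.map_knee)
    spo2_clean = config.spo2_baseline - config.spo2_drop * loss ** 2

    hr = np.maximum(hr + _ar1(rng, len(vt), config.vital_noise_ar, config.hr_noise_sd), 20.0)
    map_ = map_clean + _ar1(rng, len(vt), config.vital_noise_ar, config.map_noise_sd)
    spo2 = np.clip(spo2_clean + _ar1(rng, len(vt), config.vital_noise_ar, config.spo2_noise_sd),
                   50.0, 100.0)
    vitals = VitalsSeries(times=vt, heart_rate=hr, mean_arterial_pressure=map_, spo2=spo2)

    # PPG on its own grid; instantaneous rate follows the (noisy) HR series
    n = int(round(total * config.sampling_rate))
    ts = np.arange(n) / config.sampling_rate
    r_s = _physiological_reserve(protocol, ts, config.recovery_tau)
    amp = config.amp_endpoint + (config.amp_baseline - config.amp_endpoint) * r_s
    hr_s = np.interp(ts, vt, hr)
    phase = np.cumsum(hr_s / 60.0) / config.sampling_rate
    ppg = config.ppg_offset + amp * beat_template(phase) \
        + rng.normal(0.0, config.ppg_noise_sd, n)
    record = WaveformRecord(samples=ppg, sampling_rate=config.sampling_rate,
                            source_label="simulated")

    latent = reserve_fraction(protocol, vt, interpolate=False)
    sid = subject_id if subject_id is not None else f"subj{seed:05d}"
    return SubjectDataset(subject_id=sid, ppg=record, vitals=vitals, protocol=protocol,
                          latent_times=vt, latent_reserve=latent, seed=seed)


# -- export / import --------------------------------------------------------

def export_subject(dataset: SubjectDataset, outdir: str | Path) -> dict[str, Path]:
    """Write ``<id>_ppg.csv``, ``<id>_vitals.csv`` and ``<id>_protocol.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppg": outdir / f"{dataset.subject_id}_ppg.csv",
        "vitals": outdir / f"{dataset.subject_id}_vitals.csv",
        "protocol": outdir / f"{dataset.subject_id}_protocol.json",
    }
    write_ppg_csv(dataset.ppg, paths["ppg"])
    dataset.vitals.to_frame().to_csv(paths["vitals"], index=False,
                                     float_format="%.6f", lineterminator="\n")
    save_protocol(dataset.protocol, paths["protocol"])
    return paths


def read_vitals_csv(path: str | Path) -> VitalsSeries:
    frame = pd.read_csv(path)
    expected = ["time_s", "hr_bpm", "map_mmHg", "spo2_pct"]
    if list(frame.columns[:4]) != expected:
        raise ConfigurationError(f"{path}: expected header {','.join(expected)}")
    return VitalsSeries(
        times=frame["time_s"].to_numpy(float),
        heart_rate=frame["hr_bpm"].to_numpy(float),
        mean_arterial_pressure=frame["map_mmHg"].to_numpy(float),
        spo2=frame["spo2_pct"].to_numpy(float),
    )
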