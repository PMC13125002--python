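"""Lower-body negative pressure (LBNP) protocol description.

An LBNP session consists of a resting baseline, a staircase of progressively
stronger chamber suction applied in fixed-length stages, an endpoint at which
the run is stopped (pre-syncopal stop criteria in the human protocol), and a
recovery period with the chamber released.  Pressures are stored as positive
magnitudes in mmHg (the chamber applies -15 mmHg when ``stage_pressures[0]``
is 15).

The protocol doubles as the reserve reference: the ground-truth compensatory
reserve at time ``t`` is ``1 - P(t) / P_endpoint`` where ``P(t)`` is the
pressure magnitude at ``t`` and ``P_endpoint`` the magnitude at the moment the
stop criteria were reached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ProtocolError

DEFAULT_STAGE_PRESSURES: tuple[float, ...] = (15.0, 30.0, 45.0, 60.0, 70.0, 80.0, 90.0, 100.0)


@dataclass(frozen=True)
class LBNPProtocol:
    """Timing and pressure schedule of one LBNP run.

    Parameters
    ----------
    endpoint_time:
        Seconds from record start at which the stop criteria were reached and
        the chamber released.
    baseline_duration:
        Resting period before any suction, seconds.
    stage_pressures:
        Strictly increasing pressure magnitudes, mmHg, one per 5-min stage.
    stage_duration:
        Length of each pressure stage, seconds.
    recovery_duration:
        Chamber-released monitoring period after the endpoint, seconds.
    """

    endpoint_time: float
    baseline_duration: float = 300.0
    stage_pressures: tuple[float, ...] = DEFAULT_STAGE_PRESSURES
    stage_duration: float = 300.0
    recovery_duration: float = 600.0

    def __post_init__(self) -> None:
        pressures = tuple(float(p) for p in self.stage_pressures)
        object.__setattr__(self, "stage_pressures", pressures)
        if not pressures or any(p <= 0 for p in pressures):
            raise ProtocolError("stage pressures must be positive")
        if any(b <= a for a, b in zip(pressures, pressures[1:])):
            raise ProtocolError("stage pressures must be strictly increasing")
        for name in ("baseline_duration", "stage_duration", "recovery_duration"):
            if getattr(self, name) <= 0:
                raise ProtocolError(f"{name} must be positive")
        max_end = self.baseline_duration + len(pressures) * self.stage_duration
        if not (self.baseline_duration < self.endpoint_time <= max_end):
            raise ProtocolError(
                "endpoint_time must fall within the chamber-active stage schedule "
                f"({self.baseline_duration} < t <= {max_end}), got {self.endpoint_time}"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def total_duration(self) -> float:
        """Full record span: baseline + stages up to the endpoint + recovery."""
        return self.endpoint_time + self.recovery_duration

    @property
    def chamber_interval(self) -> tuple[float, float]:
        """Closed interval during which the chamber is applying suction."""
        return (self.baseline_duration, self.endpoint_time)

    @property
    def endpoint_stage_index(self) -> int:
        idx = int((self.endpoint_time - self.baseline_duration) // self.stage_duration)
        return min(idx, len(self.stage_pressures) - 1)

    @property
    def endpoint_pressure(self) -> float:
        """Pressure magnitude at the decompensation endpoint (mmHg)."""
        return self.stage_pressures[self.endpoint_stage_index]

    def pressure_at(self, times: np.ndarray | float) -> np.ndarray:
        """Chamber pressure magnitude at ``times`` (right-continuous staircase).

        Zero during baseline and after the endpoint release; the endpoint
        instant itself still carries the endpoint-stage pressure.
        """
        t = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.floor((t - self.baseline_duration) / self.stage_duration).astype(int)
        idx = np.clip(idx, 0, len(self.stage_pressures) - 1)
        p = np.asarray(self.stage_pressures, dtype=float)[idx]
        p[(t < self.baseline_duration) | (t > self.endpoint_time)] = 0.0
        return p

    def pressure_interp_at(self, times: np.ndarray | float) -> np.ndarray:
        """Within-stage linearly interpolated pressure magnitude.

        Each stage ramps from the previous stage's pressure (0 before the
        first stage) at stage start to its own pressure at stage end — a
        smooth stand-in for the delayed physiological response to the
        stepwise chamber schedule.
        """
        t = np.atleast_1d(np.asarray(times, dtype=float))
        n = len(self.stage_pressures)
        knots_t = [self.baseline_duration]
        knots_p = [0.0]
        for k, p in enumerate(self.stage_pressures):
            knots_t.append(self.baseline_duration + (k + 1) * self.stage_duration)
            knots_p.append(p)
        p = np.interp(t, knots_t, knots_p, left=0.0, right=self.stage_pressures[-1])
        p[(t < self.baseline_duration) | (t > self.endpoint_time)] = 0.0
        return p


def reserve_fraction(
    protocol: LBNPProtocol,
    times: np.ndarray | Sequence[float] | float,
    interpolate: bool = False,
) -> np.ndarray:
    """True reserve fraction ``clip(1 - P(t)/P_endpoint, 0, 1)`` on the protocol.

    ``interpolate=False`` (default) evaluates the literal pressure staircase;
    ``interpolate=True`` uses the within-stage linear ramp.  Equals 1 during
    baseline and recovery (pressure 0) and 0 wherever the pressure reaches the
    endpoint magnitude.
    """
    hdd = protocol.endpoint_pressure
    if hdd <= 0:
        raise ProtocolError("endpoint pressure is zero; reserve reference undefined")
    p = protocol.pressure_interp_at(times) if interpolate else protocol.pressure_at(times)
    return np.clip(1.0 - p / hdd, 0.0, 1.0)


# -- serialisation ----------------------------------------------------------

def save_protocol(protocol: LBNPProtocol, path: str | Path) -> None:
    """Write the protocol as a JSON key-value sidecar."""
    payload = {
        "baseline_duration_s": protocol.baseline_duration,
        "stage_pressures_mmHg": list(protocol.stage_pressures),
        "stage_duration_s": protocol.stage_duration,
        "endpoint_time_s": protocol.endpoint_time,
        "recovery_duration_s": protocol.recovery_duration,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def load_protocol(path: str | Path) -> LBNPProtocol:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return LBNPProtocol(
        endpoint_time=payload["endpoint_time_s"],
        baseline_duration=payload["baseline_duration_s"],
        stage_pressures=tuple(payload["stage_pressures_mmHg"]),
        stage_duration=payload["stage_duration_s"],
        recovery_duration=payload["recovery_duration_s"],
    )
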