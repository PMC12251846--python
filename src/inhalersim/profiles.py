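"""Inhalation flow profiles and inhaled-volume geometry.

A smart reusable inhaler senses the pressure drop generated across the
mouthpiece while the patient inhales.  With a dimensionless device
resistance ``R`` the instantaneous inspiratory flow rate is ``Q = dp / R``,
so the sensed pressure trace maps one-to-one onto a flow-time curve.  The
curve rises from rest to the Peak Inspiratory Flow (PIF) and decays back
towards zero; the area under it (trapezoidal sum of the segment areas) is
the inhaled volume, which is the quantity the training simulation compares
between a patient's attempt and the severity-specific reference profile.

Units: times in seconds, flows in L/min, volumes in litres (the 1/60
conversion is applied inside :func:`inhaled_volume`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FlowCurve",
    "DeviceResistance",
    "SlopeSequence",
    "SeverityProfileSpec",
    "flow_from_pressure",
    "decompose_slopes",
    "recompose_from_slopes",
    "inhaled_volume",
    "build_reference_profile",
    "MODERATE_PROFILE",
    "SEVERE_PROFILE",
]


class InvalidProfileError(ValueError):
    """Raised when a flow curve or profile specification is malformed."""


@dataclass(frozen=True)
class DeviceResistance:
    """Dimensionless pressure-per-flow resistance of the inhaler (default 1)."""

    R: float = 1.0

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise InvalidProfileError(f"device resistance must be positive, got {self.R}")


@dataclass(frozen=True)
class FlowCurve:
    """A time-ordered inhalation profile.

    Attributes
    ----------
    times : np.ndarray
        Sample times in seconds, strictly increasing, starting at 0.
    flows : np.ndarray
        Instantaneous flow rates in L/min, non-negative; the first sample is
        0 (inhalation starts from rest).
    """

    times: np.ndarray
    flows: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        flows = np.asarray(self.flows, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "flows", flows)
        if times.ndim != 1 or flows.ndim != 1 or len(times) != len(flows):
            raise InvalidProfileError("times and flows must be 1-d arrays of equal length")
        if len(times) < 2:
            raise InvalidProfileError("a flow curve needs at least two samples")
        if times[0] != 0:
            raise InvalidProfileError("inhalation must start at t = 0")
        if np.any(np.diff(times) <= 0):
            raise InvalidProfileError("times must be strictly increasing")
        if np.any(flows < 0):
            raise InvalidProfileError("flows must be non-negative")
        if flows[0] != 0:
            raise InvalidProfileError("inhalation starts from rest (flows[0] == 0)")

    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def pif_index(self) -> int:
        """Index of the Peak Inspiratory Flow; earliest index wins on ties."""
        return int(np.argmax(self.flows))

    @property
    def pif(self) -> float:
        """Peak Inspiratory Flow in L/min."""
        return float(self.flows[self.pif_index])

    @property
    def time_to_pif(self) -> float:
        return float(self.times[self.pif_index])

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "flow_lpm": self.flows}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FlowCurve":
        df = pd.read_csv(path)
        return cls(times=df["time_s"].to_numpy(), flows=df["flow_lpm"].to_numpy())


@dataclass(frozen=True)
class SlopeSequence:
    """Per-segment flow slopes in (L/min)/s; length is ``n_points - 1``."""

    slopes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "slopes", np.asarray(self.slopes, dtype=float))

    def __len__(self) -> int:
        return len(self.slopes)


def flow_from_pressure(delta_p, resistance: DeviceResistance = DeviceResistance()):
    """Convert a sensed pressure drop to an inspiratory flow rate, Q = dp / R.

    Accepts scalars or arrays; raises on negative pressure drops.
    """
    delta_p = np.asarray(delta_p, dtype=float)
    if np.any(delta_p < 0):
        raise InvalidProfileError("pressure drop must be non-negative during inhalation")
    out = delta_p / resistance.R
    return float(out) if out.ndim == 0 else out


def decompose_slopes(curve: FlowCurve) -> SlopeSequence:
    """Slopes m_i = (Q_{i+1} - Q_i) / (t_{i+1} - t_i) for each segment."""
    return SlopeSequence(np.diff(curve.flows) / np.diff(curve.times))


def recompose_from_slopes(start_flow: float, slopes: SlopeSequence, times) -> FlowCurve:
    """Rebuild a flow curve by propagating slopes segment by segment.

    A deviation in slope i shifts the starting flow of segment i+1, so
    sampling errors propagate cumulatively along the curve.  Negative
    intermediate flows are physically impossible during inhalation and are
    clamped to zero (the clamp count is logged at DEBUG level).
    """
    times = np.asarray(times, dtype=float)
    m = slopes.slopes
    if len(m) != len(times) - 1:
        raise InvalidProfileError(
            f"need len(times) - 1 slopes, got {len(m)} slopes for {len(times)} times"
        )
    flows = np.empty(len(times))
    flows[0] = max(float(start_flow), 0.0)
    dt = np.diff(times)
    n_clamped = 0
    for i in range(len(m)):
        nxt = flows[i] + m[i] * dt[i]
        if nxt < 0:
            nxt = 0.0
            n_clamped += 1
        flows[i + 1] = nxt
    if n_clamped:
        logger.debug("recompose_from_slopes clamped %d negative flows to 0", n_clamped)
    return FlowCurve(times=times, flows=flows)


def inhaled_volume(curve: FlowCurve) -> float:
    """Inhaled volume in litres: trapezoidal area under the flow curve.

    Flows are in L/min and times in seconds, hence the 1/60 factor.
    """
    return float(np.trapezoid(curve.flows, curve.times)) / 60.0


@dataclass(frozen=True)
class SeverityProfileSpec:
    """Parameters of a synthetic severity-specific reference inhalation.

    The manufacturer's in-vitro flow profiles for moderate and severe COPD
    are unimodal: a concave rising limb up to the PIF followed by a roughly
    exponential decay.  ``rise_shape`` is the power-law exponent of the
    rising limb (< 1 means fast early acceleration) and ``decay_shape`` the
    exponential rate of the decaying limb (flow at total_duration is
    ``pif * exp(-decay_shape)``).
    """

    severity: str
    pif: float
    time_to_pif: float
    total_duration: float
    rise_shape: float = 0.8
    decay_shape: float = 2.5
    n_points: int = 18

    def __post_init__(self) -> None:
        if self.severity not in ("moderate", "severe"):
            raise InvalidProfileError(f"unknown severity {self.severity!r}")
        if not self.pif > 0:
            raise InvalidProfileError("pif must be positive")
        if not 0 < self.time_to_pif < self.total_duration:
            raise InvalidProfileError("need 0 < time_to_pif < total_duration")
        if self.rise_shape <= 0 or self.decay_shape <= 0:
            raise InvalidProfileError("shape parameters must be positive")
        if self.n_points < 3:
            raise InvalidProfileError("need at least 3 points for a unimodal profile")


def build_reference_profile(spec: SeverityProfileSpec) -> FlowCurve:
    """Build the condensed (default 18-point) reference curve for a severity.

    The time grid is uniform over [0, total_duration]; the requested
    time-to-PIF is snapped to the nearest interior grid point so that
    exactly one sample attains the maximum.  Deterministic for a given spec.
    """
    times = np.linspace(0.0, spec.total_duration, spec.n_points)
    dt = times[1] - times[0]
    k = int(round(spec.time_to_pif / dt))
    k = min(max(k, 1), spec.n_points - 2)
    t_pif = times[k]
    flows = np.empty(spec.n_points)
    rise = times[: k + 1] / t_pif
    flows[: k + 1] = spec.pif * rise**spec.rise_shape
    tail = (times[k + 1 :] - t_pif) / (spec.total_duration - t_pif)
    flows[k + 1 :] = spec.pif * np.exp(-spec.decay_shape * tail)
    return FlowCurve(times=times, flows=flows)


# Default synthetic stand-ins for the manufacturer's moderate / severe
# reference inhalations (the published figures are not tabulated; only
# quantities relative to the reference volume enter the simulation).
MODERATE_PROFILE = SeverityProfileSpec(
    severity="moderate", pif=35.0, time_to_pif=0.8, total_duration=2.5
)
SEVERE_PROFILE = SeverityProfileSpec(
    severity="severe", pif=45.0, time_to_pif=0.6, total_duration=2.2
)
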