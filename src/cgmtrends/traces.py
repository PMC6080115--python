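"""Glucose trace containers, linear interpolation and forward rate of change.

The analysis evaluates an arrow by the glucose change it "predicted": the
trace is linearly interpolated at the moment the arrow was recorded and again
a fixed horizon later (30 min by default), and the difference divided by the
horizon gives the realized rate in mg/(dL.min).  Missing data are never
imputed; if the samples bracketing a requested time are further apart than
``max_gap`` the record is excluded upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TraceGapError, TraceRangeError

__all__ = ["GlucoseTrace", "interpolate", "forward_rate"]

#: Interpolation gap cap as a multiple of the device storage cadence.
#: 2.5 x cadence (DG5: 12.5 min, FL: 37.5 min) tolerates a single missed
#: reading but refuses to bridge real sensor dropouts.
DEFAULT_GAP_FACTOR = 2.5


@dataclass(frozen=True)
class GlucoseTrace:
    """Time-ordered glucose samples for one sensor (or the BG reference).

    ``times`` are real-valued minutes since study start (day 0, 00:00);
    ``values`` are glucose in mg/dL.  Times must be strictly increasing and
    values finite and positive.
    """

    sensor_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError(f"trace {self.sensor_id}: times must be strictly increasing")
        if not (np.all(np.isfinite(v)) and np.all(v > 0)):
            raise ValueError(f"trace {self.sensor_id}: values must be finite and positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


def interpolate(trace: GlucoseTrace, t: float, max_gap: float = np.inf) -> float:
    """Linearly interpolate the trace at time ``t`` (minutes).

    Returns the stored value exactly when ``t`` coincides with a sample
    time.  Raises :class:`TraceRangeError` if ``t`` lies outside the trace
    span and :class:`TraceGapError` if the bracketing samples are more than
    ``max_gap`` minutes apart.
    """
    if len(trace) < 2:
        raise TraceRangeError(f"trace {trace.sensor_id}: need >= 2 samples to interpolate")
    times, values = trace.times, trace.values
    if not times[0] <= t <= times[-1]:
        raise TraceRangeError(
            f"trace {trace.sensor_id}: t={t:g} outside span [{times[0]:g}, {times[-1]:g}]"
        )
    j = int(np.searchsorted(times, t))
    if j < times.size and times[j] == t:
        return float(values[j])
    lo, hi = j - 1, j
    gap = times[hi] - times[lo]
    if gap > max_gap:
        raise TraceGapError(
            f"trace {trace.sensor_id}: gap {gap:g} min around t={t:g} exceeds max_gap {max_gap:g}"
        )
    w = (t - times[lo]) / gap
    return float(values[lo] + w * (values[hi] - values[lo]))


def forward_rate(
    trace: GlucoseTrace,
    t: float,
    horizon: float = 30.0,
    max_gap: float = np.inf,
) -> float:
    """Realized forward glucose rate of change in mg/(dL.min).

    Computed as ``(G(t + horizon) - G(t)) / horizon`` with both endpoints
    obtained by :func:`interpolate`; interpolation errors propagate so that
    records with missing data can be excluded rather than imputed.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon!r}")
    g0 = interpolate(trace, t, max_gap=max_gap)
    g1 = interpolate(trace, t + horizon, max_gap=max_gap)
    return (g1 - g0) / horizon


def default_max_gap(storage_interval: float) -> float:
    """Gap cap implied by a device's storage cadence."""
    return DEFAULT_GAP_FACTOR * storage_interval
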