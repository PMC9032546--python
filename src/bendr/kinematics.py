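"""Angular amplitude and variability descriptors of the bending cycles.

The sagittal pitch angle is obtained by cumulative trapezoidal integration of
the pitch-rate channel GyrX over the trimmed test span, with the integration
constant fixed at zero at the trim start.  Raw gyroscope integration drifts
(bias ~ deg/s accumulates to tens of degrees over a 100 s test), so a linear
detrend is applied by default: the slope of a least-squares line fitted to
the integrated trace is subtracted while the value at the trim start is kept,
preserving angle[0] = 0.

Cycle extraction identifies alternating angle minima and maxima
(prominence- and separation-gated local extrema), pairs each minimum with the
following maximum, and reports the per-cycle amplitudes A_i = max_i - min_i
and their mean.  Variability magnitude is summarised by the population SDs of
the three angular-velocity channels (SDX, SDY, SDZ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

from .recording import TrimmedSeries

__all__ = [
    "AngleTrace",
    "CycleAmplitudes",
    "VelocitySDs",
    "integrate_gyro",
    "detect_cycles",
    "velocity_sds",
]


@dataclass(frozen=True)
class AngleTrace:
    """Integrated pitch angle (degrees), same length and rate as its source."""

    angle: np.ndarray
    sampling_rate: float
    detrended: bool
    method: str = "cumulative_trapezoid"


@dataclass(frozen=True)
class CycleAmplitudes:
    """Alternating extrema of the angle trace and the per-cycle amplitudes."""

    minima: list[tuple[int, float]]
    maxima: list[tuple[int, float]]
    amplitudes: np.ndarray  # A_i = max_i - min_i, degrees
    mean_amplitude: float
    n_cycles: int


@dataclass(frozen=True)
class VelocitySDs:
    """Population SDs of GyrX/GyrY/GyrZ over the trimmed span (deg/s)."""

    sd_x: float
    sd_y: float
    sd_z: float


def integrate_gyro(gyr_x: TrimmedSeries, detrend: bool = True) -> AngleTrace:
    """Integrate the pitch-rate channel to a pitch-angle trace.

    ``detrend=True`` removes the fitted linear slope of the integrated trace
    (gyro-bias drift) while keeping angle[0] = 0.
    """
    values = np.asarray(gyr_x.values, dtype=float)
    dt = 1.0 / gyr_x.sampling_rate
    angle = cumulative_trapezoid(values, dx=dt, initial=0.0)
    if detrend:
        t = np.arange(angle.size) * dt
        slope = np.polyfit(t, angle, 1)[0]
        angle = angle - slope * t
    return AngleTrace(angle=angle, sampling_rate=gyr_x.sampling_rate, detrended=detrend)


def _default_min_separation(centered: np.ndarray, fs: float) -> float:
    """Half the median zero-crossing period of the mean-centred trace."""
    signs = np.sign(centered)
    signs[signs == 0] = 1
    crossings = np.nonzero(np.diff(signs) != 0)[0]
    if crossings.size < 2:
        return 0.0
    half_periods = np.diff(crossings) / fs  # crossings come twice per period
    period = 2.0 * float(np.median(half_periods))
    return 0.5 * period


def _alternate(events: list[tuple[int, float, str]]) -> list[tuple[int, float, str]]:
    """Collapse runs of same-type extrema, keeping the most extreme of each run."""
    out: list[tuple[int, float, str]] = []
    for idx, val, kind in events:
        if out and out[-1][2] == kind:
            prev = out[-1]
            better = val > prev[1] if kind == "max" else val < prev[1]
            if better:
                out[-1] = (idx, val, kind)
        else:
            out.append((idx, val, kind))
    return out


def detect_cycles(
    angle: AngleTrace,
    min_prominence_frac: float = 0.2,
    min_separation: float | None = None,
) -> CycleAmplitudes:
    """Detect bending cycles as alternating minima/maxima of the angle trace.

    Extrema need a prominence of at least ``min_prominence_frac`` times the
    global range and a same-type separation of at least ``min_separation``
    seconds (default: half the median zero-crossing period, robust for 1-4 s
    cycles).  Amplitudes pair each minimum with the following maximum; when
    the trace starts rising immediately (as a bending test does, from
    standing), the minimum of the leading segment is used as the first
    minimum.  Invariant to adding a constant to the trace.
    """
    a = np.asarray(angle.angle, dtype=float)
    fs = angle.sampling_rate
    rng = float(a.max() - a.min())
    if rng == 0.0:
        raise ValueError("insufficient cycles: angle trace is constant")
    prominence = min_prominence_frac * rng
    if min_separation is None:
        min_separation = _default_min_separation(a - a.mean(), fs)
    distance = max(1, int(round(min_separation * fs)))

    peaks_max, _ = find_peaks(a, prominence=prominence, distance=distance)
    peaks_min, _ = find_peaks(-a, prominence=prominence, distance=distance)
    events = sorted(
        [(int(i), float(a[i]), "max") for i in peaks_max]
        + [(int(i), float(a[i]), "min") for i in peaks_min]
    )
    events = _alternate(events)
    if events and events[0][2] == "max":
        lead = a[: events[0][0]]
        if lead.size:
            i0 = int(np.argmin(lead))
            events.insert(0, (i0, float(a[i0]), "min"))

    minima: list[tuple[int, float]] = []
    maxima: list[tuple[int, float]] = []
    amplitudes: list[float] = []
    for prev, nxt in zip(events, events[1:]):
        if prev[2] == "min" and nxt[2] == "max":
            minima.append((prev[0], prev[1]))
            maxima.append((nxt[0], nxt[1]))
            amplitudes.append(nxt[1] - prev[1])

    if len(amplitudes) < 2:
        raise ValueError(f"insufficient cycles: found {len(amplitudes)}")
    amps = np.asarray(amplitudes)
    return CycleAmplitudes(
        minima=minima,
        maxima=maxima,
        amplitudes=amps,
        mean_amplitude=float(amps.mean()),
        n_cycles=len(amplitudes),
    )


def velocity_sds(trimmed: dict[str, TrimmedSeries]) -> VelocitySDs:
    """SDX/SDY/SDZ: population SDs of the trimmed angular-velocity channels."""
    return VelocitySDs(
        sd_x=float(np.std(trimmed["gyr_x"].values)),
        sd_y=float(np.std(trimmed["gyr_y"].values)),
        sd_z=float(np.std(trimmed["gyr_z"].values)),
    )
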