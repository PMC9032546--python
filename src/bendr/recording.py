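"""IMU recordings: in-memory container, delimited-text I/O, and test-span
segmentation.

A recording is six synchronized channels from a single sacrum-mounted IMU —
AccX/AccY/AccZ in g and GyrX/GyrY/GyrZ in deg/s — sampled uniformly (100 Hz in
the reference protocol), plus a time column and free-form metadata.  Files are
plain CSV with a ``# key: value`` sidecar header block.

The bending-and-return test protocol brackets the 50 movement cycles with a
left-right rotation marker: quiet standing, marker pulse, a short pause, the
cycles, quiet tail.  :func:`segment_test` automates the study's manual
trimming: it locates the marker pulse, then takes the last near-zero GyrX
sample before the first cycle launches as the start and the first near-zero
GyrX sample after the last cycle as the end, and applies the same half-open
``[start, end)`` span to all six channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CHANNELS",
    "IMURecording",
    "TrimmedSeries",
    "read_recording",
    "write_recording",
    "segment_test",
    "trim_recording",
]

#: canonical channel names, in file-column order
CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

MIN_TRIMMED_SAMPLES = 200

_CANONICAL = {
    "time": "time",
    "t": "time",
    "accx": "acc_x",
    "accy": "acc_y",
    "accz": "acc_z",
    "gyrx": "gyr_x",
    "gyry": "gyr_y",
    "gyrz": "gyr_z",
}


@dataclass
class IMURecording:
    """Six synchronized IMU channels plus time, sampling rate and metadata."""

    time: np.ndarray  # seconds, uniform step 1/sampling_rate
    acc_x: np.ndarray  # g
    acc_y: np.ndarray
    acc_z: np.ndarray
    gyr_x: np.ndarray  # deg/s
    gyr_y: np.ndarray
    gyr_z: np.ndarray
    sampling_rate: float  # Hz
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.time.size
        if n < 2:
            raise ValueError("recording must contain at least 2 samples")
        for name in CHANNELS:
            if self.channel(name).size != n:
                raise ValueError(f"channel {name} length differs from time axis")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return getattr(self, name)

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        """Recording duration in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.time}
        data.update({name: self.channel(name) for name in CHANNELS})
        return pd.DataFrame(data)


@dataclass(frozen=True)
class TrimmedSeries:
    """One channel restricted to the test span, with provenance indices.

    ``start_index``/``end_index`` are 0-based half-open ``[start, end)``
    indices into the source recording.
    """

    values: np.ndarray
    start_index: int
    end_index: int
    channel: str
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.end_index - self.start_index != self.values.size:
            raise ValueError("index span does not match values length")
        if self.values.size < MIN_TRIMMED_SAMPLES:
            raise ValueError(
                f"trimmed span has {self.values.size} samples; "
                f"at least {MIN_TRIMMED_SAMPLES} are required for entropy analysis"
            )

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def _parse_meta_value(raw: str):
    raw = raw.strip()
    for caster in (int, float):
        try:
            return caster(raw)
        except ValueError:
            pass
    if raw.lower() in ("true", "false"):
        return raw.lower() == "true"
    return raw


def _canonical_name(name: str) -> str | None:
    key = name.strip().lower().replace("_", "").replace(" ", "")
    return _CANONICAL.get(key)


def read_recording(
    path,
    *,
    delimiter: str = ",",
    column_map: dict[str, str] | None = None,
    jitter_tol: float = 0.01,
) -> IMURecording:
    """Read a delimited-text recording.

    The header must name the seven columns (case-insensitively: time,
    AccX..GyrZ in any common spelling); ``column_map`` maps non-standard
    source headers to canonical names (``{"pitch_rate": "gyr_x"}``) for
    deposits with other conventions.  Rows containing non-finite values are
    dropped and the count is reported in ``meta['n_dropped_rows']``.  The
    sampling rate is inferred from the median time step; more than 1% of
    steps deviating from it by over ``jitter_tol`` (relative) is an error.
    """
    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, raw = body.split(":", 1)
                meta[key.strip()] = _parse_meta_value(raw)

    df = pd.read_csv(path, sep=delimiter, comment="#", float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    renames = {}
    for col in df.columns:
        canon = _canonical_name(str(col))
        if canon is not None:
            renames[col] = canon
    df = df.rename(columns=renames)

    required = ("time",) + CHANNELS
    for name in required:
        if name not in df.columns:
            raise ValueError(
                f"missing required column '{name}' in {path} "
                f"(found: {list(df.columns)}); use column_map for non-standard headers"
            )
    df = df[list(required)].astype(float)

    finite = np.isfinite(df.to_numpy()).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with non-finite values", path, n_dropped)
        meta["n_dropped_rows"] = n_dropped
        df = df[finite]

    time = df["time"].to_numpy()
    if time.size < 2:
        raise ValueError(f"{path}: fewer than 2 valid rows")
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    step = float(np.median(dt))
    bad = np.abs(dt - step) > jitter_tol * step
    if bad.mean() > 0.01:
        jitter = float(np.max(np.abs(dt - step)))
        raise ValueError(
            f"{path}: non-uniform sampling — {int(bad.sum())}/{dt.size} steps deviate "
            f"from the median step {step:.6g} s (max jitter {jitter:.6g} s)"
        )

    return IMURecording(
        time=time,
        **{name: df[name].to_numpy() for name in CHANNELS},
        sampling_rate=1.0 / step,
        meta=meta,
    )


def write_recording(rec: IMURecording, path) -> None:
    """Write a recording as CSV with a ``# key: value`` metadata header.

    Floats are written at full round-trip precision so that
    write -> read reproduces the recording exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(rec.meta):
            fh.write(f"# {key}: {rec.meta[key]}\n")
        rec.to_frame().to_csv(fh, index=False)


def _last_near_zero(values: np.ndarray, lo: int, hi: int, zero_tol: float) -> int:
    """Index in [lo, hi) of the last |value| <= zero_tol, falling back to the
    last global argmin of |value| over the window."""
    window = np.abs(values[lo:hi])
    below = np.nonzero(window <= zero_tol)[0]
    if below.size:
        return lo + int(below[-1])
    rev = window[::-1]
    return hi - 1 - int(np.argmin(rev))


def _first_near_zero(values: np.ndarray, lo: int, hi: int, zero_tol: float) -> int:
    window = np.abs(values[lo:hi])
    below = np.nonzero(window <= zero_tol)[0]
    if below.size:
        return lo + int(below[0])
    return lo + int(np.argmin(window))


def segment_test(
    rec: IMURecording,
    *,
    marker_channel: str = "gyr_y",
    zero_tol: float = 2.0,
    launch_frac: float = 0.1,
    min_launch_duration: float = 0.25,
    require_marker: bool = True,
) -> dict[str, TrimmedSeries]:
    """Locate the bending-and-return test span and trim all six channels.

    The marker pulse (the pre-test left-right rotation) must exceed
    ``5 * zero_tol`` on ``marker_channel``; its end is the last crossing of
    half the marker peak.  The span start is the closest-to-zero GyrX sample
    between the marker end and the first cycle's launch (|GyrX| exceeding
    ``launch_frac`` of its post-marker peak); the end is the closest-to-zero
    sample after the last launch-level excursion.  The identical half-open
    span is applied to every channel.

    With ``require_marker=False`` a recording without a detectable marker
    (e.g. one that has already been trimmed) is segmented from its first
    sample; this makes trimming idempotent.
    """
    fs = rec.sampling_rate
    mk = np.abs(rec.channel(marker_channel))
    peak_mk = float(mk.max())
    if peak_mk > 5.0 * zero_tol:
        above = np.nonzero(mk > 0.5 * peak_mk)[0]
        marker_end = int(above[-1]) + 1
    elif require_marker:
        raise ValueError("marker not detected")
    else:
        marker_end = 0

    gx = rec.gyr_x
    active = np.abs(gx[marker_end:])
    if active.size == 0 or float(active.max()) <= zero_tol:
        raise ValueError("no movement detected after marker")
    launch = launch_frac * float(active.max())
    # a cycle launch must hold the threshold for min_launch_duration, so a
    # lone correlated-noise spike during the pause cannot trigger it
    run = max(1, int(round(min_launch_duration * fs)))
    above = active > launch
    if run > 1:
        sustained = np.convolve(above.astype(float), np.ones(run), mode="valid") == run
    else:
        sustained = above
    starts = np.nonzero(sustained)[0]
    if starts.size == 0:
        raise ValueError("no movement detected after marker")
    first_active = marker_end + int(starts[0])
    last_active = marker_end + int(starts[-1]) + run - 1

    start = _last_near_zero(gx, marker_end, first_active + 1, zero_tol)
    tail_hi = min(rec.n_samples, last_active + int(round(fs)) + 1)
    end = _first_near_zero(gx, last_active, tail_hi, zero_tol) + 1

    if end - start < MIN_TRIMMED_SAMPLES:
        raise ValueError(
            f"test span [{start}, {end}) has fewer than {MIN_TRIMMED_SAMPLES} samples"
        )
    return {
        name: TrimmedSeries(
            values=rec.channel(name)[start:end],
            start_index=start,
            end_index=end,
            channel=name,
            sampling_rate=fs,
        )
        for name in CHANNELS
    }


def trim_recording(rec: IMURecording, **segment_kwargs) -> IMURecording:
    """Return a new recording restricted to the segmented test span."""
    trimmed = segment_test(rec, **segment_kwargs)
    start = trimmed["gyr_x"].start_index
    end = trimmed["gyr_x"].end_index
    meta = dict(rec.meta)
    meta.update(trimmed=True, trim_start_index=start, trim_end_index=end)
    return replace(
        rec,
        time=rec.time[start:end],
        **{name: rec.channel(name)[start:end] for name in CHANNELS},
        meta=meta,
    )
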