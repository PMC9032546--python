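"""Windowed SampEn convergence: the full-test value and growing partial windows.

SampEn50 is the sample entropy of the whole trimmed test span (all 50
bending cycles).  The partial values SampEn10I are computed on windows
running from 10 s after the trim start up to I s, for I = 12, 14, ..., 70 —
2 s increments of exactly 200 samples at 100 Hz.  The 10 s offset discards
the habituation phase; the 70 s cap equalises window lengths across
participants (every test in the reference cohort lasted at least 72 s).
Comparing SampEn10I against SampEn50 across a cohort is what determines the
shortest clinically feasible test duration.

In relative tolerance mode, r is resolved per window (each window's own SD)
by default, keeping every window self-contained; ``r_scope="full"`` resolves
r once from the full trimmed span instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .recording import TrimmedSeries
from .sampen import SampEnParams, SampEnResult, sampen

__all__ = ["ConvergenceTable", "sampen50", "sampen_partials"]


@dataclass
class ConvergenceTable:
    """SampEn50 plus the ordered partial values for one channel of one test."""

    participant: str
    condition: str
    channel: str
    sampen50: SampEnResult
    partials: dict[int, SampEnResult]  # window end I (s, even) -> result
    params: SampEnParams


def sampen50(trimmed: TrimmedSeries, params: SampEnParams | None = None) -> SampEnResult:
    """SampEn over the entire trimmed test span."""
    return sampen(trimmed.values, params)


def sampen_partials(
    trimmed: TrimmedSeries,
    params: SampEnParams | None = None,
    *,
    t_start: float = 10.0,
    t_end: float = 70.0,
    step: float = 2.0,
    r_scope: str = "window",
    participant: str = "",
    condition: str = "",
) -> ConvergenceTable:
    """SampEn10I on half-open windows [t_start, I) s relative to trim start.

    I runs from ``t_start + step`` to ``t_end`` in ``step`` increments; the
    table is truncated (with a warning) at the last window that fits the
    trimmed span.  Window boundaries are exact sample counts: window I holds
    ``(I - t_start) * rate`` samples.
    """
    if params is None:
        params = SampEnParams()
    if r_scope not in ("window", "full"):
        raise ValueError(f"r_scope must be 'window' or 'full', got {r_scope!r}")
    fs = trimmed.sampling_rate
    n = trimmed.n_samples
    i0 = int(round(t_start * fs))
    if n < int(round((t_start + step) * fs)):
        raise ValueError(
            f"trimmed span of {n / fs:.1f} s is too short for a first window "
            f"ending at {t_start + step:.0f} s"
        )

    window_params = params
    if params.r_mode == "relative" and r_scope == "full":
        full = sampen50(trimmed, params)
        window_params = SampEnParams(m=params.m, r_mode="absolute", r_value=full.r_absolute)

    partials: dict[int, SampEnResult] = {}
    i_values = []
    end = t_start + step
    while end <= t_end + 1e-9:
        i_values.append(end)
        end += step
    for end_s in i_values:
        j = int(round(end_s * fs))
        if j > n:
            warnings.warn(
                f"trimmed span of {n / fs:.1f} s < {t_end:.0f} s; "
                f"partial table truncated at I = {int(end_s - step)} s",
                stacklevel=2,
            )
            break
        partials[int(round(end_s))] = sampen(trimmed.values[i0:j], window_params)

    return ConvergenceTable(
        participant=participant,
        condition=condition,
        channel=trimmed.channel,
        sampen50=sampen50(trimmed, params),
        partials=partials,
        params=params,
    )
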