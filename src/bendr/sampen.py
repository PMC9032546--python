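"""Sample Entropy (SampEn) of a finite time series.

SampEn(m, r)(x) = -ln(A / B), where B counts ordered template pairs
``(i, j), i != j`` whose length-``m`` embedding vectors lie within Chebyshev
(max-coordinate) distance ``r`` of each other, and A counts the same pairs at
length ``m + 1``.  Both counts run over the ``N - m`` templates that admit an
(m+1)-length extension, so ``A <= B`` always and ``A / B`` is a conditional
probability: given that two length-m patterns match, how often does the next
sample still match?  Low SampEn means a regular, predictable series; high
SampEn an irregular one.  Self-matches are excluded, which is what makes
SampEn (unlike approximate entropy) largely insensitive to series length and
usable on short physiological recordings — we enforce a conservative floor of
200 samples by default.

The tolerance ``r`` is conventionally expressed relative to the series
standard deviation (``r = 0.2 * SD`` with embedding dimension ``m = 2`` being
the standard Richman–Moorman choice); the population SD (divisor ``N``) is
used because ``r`` scales with it.

Two implementations are provided:

* :func:`sampen` — the production path, a compiled double loop with
  early-abort Chebyshev comparison.  Count-exact (no approximate neighbour
  search).
* :func:`sampen_oracle` — an exhaustive verification twin organised
  completely differently (per-template numpy broadcasting over the full
  embedding matrix).  The two must agree bit-exactly on the counts A and B;
  the test suite enforces this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SampEnParams", "SampEnResult", "sampen", "sampen_oracle"]

DEFAULT_MIN_LENGTH = 200


@dataclass(frozen=True)
class SampEnParams:
    """Embedding dimension and tolerance for a SampEn computation.

    r_mode "relative" interprets ``r_value`` as a multiple of the series'
    population SD; "absolute" interprets it in the units of the series.
    """

    m: int = 2
    r_mode: str = "relative"
    r_value: float = 0.2

    def __post_init__(self) -> None:
        if not isinstance(self.m, (int, np.integer)) or self.m < 1:
            raise ValueError(f"m must be a positive integer, got {self.m!r}")
        if self.r_mode not in ("relative", "absolute"):
            raise ValueError(f"r_mode must be 'relative' or 'absolute', got {self.r_mode!r}")
        if not math.isfinite(self.r_value):
            raise ValueError("r_value must be finite")
        if self.r_mode == "relative" and self.r_value <= 0:
            raise ValueError("relative r_value must be > 0")
        if self.r_mode == "absolute" and self.r_value < 0:
            raise ValueError("absolute r_value must be >= 0")


@dataclass(frozen=True)
class SampEnResult:
    """SampEn value with the raw match counts behind it.

    ``sampen`` is NaN (and :attr:`defined` False) when either count is zero —
    the estimate is then undefined rather than infinite, so cohort
    aggregation can skip it instead of crashing.
    """

    sampen: float
    match_count_m: int  # B: ordered pairs matching at length m
    match_count_m1: int  # A: ordered pairs matching at length m + 1
    n_templates: int  # N - m
    params: SampEnParams
    r_absolute: float = field(default=float("nan"))

    @property
    def defined(self) -> bool:
        return math.isfinite(self.sampen)


@njit(cache=True)
def _match_counts(x, m, r):  # pragma: no cover - exercised via sampen()
    n = x.shape[0]
    nt = n - m
    a = 0
    b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            ok = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    ok = False
                    break
            if ok:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    # matching is symmetric: ordered-pair counts are twice the triangle counts
    return 2 * a, 2 * b


def _validate(x: np.ndarray, params: SampEnParams, min_length: int) -> np.ndarray:
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {x.shape}")
    n = x.size
    if n < min_length:
        raise ValueError(
            f"series has {n} samples; SampEn requires at least {min_length} "
            "(configurable via min_length)"
        )
    if n <= params.m + 1:
        raise ValueError(f"series length {n} must exceed m + 1 = {params.m + 1}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def _resolve_r(x: np.ndarray, params: SampEnParams) -> float:
    if params.r_mode == "absolute":
        return float(params.r_value)
    sd = float(x.std())  # population SD, divisor N
    if sd == 0.0:
        raise ValueError("degenerate constant series under relative tolerance")
    return params.r_value * sd


def _result(a: int, b: int, n_templates: int, params: SampEnParams, r_abs: float) -> SampEnResult:
    value = -math.log(a / b) if (a > 0 and b > 0) else float("nan")
    return SampEnResult(
        sampen=value,
        match_count_m=int(b),
        match_count_m1=int(a),
        n_templates=int(n_templates),
        params=params,
        r_absolute=float(r_abs),
    )


def sampen(
    x,
    params: SampEnParams | None = None,
    *,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> SampEnResult:
    """Sample Entropy of series ``x``.

    Parameters
    ----------
    x : array-like, 1-D
        The time series.
    params : SampEnParams, optional
        Embedding dimension and tolerance; defaults to m = 2, r = 0.2 * SD.
    min_length : int
        Hard floor on the series length (default 200, the conservative
        minimum for a stable SampEn estimate on physiological data).

    Returns
    -------
    SampEnResult
        With ordered-pair match counts A (length m + 1) and B (length m).
    """
    if params is None:
        params = SampEnParams()
    x = _validate(x, params, min_length)
    r_abs = _resolve_r(x, params)
    a, b = _match_counts(x, params.m, r_abs)
    return _result(a, b, x.size - params.m, params, r_abs)


def sampen_oracle(
    x,
    params: SampEnParams | None = None,
    *,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> SampEnResult:
    """Exhaustive O(N^2) SampEn, a verification twin of :func:`sampen`.

    Counts every template pair through full embedding matrices, one template
    row at a time, with no early abort and no shared counting code with the
    production kernel.  Slow but transparent; intended for tests.
    """
    if params is None:
        params = SampEnParams()
    x = _validate(x, params, min_length)
    r_abs = _resolve_r(x, params)
    m = params.m
    nt = x.size - m
    emb_m = sliding_window_view(x, m)[:nt]
    emb_m1 = sliding_window_view(x, m + 1)  # exactly nt rows
    a = 0
    b = 0
    for i in range(nt):
        d_m = np.max(np.abs(emb_m - emb_m[i]), axis=1)
        b += int(np.count_nonzero(d_m <= r_abs)) - 1  # drop the self-match
        d_m1 = np.max(np.abs(emb_m1 - emb_m1[i]), axis=1)
        a += int(np.count_nonzero(d_m1 <= r_abs)) - 1
    return _result(a, b, nt, params, r_abs)
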