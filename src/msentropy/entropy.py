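"""Single-scale entropy statistics: SampEn, ApEn, and a literal oracle.

Sample entropy (SampEn) is the negative log of the conditional
probability that two length-m windows of a series that match within a
Chebyshev tolerance r still match when extended to length m+1,
counting ordered template pairs and excluding self-matches.
Approximate entropy (ApEn) is its self-match-including predecessor,
``Phi^m(r) - Phi^(m+1)(r)``.

Conventions fixed here for exact reproducibility of integer counts:

* a distance exactly equal to r is a match (Heaviside theta(0) = 1);
* both m- and (m+1)-template pairs are counted over start positions
  1..N-m, so an (m+1)-match always implies an m-match and
  ``a_count <= b_count`` holds by construction;
* counts are stored raw (ordered pairs); the (N-m)(N-m-1) normalizers
  cancel in the ratio and are never applied;
* the tolerance is always *absolute* in this module — conversion from
  "r times SD" happens in :mod:`msentropy.multiscale`, the one place
  that owns threshold policy.

A zero count at either order yields a flagged, NaN-valued result
rather than an exception, so multi-scale curves can carry gaps at
scales too short to produce matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from ._kernels import count_template_matches, mean_log_match_fraction
from .exceptions import (InvalidInputError, OracleSizeExceededError,
                         SeriesTooShortError)
from .signals import TimeSeries

__all__ = ["EntropyParams", "EntropyResult", "embed", "sample_entropy",
           "approximate_entropy", "brute_force_sample_entropy"]

SeriesLike = Union[TimeSeries, Sequence[float], np.ndarray]

_ORACLE_MAX_N = 2000


@dataclass(frozen=True)
class EntropyParams:
    """Embedding window length m and absolute matching tolerance r_abs."""

    m: int
    r_abs: float

    def __post_init__(self):
        if int(self.m) < 1:
            raise InvalidInputError(f"m must be >= 1, got {self.m}")
        if not (self.r_abs > 0):
            raise InvalidInputError(f"r_abs must be > 0, got {self.r_abs}")


@dataclass(frozen=True)
class EntropyResult:
    """An entropy value together with the raw counts that produced it.

    ``value`` is NaN (and ``defined`` False) when either count is
    zero.  For SampEn, ``value == -log(a_count / b_count)`` whenever
    defined; for ApEn the counts are the self-inclusive match totals
    at orders m+1 and m and the value is the Phi difference.
    """

    value: float
    a_count: int
    b_count: int
    n_templates: int
    r_abs: float
    m: int

    @property
    def defined(self) -> bool:
        return self.a_count > 0 and self.b_count > 0


def _as_values(x: SeriesLike) -> np.ndarray:
    v = np.asarray(getattr(x, "values", x), dtype=np.float64)
    if v.ndim != 1:
        raise InvalidInputError("expected a one-dimensional series")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("series contains non-finite values")
    return v


def embed(x: SeriesLike, m: int) -> np.ndarray:
    """All length-m embedding vectors (N - m + 1 rows of m consecutive samples)."""
    v = _as_values(x)
    if int(m) < 1:
        raise InvalidInputError(f"m must be >= 1, got {m}")
    if v.size < m:
        raise SeriesTooShortError(f"need n >= m, got n={v.size}, m={m}")
    return np.lib.stride_tricks.sliding_window_view(v, int(m)).copy()


def sample_entropy(x: SeriesLike, params: EntropyParams) -> EntropyResult:
    """SampEn(x; m, r_abs) with raw ordered-pair counts."""
    v = _as_values(x)
    m, r = int(params.m), float(params.r_abs)
    if v.size < m + 2:
        raise SeriesTooShortError(
            f"sample entropy needs n >= m + 2, got n={v.size}, m={m}")
    a, b = count_template_matches(v, m, r)
    value = -math.log(a / b) if (a > 0 and b > 0) else math.nan
    return EntropyResult(value=value, a_count=int(a), b_count=int(b),
                         n_templates=v.size - m, r_abs=r, m=m)


def approximate_entropy(x: SeriesLike, params: EntropyParams) -> EntropyResult:
    """ApEn(x; m, r_abs) = Phi^m(r) - Phi^(m+1)(r), self-matches included."""
    v = _as_values(x)
    m, r = int(params.m), float(params.r_abs)
    if v.size < m + 1:
        raise SeriesTooShortError(
            f"approximate entropy needs n >= m + 1, got n={v.size}, m={m}")
    phi_m, total_m = mean_log_match_fraction(v, m, r)
    phi_m1, total_m1 = mean_log_match_fraction(v, m + 1, r)
    return EntropyResult(value=float(phi_m - phi_m1), a_count=int(total_m1),
                         b_count=int(total_m), n_templates=v.size - m,
                         r_abs=r, m=m)


def brute_force_sample_entropy(x: SeriesLike, params: EntropyParams) -> EntropyResult:
    """Independent SampEn oracle: the defining sums written out literally.

    Two separate double loops — one over m-template pairs for the B
    count, one over (m+1)-template pairs for the A count — in pure
    Python, sharing no code with the compiled kernel.  Restricted to
    n <= 2000 because of the quadratic cost.
    """
    v = _as_values(x)
    m, r = int(params.m), float(params.r_abs)
    if v.size > _ORACLE_MAX_N:
        raise OracleSizeExceededError(
            f"oracle limited to n <= {_ORACLE_MAX_N}, got n={v.size}")
    if v.size < m + 2:
        raise SeriesTooShortError(
            f"sample entropy needs n >= m + 2, got n={v.size}, m={m}")
    u = v.tolist()
    n = len(u)
    nt = n - m

    b = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            d = 0.0
            for k in range(m):
                e = abs(u[i + k] - u[j + k])
                if e > d:
                    d = e
            if d <= r:
                b += 1

    a = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            d = 0.0
            for k in range(m + 1):
                e = abs(u[i + k] - u[j + k])
                if e > d:
                    d = e
            if d <= r:
                a += 1

    value = -math.log(a / b) if (a > 0 and b > 0) else math.nan
    return EntropyResult(value=value, a_count=a, b_count=b,
                         n_templates=nt, r_abs=r, m=m)
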