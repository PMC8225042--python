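"""Seeded synthetic signal generators.

The generators cover the canonical reference signals of multi-scale
entropy work: white Gaussian noise (the zero-complexity reference),
1/f "pink" noise (the high-complexity reference), a random walk
(nonstationary integrated noise) and general ARIMA processes.  Every
generator takes an explicit seed through :class:`SignalSpec` and draws
from its own ``numpy.random.Generator`` stream, so a spec determines
its output bit-for-bit — no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from statsmodels.tsa.arima_process import ArmaProcess

from .exceptions import InvalidInputError, InvalidSpecError, UnsupportedExponentError

__all__ = ["SignalSpec", "TimeSeries", "generate", "generate_gaussian",
           "generate_one_over_f", "generate_random_walk", "generate_arima",
           "sample_sd"]

_KINDS = ("gaussian", "one_over_f", "random_walk", "arima")


def sample_sd(values: np.ndarray) -> float:
    """Sample standard deviation with the n-1 denominator.

    One SD convention is used everywhere in the package (generators,
    coarse-graining, threshold derivation) so that thresholds expressed
    as multiples of SD are reproducible to the last bit.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        return 0.0
    return float(np.std(v, ddof=1))


@dataclass(frozen=True)
class SignalSpec:
    """Full description of a synthetic signal: kind, length, seed, parameters.

    Parameters
    ----------
    kind:
        One of ``gaussian``, ``one_over_f``, ``random_walk``, ``arima``.
    n:
        Number of samples (>= 1; spectral synthesis needs >= 16).
    seed:
        Seed for the generator's private RNG stream. Identical spec +
        seed gives bit-identical output.
    mean, sd:
        Target location/scale. For the random walk ``sd`` is the SD of
        the iid Gaussian increments; the walk itself is never rescaled.
    arima_order:
        (p, d, q) for ``kind="arima"``.
    ar_coeffs, ma_coeffs:
        AR and MA coefficients in regression form (len p and q).
    spectral_exponent:
        beta for ``kind="one_over_f"``: power spectral density
        proportional to f**-beta. beta=1 is pink noise, beta=0 white.
    """

    kind: str
    n: int
    seed: int
    mean: float = 0.0
    sd: float = 1.0
    arima_order: tuple[int, int, int] = (0, 0, 0)
    ar_coeffs: tuple[float, ...] = ()
    ma_coeffs: tuple[float, ...] = ()
    spectral_exponent: float = 1.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise InvalidSpecError(f"unknown signal kind {self.kind!r}")
        if int(self.n) < 1:
            raise InvalidSpecError(f"n must be positive, got {self.n}")
        if not (self.sd > 0):
            raise InvalidSpecError(f"sd must be > 0, got {self.sd}")
        p, d, q = self.arima_order
        if min(p, d, q) < 0:
            raise InvalidSpecError(f"arima_order must be non-negative, got {self.arima_order}")
        if self.kind == "arima":
            if len(self.ar_coeffs) != p:
                raise InvalidSpecError(
                    f"len(ar_coeffs)={len(self.ar_coeffs)} but p={p}")
            if len(self.ma_coeffs) != q:
                raise InvalidSpecError(
                    f"len(ma_coeffs)={len(self.ma_coeffs)} but q={q}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "n": int(self.n), "seed": int(self.seed),
            "mean": float(self.mean), "sd": float(self.sd),
            "arima_order": list(self.arima_order),
            "ar_coeffs": list(self.ar_coeffs),
            "ma_coeffs": list(self.ma_coeffs),
            "spectral_exponent": float(self.spectral_exponent),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignalSpec":
        return cls(
            kind=d["kind"], n=int(d["n"]), seed=int(d["seed"]),
            mean=float(d.get("mean", 0.0)), sd=float(d.get("sd", 1.0)),
            arima_order=tuple(d.get("arima_order", (0, 0, 0))),
            ar_coeffs=tuple(d.get("ar_coeffs", ())),
            ma_coeffs=tuple(d.get("ma_coeffs", ())),
            spectral_exponent=float(d.get("spectral_exponent", 1.0)),
        )


@dataclass(frozen=True)
class TimeSeries:
    """An ordered single-channel series of finite real samples."""

    values: np.ndarray
    label: str = ""
    spec: Optional[SignalSpec] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise InvalidInputError("TimeSeries values must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("TimeSeries values must all be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n


def _rng(spec: SignalSpec) -> np.random.Generator:
    return np.random.default_rng(int(spec.seed))


def generate_gaussian(spec: SignalSpec) -> TimeSeries:
    """iid draws from Normal(mean, sd^2)."""
    if spec.kind != "gaussian":
        raise InvalidSpecError(f"expected kind 'gaussian', got {spec.kind!r}")
    values = _rng(spec).normal(spec.mean, spec.sd, spec.n)
    return TimeSeries(values, label="gaussian", spec=spec)


def generate_one_over_f(spec: SignalSpec) -> TimeSeries:
    """Noise with power spectral density proportional to f**-beta.

    Spectral synthesis: draw a complex Gaussian spectrum, shape its
    amplitude by f**(-beta/2), zero the DC bin, and invert the FFT.
    The result is exactly zero-mean (DC = 0) and is rescaled so the
    sample SD equals ``spec.sd``; ``spec.mean`` is then added.
    """
    if spec.kind != "one_over_f":
        raise InvalidSpecError(f"expected kind 'one_over_f', got {spec.kind!r}")
    beta = float(spec.spectral_exponent)
    if not (0.0 <= beta <= 2.0):
        raise UnsupportedExponentError(
            f"spectral exponent must lie in [0, 2], got {beta}")
    n = int(spec.n)
    if n < 16:
        raise InvalidSpecError(f"spectral synthesis needs n >= 16, got {n}")

    rng = _rng(spec)
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    re = rng.standard_normal(freqs.size)
    im = rng.standard_normal(freqs.size)
    spectrum = (re + 1j * im) * amp
    spectrum[0] = 0.0
    if n % 2 == 0:
        # Nyquist bin must be real for a real-valued inverse transform
        spectrum[-1] = re[-1] * amp[-1]
    y = np.fft.irfft(spectrum, n=n)
    y = y / sample_sd(y) * spec.sd + spec.mean
    return TimeSeries(y, label=f"one_over_f(beta={beta:g})", spec=spec)


def generate_random_walk(spec: SignalSpec) -> TimeSeries:
    """Cumulative sum of iid Normal(0, sd^2) increments.

    Deliberately not re-standardized: the hallmark of a random walk is
    nonstationary, growing variance, and normalization would erase it.
    """
    if spec.kind != "random_walk":
        raise InvalidSpecError(f"expected kind 'random_walk', got {spec.kind!r}")
    steps = _rng(spec).normal(0.0, spec.sd, spec.n)
    return TimeSeries(np.cumsum(steps) + spec.mean, label="random_walk", spec=spec)


def generate_arima(spec: SignalSpec) -> TimeSeries:
    """ARIMA(p, d, q) realization driven by iid Gaussian(0, sd^2) residuals.

    The stationary ARMA core is simulated with a burn-in of
    10*(p + q + 1) samples discarded, then integrated d times by
    cumulative summation.  With d = 0 the AR polynomial must have all
    roots outside the unit circle.
    """
    if spec.kind != "arima":
        raise InvalidSpecError(f"expected kind 'arima', got {spec.kind!r}")
    p, d, q = spec.arima_order
    ar_poly = np.r_[1.0, -np.asarray(spec.ar_coeffs, dtype=float)]
    ma_poly = np.r_[1.0, np.asarray(spec.ma_coeffs, dtype=float)]
    process = ArmaProcess(ar_poly, ma_poly)
    if d == 0 and p > 0 and not process.isstationary:
        raise InvalidSpecError(
            f"AR coefficients {spec.ar_coeffs} are non-stationary with d=0")
    rng = _rng(spec)
    burnin = 10 * (p + q + 1)
    y = process.generate_sample(nsample=spec.n, scale=spec.sd,
                                distrvs=rng.standard_normal, burnin=burnin)
    for _ in range(d):
        y = np.cumsum(y)
    if d == 0:
        y = y + spec.mean
    return TimeSeries(y, label=f"arima{spec.arima_order}", spec=spec)


_DISPATCH = {
    "gaussian": generate_gaussian,
    "one_over_f": generate_one_over_f,
    "random_walk": generate_random_walk,
    "arima": generate_arima,
}


def generate(spec: SignalSpec) -> TimeSeries:
    """Generate the signal described by ``spec`` (dispatch on kind)."""
    return _DISPATCH[spec.kind](spec)
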