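"""Closed-form Gaussian results for entropy across coarse-graining scales.

For a unit-variance iid Gaussian series, block-averaging over windows
of length tau shrinks the standard deviation to 1/sqrt(tau).  Holding
the matching tolerance fixed at ``r`` (a multiple of the *original*
SD) therefore inflates the match probability with scale.  Because the
samples are independent, the SampEn conditional probability reduces to
a single pairwise probability independent of the embedding dimension:

    SampEn(tau, r) = -log P(|xi - eta| <= r),   xi, eta ~ N(0, 1/tau) iid
                   = -log erf(r * sqrt(tau) / 2)

(the difference of two independent N(0, 1/tau) variables has SD
sqrt(2/tau)).  The module exposes both this closed form and a literal
2-D adaptive-quadrature evaluation of the underlying double integral;
their agreement to 1e-6 over a (tau, r) grid is the module's core
correctness test.  All entropies are in nats.
"""

from __future__ import annotations

import math

from scipy import integrate, special

from .exceptions import DomainError, QuadratureError

__all__ = ["sd_at_scale", "shannon_entropy_gaussian_at_scale",
           "theoretical_sampen_gaussian", "quadrature_sampen_oracle",
           "predicted_bias", "entropy_in_base"]


def _check_tau(tau: int) -> int:
    if int(tau) < 1:
        raise DomainError(f"scale tau must be >= 1, got {tau}")
    return int(tau)


def sd_at_scale(sigma0: float, tau: int) -> float:
    """SD of a block-mean over tau iid samples: sigma0 / sqrt(tau)."""
    tau = _check_tau(tau)
    if not (sigma0 > 0):
        raise DomainError(f"sigma0 must be > 0, got {sigma0}")
    return float(sigma0) / math.sqrt(tau)


def shannon_entropy_gaussian_at_scale(tau: int) -> float:
    """Differential Shannon entropy (nats) of N(0, 1/tau): 0.5*log(2*pi/tau) + 0.5."""
    tau = _check_tau(tau)
    return 0.5 * math.log(2.0 * math.pi / tau) + 0.5


def theoretical_sampen_gaussian(tau: int, r_factor: float) -> float:
    """Closed-form SampEn of coarse-grained unit Gaussian noise at scale tau.

    ``r_factor`` is the tolerance in units of the original (scale-1)
    SD.  Independent of the embedding dimension m.  Depends on
    (tau, r_factor) only through the product r_factor * sqrt(tau).
    """
    tau = _check_tau(tau)
    if not (r_factor > 0):
        raise DomainError(f"r_factor must be > 0, got {r_factor}")
    return float(-math.log(special.erf(r_factor * math.sqrt(tau) / 2.0)))


def quadrature_sampen_oracle(tau: int, r_factor: float, tol: float = 1e-8) -> float:
    """The same quantity by literal 2-D adaptive quadrature (no erf shortcut).

    Evaluates -log[(1/2pi) * int_-inf^inf int_{t - r*sqrt(tau)}^{t + r*sqrt(tau)}
    exp(-(s^2 + t^2)/2) ds dt].  ``tol`` bounds the absolute error of
    the returned entropy and must lie in (0, 1e-4].
    """
    tau = _check_tau(tau)
    if not (r_factor > 0):
        raise DomainError(f"r_factor must be > 0, got {r_factor}")
    if not (0.0 < tol <= 1e-4):
        raise DomainError(f"tol must lie in (0, 1e-4], got {tol}")
    half_width = r_factor * math.sqrt(tau)
    norm = 1.0 / (2.0 * math.pi)

    def integrand(s: float, t: float) -> float:
        return norm * math.exp(-(s * s + t * t) / 2.0)

    prob, abserr = integrate.dblquad(
        integrand, -math.inf, math.inf,
        lambda t: t - half_width, lambda t: t + half_width,
        epsabs=1e-12, epsrel=1e-11)
    if not (0.0 < prob <= 1.0 + 1e-9):
        raise QuadratureError(
            f"quadrature returned invalid probability {prob} (abserr {abserr})")
    # error of -log(p) is approximately abserr / p
    if abserr / prob > tol:
        raise QuadratureError(
            f"quadrature error {abserr / prob:.3e} exceeds tol {tol:.3e} "
            f"(tau={tau}, r={r_factor})")
    return float(-math.log(min(prob, 1.0)))


def predicted_bias(tau: int, r_factor: float) -> float:
    """Systematic fixed-threshold bias at scale tau for unit Gaussian input.

    The entropy deficit relative to scale 1:
    ``theoretical_sampen_gaussian(1, r) - theoretical_sampen_gaussian(tau, r)``.
    Zero at tau = 1 and strictly increasing in tau.
    """
    return theoretical_sampen_gaussian(1, r_factor) - theoretical_sampen_gaussian(tau, r_factor)


def entropy_in_base(value_nats: float, base: float) -> float:
    """Convert an entropy from nats to logarithm base ``base``."""
    if not (base > 0) or base == 1.0:
        raise DomainError(f"log base must be positive and != 1, got {base}")
    return value_nats / math.log(base)
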