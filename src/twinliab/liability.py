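"""Numerics of the liability-threshold model.

A binary trait is modelled as the dichotomization of a latent standard-normal
"liability": an individual is affected when the liability exceeds a threshold
tau, so the trait prevalence fixes tau via ``Phi(tau) = 1 - prevalence``.  For
a twin pair the two liabilities are standard bivariate normal with correlation
rho, and the 2x2 table of joint outcomes has cell probabilities given by
bivariate-normal orthant integrals.  Everything downstream (tetrachoric
correlations, the ACE maximum-likelihood machinery) is built on the three
primitives in this module:

* :func:`threshold_from_prevalence` -- normal quantile of the threshold,
* :func:`bvn_upper_tail` -- ``P(X > t1, Y > t2)`` to ~1e-14 absolute accuracy,
* :func:`cell_probabilities` -- the four joint-outcome probabilities.

:func:`falconer_decompose` implements the classical moment decomposition of
MZ/DZ correlations into additive-genetic (A), shared-environment (C) and
unique-environment (E) variance shares; it is used as an algebraic cross-check
of the likelihood-based fits, not as an estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import norm

__all__ = [
    "threshold_from_prevalence",
    "bvn_upper_tail",
    "bvn_density",
    "bvn_upper_tail_grad",
    "CellProbs",
    "cell_probabilities",
    "FalconerComponents",
    "falconer_decompose",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)
_INV_SQRT2 = 1.0 / math.sqrt(2.0)


def _phi(x: float) -> float:
    return math.exp(-0.5 * x * x) / _SQRT_2PI


def _phi_bar(x: float) -> float:
    # Upper-tail standard normal via erfc; much cheaper than scipy here.
    return 0.5 * math.erfc(x * _INV_SQRT2)

# Gauss-Legendre rule for the arcsine-form integral (smooth for |rho|<=0.925).
_GL_X, _GL_W = np.polynomial.legendre.leggauss(20)

# Tanh-sinh (double-exponential) rule on (0, 1) for the near-singular tail
# form used when |rho| > 0.925.  Node density near 0 handles the essential
# singularity exp(-c/x^2) of the integrand.
_TS_H = 0.05
_TS_T = np.arange(-84, 85) * _TS_H
_TS_U = 0.5 * math.pi * np.sinh(_TS_T)
_TS_X = 0.5 * (1.0 + np.tanh(_TS_U))
_TS_W = _TS_H * 0.25 * math.pi * np.cosh(_TS_T) / np.cosh(_TS_U) ** 2
_keep = (_TS_X > 1e-280) & (_TS_X < 1.0 - 1e-16) & (_TS_W > 1e-280)
_TS_X = _TS_X[_keep]
_TS_W = _TS_W[_keep]


def threshold_from_prevalence(prev: float) -> float:
    """Liability threshold tau with ``Phi(tau) = 1 - prev``.

    Parameters
    ----------
    prev : float
        Trait prevalence, strictly inside (0, 1).
    """
    if not 0.0 < prev < 1.0:
        raise ValueError(f"prevalence must lie in (0, 1), got {prev!r}")
    return float(norm.isf(prev))


def _bvn_arcsine(t1: float, t2: float, rho: float) -> float:
    """Upper-tail probability via the arcsine-form single integral.

    P(X>t1, Y>t2) = Phibar(t1) Phibar(t2)
                    + (1/2pi) Int_0^{asin rho} exp(-(t1^2 - 2 t1 t2 sin u
                      + t2^2) / (2 cos^2 u)) du
    """
    asr = math.asin(rho)
    theta = 0.5 * asr * (_GL_X + 1.0)
    sn = np.sin(theta)
    cs2 = 1.0 - sn * sn
    integrand = np.exp(-(t1 * t1 - 2.0 * t1 * t2 * sn + t2 * t2) / (2.0 * cs2))
    integral = 0.5 * asr * float(integrand @ _GL_W)
    return _phi_bar(t1) * _phi_bar(t2) + integral / (2.0 * math.pi)


def _bvn_tail(t1: float, t2: float, rho: float) -> float:
    """Upper-tail probability for rho close to +1 (rho > 0 required).

    Integrates d P / d rho from the comonotone limit:
    P = Phibar(max(t1,t2))
        - (1/2pi) Int_0^s exp(-(t1-t2)^2/(2 x^2) - t1 t2/(1+sqrt(1-x^2)))
          / sqrt(1-x^2) dx,       s = sqrt(1-rho^2).
    """
    s = math.sqrt(max(0.0, (1.0 - rho) * (1.0 + rho)))
    if s == 0.0:
        return _phi_bar(max(t1, t2))
    bs = (t1 - t2) ** 2
    hk = t1 * t2
    x = s * _TS_X
    w = s * _TS_W
    r1 = np.sqrt(1.0 - x * x)
    with np.errstate(divide="ignore", over="ignore"):
        expo = -bs / (2.0 * x * x) - hk / (1.0 + r1)
    integrand = np.where(expo < -745.0, 0.0, np.exp(np.maximum(expo, -745.0)) / r1)
    integral = float(integrand @ w)
    return _phi_bar(max(t1, t2)) - integral / (2.0 * math.pi)


def bvn_upper_tail(t1: float, t2: float, rho: float) -> float:
    """``P(X > t1, Y > t2)`` for standard bivariate normal (X, Y), corr rho.

    Accuracy is ~1e-14 absolute over rho in (-1, 1); the degenerate limits
    rho = +-1 (within 1e-12) short-circuit to their closed forms.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {rho!r}")
    if math.isinf(t1) or math.isinf(t2):
        if t1 == math.inf or t2 == math.inf:
            return 0.0
        if t1 == -math.inf:
            return 1.0 if t2 == -math.inf else _phi_bar(t2)
        return _phi_bar(t1)
    if rho >= 1.0 - 1e-12:
        return _phi_bar(max(t1, t2))
    if rho <= -1.0 + 1e-12:
        # Y = -X: need X > t1 and X < -t2.
        return max(0.0, _phi_bar(-t2) - _phi_bar(t1))
    if abs(rho) <= 0.925:
        p = _bvn_arcsine(t1, t2, rho)
    elif rho > 0.0:
        p = _bvn_tail(t1, t2, rho)
    else:
        # reflection Y -> -Y: P(X>t1, Y>t2; rho) = Phibar(t1) - P(X>t1, Y'>-t2; -rho)
        p = _phi_bar(t1) - _bvn_tail(t1, -t2, -rho)
    return min(1.0, max(0.0, p))


def bvn_density(t1: float, t2: float, rho: float) -> float:
    """Standard bivariate normal density at (t1, t2) with correlation rho."""
    omr2 = (1.0 - rho) * (1.0 + rho)
    z = (t1 * t1 - 2.0 * rho * t1 * t2 + t2 * t2) / omr2
    return math.exp(-0.5 * z) / (2.0 * math.pi * math.sqrt(omr2))


def bvn_upper_tail_grad(t1: float, t2: float, rho: float):
    """Upper-tail probability and its partial derivatives.

    Returns ``(p, dp/dt1, dp/dt2, dp/drho)``.  The derivatives have closed
    forms: differentiating under the integral gives
    ``dp/dt1 = -phi(t1) * Phibar((t2 - rho t1)/sqrt(1-rho^2))`` (and
    symmetrically for t2), while Plackett's identity gives
    ``dp/drho = phi2(t1, t2; rho)``, the bivariate density.
    """
    p = bvn_upper_tail(t1, t2, rho)
    sr = math.sqrt((1.0 - rho) * (1.0 + rho))
    d1 = -_phi(t1) * _phi_bar((t2 - rho * t1) / sr)
    d2 = -_phi(t2) * _phi_bar((t1 - rho * t2) / sr)
    dr = bvn_density(t1, t2, rho)
    return p, d1, d2, dr


@dataclass(frozen=True)
class CellProbs:
    """Joint-outcome probabilities for a twin pair.

    ``p11`` both affected, ``p10`` twin 1 affected only, ``p01`` twin 2
    affected only, ``p00`` neither.
    """

    p11: float
    p10: float
    p01: float
    p00: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p11, self.p10, self.p01, self.p00])


def cell_probabilities(t1: float, t2: float, rho: float) -> CellProbs:
    """Four joint-outcome probabilities at thresholds (t1, t2), corr rho.

    Margins are consistent by construction:
    ``p11 + p10 = Phibar(t1)`` and ``p11 + p01 = Phibar(t2)``.
    """
    p11 = bvn_upper_tail(t1, t2, rho)
    m1 = _phi_bar(t1)
    m2 = _phi_bar(t2)
    p10 = max(0.0, m1 - p11)
    p01 = max(0.0, m2 - p11)
    p00 = max(0.0, 1.0 - m1 - m2 + p11)
    return CellProbs(p11=p11, p10=p10, p01=p01, p00=p00)


class FalconerComponents(NamedTuple):
    """Moment-based variance shares; ``admissible`` is False when any share
    falls outside [0, 1] (the algebra is reported untruncated)."""

    A: float
    C: float
    E: float
    admissible: bool


def falconer_decompose(r_mz: float, r_dz: float) -> FalconerComponents:
    """Classical decomposition A = 2(rMZ - rDZ), C = 2 rDZ - rMZ, E = 1 - rMZ.

    Valid as a moment identity for any pair of correlations with
    ``-1 <= r_dz <= r_mz <= 1``; components may leave [0, 1] and are then
    flagged rather than truncated (truncation is a model-fitting concern).
    """
    if not (-1.0 <= r_dz <= r_mz <= 1.0):
        raise ValueError("require -1 <= r_dz <= r_mz <= 1")
    a = 2.0 * (r_mz - r_dz)
    c = 2.0 * r_dz - r_mz
    e = 1.0 - r_mz
    ok = all(0.0 <= x <= 1.0 for x in (a, c, e))
    return FalconerComponents(A=a, C=c, E=e, admissible=ok)
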