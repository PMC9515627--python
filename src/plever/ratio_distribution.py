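"""Distribution of the protein share of energy under a bivariate-normal intake model.

When protein energy ``U`` and non-protein energy ``V`` are jointly normal,
total energy is ``Z = U + V`` and the protein share ``W = U / Z`` is the
ratio of two correlated normal variables.  Its exact density involves
Kummer's confluent hypergeometric function ``M(a, b, z)`` (Pham-Gia form);
an algebraically equivalent expression uses the error function (Hinkley
form).  This module evaluates that density, the density of ``log W``
obtained by change of variables, and moments of either by adaptive
quadrature on a truncated support.

The ratio of normals has unbounded support, but when the coefficients of
variation of ``U`` and ``Z`` are small (intakes many standard deviations
above zero) virtually all mass lies in a narrow interval around
``mu_U / mu_Z``.  Densities here carry explicit support bounds enclosing at
least ``1 - 1e-9`` of probability, located by expanding outward from the
central ratio, and all quadrature is performed on that interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import integrate, special

__all__ = [
    "Model1Params",
    "Density",
    "MomentSet",
    "kummer_M",
    "proportion_density",
    "density_moments",
    "log_transform_density",
    "truncate_density",
]

#: mass allowed outside a Density's declared support
TAIL_MASS = 1e-9
#: tolerance on the normalization of a Density over its support
NORM_TOL = 1e-5
#: argument above which kummer_M applies the Kummer transformation
KUMMER_TRANSFORM_AT = 50.0


@dataclass(frozen=True)
class Model1Params:
    """Means, SDs and correlation of protein (U) and non-protein (V) energy intake.

    Units are kJ throughout.  A warning is emitted when either coefficient
    of variation reaches 0.5: the normal model then places non-negligible
    mass on negative intakes and the bounded-support treatment of the
    share distribution degrades.
    """

    mu_U: float
    mu_V: float
    sigma_U: float
    sigma_V: float
    rho_UV: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu_U", "mu_V", "sigma_U", "sigma_V"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        if not -1.0 <= self.rho_UV <= 1.0:
            raise ValueError(f"rho_UV must lie in [-1, 1], got {self.rho_UV!r}")
        cv_u = self.sigma_U / self.mu_U
        cv_v = self.sigma_V / self.mu_V
        if cv_u >= 0.5 or cv_v >= 0.5:
            warnings.warn(
                f"coefficient of variation outside the well-posed regime "
                f"(CV_U={cv_u:.3f}, CV_V={cv_v:.3f}; both should be < 0.5): "
                f"normal intake mass below zero is no longer negligible",
                RuntimeWarning,
                stacklevel=3,
            )

    @property
    def sigma_UV(self) -> float:
        """Covariance of U and V (kJ^2)."""
        return self.rho_UV * self.sigma_U * self.sigma_V


@dataclass(frozen=True)
class MomentSet:
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError(f"variance must be non-negative, got {self.variance!r}")

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class Density:
    """A univariate density with explicit support bounds and a quadrature contract.

    ``pdf`` must be vectorized over numpy arrays.  ``[support_lo,
    support_hi]`` encloses at least ``1 - 1e-9`` of probability, and the
    integral of ``pdf`` over it must equal 1 within ``1e-5``.
    """

    pdf: Callable[[np.ndarray], np.ndarray]
    support_lo: float
    support_hi: float
    tol: float = 1e-8

    def integral(self) -> float:
        """Total mass on the declared support."""
        val, _ = _quad(self.pdf, self.support_lo, self.support_hi, self.tol)
        return val

    def validate(self) -> "Density":
        total = self.integral()
        if abs(total - 1.0) > NORM_TOL:
            raise RuntimeError(
                f"density fails to normalize on [{self.support_lo}, {self.support_hi}]: "
                f"integral = {total!r} (|integral - 1| > {NORM_TOL})"
            )
        return self

    def cdf_interpolant(self, n: int = 4097) -> Callable[[np.ndarray], np.ndarray]:
        """Piecewise-linear CDF built from a dense cumulative-trapezoid grid."""
        grid = np.linspace(self.support_lo, self.support_hi, n)
        dens = np.asarray(self.pdf(grid), dtype=float)
        cum = integrate.cumulative_trapezoid(dens, grid, initial=0.0)
        cum /= cum[-1]

        def cdf(x: np.ndarray) -> np.ndarray:
            return np.interp(x, grid, cum, left=0.0, right=1.0)

        return cdf

    def to_frame(self, n: int = 512) -> pd.DataFrame:
        """(grid, pdf) table for serialization/debugging."""
        grid = np.linspace(self.support_lo, self.support_hi, n)
        return pd.DataFrame({"x": grid, "pdf": np.asarray(self.pdf(grid), dtype=float)})

    def to_csv(self, path, n: int = 512) -> None:
        self.to_frame(n).to_csv(path, index=False)


def _quad(f, lo: float, hi: float, tol: float) -> tuple[float, float]:
    """Adaptive quadrature with an explicit accuracy contract.

    Returns (value, error bound); raises if the estimated error exceeds a
    usable bound, reporting the estimate so the caller can diagnose.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(f, lo, hi, epsabs=tol, epsrel=tol, limit=400)
    if err > max(1e4 * tol, 1e-6 * max(1.0, abs(val))):
        raise RuntimeError(
            f"quadrature on [{lo}, {hi}] did not converge: estimate {val!r}, error bound {err!r}"
        )
    return val, err


def kummer_M(theta: float, gamma: float, zeta: float) -> float:
    """Kummer's confluent hypergeometric function of the first kind, M(theta, gamma, zeta).

    Defined by the series ``sum_k (theta)_k / (gamma)_k * zeta^k / k!``.
    For ``zeta > 50`` the Kummer transformation
    ``M(theta, gamma, zeta) = e^zeta * M(gamma - theta, gamma, -zeta)`` is
    applied, which keeps the alternating series out of the evaluation.
    Overflow is raised, never returned as a silent infinity.
    """
    if gamma == 0 or (gamma < 0 and float(gamma).is_integer()):
        raise ValueError(f"gamma must not be zero or a negative integer, got {gamma!r}")
    if zeta > KUMMER_TRANSFORM_AT:
        try:
            scale = math.exp(zeta)
        except OverflowError:
            raise OverflowError(
                f"kummer_M({theta}, {gamma}, {zeta}) overflows double precision"
            ) from None
        value = scale * float(special.hyp1f1(gamma - theta, gamma, -zeta))
    else:
        value = float(special.hyp1f1(theta, gamma, zeta))
    if not math.isfinite(value):
        raise OverflowError(f"kummer_M({theta}, {gamma}, {zeta}) overflows double precision")
    return value


def _log_M_1_half(z: np.ndarray) -> np.ndarray:
    """log M(1, 1/2, z) for z >= 0, stable for arbitrarily large z.

    Uses the closed form M(1, 1/2, z) = 1 + sqrt(pi z) e^z erf(sqrt z),
    evaluated on the log scale so the e^z factor never overflows.
    """
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    small = z < KUMMER_TRANSFORM_AT
    if np.any(small):
        out[small] = np.log(special.hyp1f1(1.0, 0.5, z[small]))
    if np.any(~small):
        zl = z[~small]
        tail = zl + 0.5 * np.log(np.pi * zl) + np.log(special.erf(np.sqrt(zl)))
        out[~small] = np.logaddexp(0.0, tail)
    return out


def _uz_moments(params: Model1Params) -> tuple[float, float, float, float]:
    """(mu_Z, sigma_Z, sigma_UZ, rho_UZ) of total energy Z = U + V."""
    mu_Z = params.mu_U + params.mu_V
    var_Z = params.sigma_U**2 + params.sigma_V**2 + 2.0 * params.sigma_UV
    sigma_Z = math.sqrt(var_Z)
    sigma_UZ = params.sigma_U**2 + params.sigma_UV
    rho_UZ = sigma_UZ / (params.sigma_U * sigma_Z)
    return mu_Z, sigma_Z, sigma_UZ, rho_UZ


def proportion_density(params: Model1Params) -> Density:
    """Exact density of the protein share W = U / (U + V) for bivariate-normal (U, V).

    Assembled from the ratio-of-correlated-normals density of U/Z with
    Z = U + V: a normalizing factor, an exponential kernel and Kummer's
    function M(1, 1/2, .) evaluated on the log scale.  Support bounds are
    found by expanding outward from mu_U / mu_Z until the enclosed mass
    reaches ``1 - 1e-9``; the result is checked to normalize within
    ``1e-5`` and a failure is reported with the achieved integral.
    """
    mu_U, sigma_U = params.mu_U, params.sigma_U
    mu_Z, sigma_Z, sigma_UZ, rho_UZ = _uz_moments(params)
    one_m_rho2 = max(1.0 - rho_UZ**2, 1e-300)
    var_U, var_Z = sigma_U**2, sigma_Z**2
    # constant part of the exponent: (sigma_Z^2 mu_U^2 - 2 sigma_UZ mu_U mu_Z + sigma_U^2 mu_Z^2)
    c_num = var_Z * mu_U**2 - 2.0 * sigma_UZ * mu_U * mu_Z + var_U * mu_Z**2
    c_exp = c_num / (2.0 * var_U * var_Z * one_m_rho2)
    log_pref = math.log(sigma_U * sigma_Z) + 0.5 * math.log(one_m_rho2) - math.log(math.pi)

    def pdf(w: np.ndarray) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        den = var_Z * w**2 - 2.0 * sigma_UZ * w + var_U  # positive definite for |rho_UZ| < 1
        num = var_Z * mu_U * w - sigma_UZ * (mu_Z * w + mu_U) + var_U * mu_Z
        theta = num**2 / (2.0 * var_U * var_Z * one_m_rho2 * den)
        return np.exp(log_pref - np.log(den) - c_exp + _log_M_1_half(theta))

    # delta-method scale of W sets the initial bracket
    var_W_approx = (var_U * mu_Z**2 - 2.0 * sigma_UZ * mu_U * mu_Z + var_Z * mu_U**2) / mu_Z**4
    s = math.sqrt(max(var_W_approx, 1e-12))
    center = mu_U / mu_Z
    lo, hi = center - 8.0 * s, center + 8.0 * s
    # grow while the next outer band still carries non-negligible mass; the
    # near-Gaussian decay of the ratio density makes the remaining tail well
    # below TAIL_MASS once a 4-sigma band drops under TAIL_MASS / 4
    for _ in range(64):
        add_lo, _ = _quad(pdf, lo - 4.0 * s, lo, 1e-13)
        add_hi, _ = _quad(pdf, hi, hi + 4.0 * s, 1e-13)
        grew = False
        if add_lo > TAIL_MASS / 4.0:
            lo -= 4.0 * s
            grew = True
        if add_hi > TAIL_MASS / 4.0:
            hi += 4.0 * s
            grew = True
        if not grew:
            break
    else:
        raise RuntimeError(
            f"support search failed to locate 1 - {TAIL_MASS} of mass within "
            f"[{lo}, {hi}] (tails decay too slowly for the truncation convention)"
        )
    return Density(pdf=pdf, support_lo=lo, support_hi=hi, tol=1e-8).validate()


def truncate_density(d: Density, lo: float, hi: float) -> Density:
    """Condition a density on the interval [lo, hi] (truncate and renormalize).

    Used to restrict the normal-model share distribution to (0, 1): mass
    outside corresponds to a negative simulated intake, which intake data
    cannot contain and which simulation protocols exclude.
    """
    lo = max(lo, d.support_lo)
    hi = min(hi, d.support_hi)
    if not hi > lo:
        raise ValueError(f"empty truncation interval [{lo}, {hi}]")
    mass, _ = _quad(d.pdf, lo, hi, d.tol)
    if mass <= 0:
        raise ValueError(f"no mass on truncation interval [{lo}, {hi}]")

    def pdf(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        inside = (x >= lo) & (x <= hi)
        return np.where(inside, np.asarray(d.pdf(x), dtype=float) / mass, 0.0)

    return Density(pdf=pdf, support_lo=lo, support_hi=hi, tol=d.tol)


def density_moments(d: Density) -> MomentSet:
    """Mean and variance of a density by adaptive quadrature at its tolerance."""
    mean, _ = _quad(lambda x: x * d.pdf(x), d.support_lo, d.support_hi, d.tol)
    var, _ = _quad(lambda x: (x - mean) ** 2 * d.pdf(x), d.support_lo, d.support_hi, d.tol)
    return MomentSet(mean=mean, variance=max(var, 0.0))


def log_transform_density(d: Density) -> Density:
    """Density of X = log W from the density of W, by change of variables.

    f_X(x) = f_W(e^x) e^x.  The input must be supported on (0, inf) up to
    the 1e-9 tail-mass convention; mass at or below zero beyond that
    tolerance is an error naming the offending amount.
    """
    lo = d.support_lo
    if lo <= 0.0:
        below, _ = _quad(d.pdf, lo, 0.0, d.tol)
        if below > TAIL_MASS:
            raise ValueError(
                f"support touches zero: mass {below!r} at or below 0 exceeds "
                f"the {TAIL_MASS} tail tolerance; log transform undefined"
            )
        # negligible mass below zero: truncate just above it
        lo = min(1e-12, d.support_hi / 2.0)

    def pdf(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        ex = np.exp(x)
        return np.asarray(d.pdf(ex), dtype=float) * ex

    return Density(
        pdf=pdf, support_lo=math.log(lo), support_hi=math.log(d.support_hi), tol=d.tol
    ).validate()
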