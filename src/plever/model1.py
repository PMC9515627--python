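"""Expected leverage coefficient E(L) under the no-leverage null (Model 1).

Protein and non-protein intake are modelled as a bivariate normal with no
causal link between them; the question is what slope a log-log regression
of total energy on protein share is *expected* to return purely from the
joint distribution of intakes.  The answer is

    E(L) = sigma_XY / sigma_X^2,
    sigma_XY = log(1 + sigma_WZ / (mu_W mu_Z)),
    sigma_WZ = mu_U - mu_W mu_Z,

where (mu_W, sigma_X^2) are moments of the protein share W and its log X,
computed exactly from the ratio-of-correlated-normals density, and the
log-scale covariance sigma_XY comes from the standard first-order Taylor
approximation for covariances of logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ratio_distribution import (
    Model1Params,
    density_moments,
    log_transform_density,
    proportion_density,
    truncate_density,
)

#: lower share bound used when conditioning the share density on (0, 1);
#: the log-moment integrands vanish like x^2 e^x below it
_SHARE_FLOOR = 1e-6

__all__ = [
    "EnergyMoments",
    "LeverageNull",
    "energy_moments",
    "expected_leverage",
    "leverage_grid",
    "params_from_share",
    "GRID_MODES",
]

GRID_MODES = ("constant_variance", "constant_ID", "free_IDR")


@dataclass(frozen=True)
class EnergyMoments:
    """Closed-form moments of total energy Z = U + V and its link to protein intake."""

    mu_Z: float
    sigma_Z: float
    sigma_UZ: float
    rho_UZ: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho_UZ <= 1.0 + 1e-12:
            raise ValueError(f"rho_UZ out of [-1, 1]: {self.rho_UZ!r}")


@dataclass(frozen=True)
class LeverageNull:
    """Expected-leverage summary under the no-leverage null.

    ``expected_L`` is a population expectation (not an estimate, hence no
    standard error); its sign always matches ``sigma_WZ`` because
    log(1 + x) preserves sign.
    """

    sigma_WZ: float
    rho_WZ: float
    sigma_XY: float
    expected_L: float
    mu_W: float
    sigma_W2: float
    sigma_X2: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.expected_L):
            raise ValueError(f"expected_L is not finite: {self.expected_L!r}")


def energy_moments(params: Model1Params) -> EnergyMoments:
    """Moments of total energy from the intake parameters; exact arithmetic."""
    mu_Z = params.mu_U + params.mu_V
    var_Z = params.sigma_U**2 + params.sigma_V**2 + 2.0 * params.sigma_UV
    sigma_Z = math.sqrt(var_Z)
    sigma_UZ = params.sigma_U**2 + params.sigma_UV
    rho_UZ = sigma_UZ / (params.sigma_U * sigma_Z)
    return EnergyMoments(mu_Z=mu_Z, sigma_Z=sigma_Z, sigma_UZ=sigma_UZ, rho_UZ=rho_UZ)


def expected_leverage(params: Model1Params) -> LeverageNull:
    """Expected slope of the log-log leverage regression under the null.

    Raises a domain error when the Taylor covariance's log argument
    ``1 + sigma_WZ / (mu_W mu_Z)`` is non-positive.
    """
    em = energy_moments(params)
    d_w = proportion_density(params)
    # sigma_WZ = E[U] - E[W]E[Z] is an identity in the *unconditional*
    # moments, so the mean of W is taken over the full ratio density
    mom_w = density_moments(d_w)
    if d_w.support_lo <= 0.0 or d_w.support_hi >= 1.0:
        # log moments require W in (0, 1); mass outside corresponds to a
        # negative intake, excluded the way simulation protocols exclude
        # negative draws
        d_w_pos = truncate_density(d_w, _SHARE_FLOOR, 1.0 - _SHARE_FLOOR)
    else:
        d_w_pos = d_w
    d_x = log_transform_density(d_w_pos)
    mom_x = density_moments(d_x)

    sigma_WZ = params.mu_U - mom_w.mean * em.mu_Z
    rho_WZ = sigma_WZ / (mom_w.sd * em.sigma_Z)
    ratio = sigma_WZ / (mom_w.mean * em.mu_Z)
    if ratio <= -1.0:
        raise ValueError(
            f"log-scale covariance undefined: sigma_WZ/(mu_W*mu_Z) = {ratio!r} <= -1 "
            f"for params {params!r}"
        )
    sigma_XY = math.log1p(ratio)
    return LeverageNull(
        sigma_WZ=sigma_WZ,
        rho_WZ=rho_WZ,
        sigma_XY=sigma_XY,
        expected_L=sigma_XY / mom_x.variance,
        mu_W=mom_w.mean,
        sigma_W2=mom_w.variance,
        sigma_X2=mom_x.variance,
    )


def params_from_share(
    share: float,
    mode: str,
    *,
    rho_UV: float = 0.0,
    totals: float = 8700.0,
    sigma_const: float = 500.0,
    id_const: float = 100.0,
    id_V: float = 125.0,
    idr: float | None = None,
) -> Model1Params:
    """Intake parameters for a given protein share under one of three variance regimes.

    - ``constant_variance``: sigma_U = sigma_V = ``sigma_const`` regardless of share.
    - ``constant_ID``: both nutrients share the index of dispersion ``id_const``.
    - ``free_IDR``: ID_V = ``id_V`` and ID_U = ``idr * id_V``.

    Shares are clipped to [0.01, 0.99] (degenerate 0/1 shares make the log
    undefined).
    """
    if mode not in GRID_MODES:
        raise ValueError(f"mode must be one of {GRID_MODES}, got {mode!r}")
    share = float(np.clip(share, 0.01, 0.99))
    mu_U = share * totals
    mu_V = totals - mu_U
    if mode == "constant_variance":
        sigma_U = sigma_V = sigma_const
    elif mode == "constant_ID":
        sigma_U = math.sqrt(id_const * mu_U)
        sigma_V = math.sqrt(id_const * mu_V)
    else:
        if idr is None:
            raise ValueError("mode 'free_IDR' requires an idr value")
        sigma_U = math.sqrt(idr * id_V * mu_U)
        sigma_V = math.sqrt(id_V * mu_V)
    return Model1Params(mu_U=mu_U, mu_V=mu_V, sigma_U=sigma_U, sigma_V=sigma_V, rho_UV=rho_UV)


def leverage_grid(
    share_grid: Sequence[float],
    idr_grid: Sequence[float] | None,
    rho_grid: Sequence[float],
    mode: str,
    totals: float = 8700.0,
    **mode_kwargs,
) -> pd.DataFrame:
    """Expected leverage over a (share, IDR, rho) grid.

    One row per grid point with columns ``(protein_share, idr, rho_uv,
    expected_L, flag)``; ``idr`` records the realized ID_U/ID_V of the
    parameterization.  Points where the log-scale covariance is undefined
    are flagged ``log_undefined`` rather than dropped.
    """
    if mode not in GRID_MODES:
        raise ValueError(f"mode must be one of {GRID_MODES}, got {mode!r}")
    if len(share_grid) == 0 or len(rho_grid) == 0:
        raise ValueError("share and rho grids must be non-empty")
    idr_values: Iterable[float | None]
    if mode == "free_IDR":
        if idr_grid is None or len(idr_grid) == 0:
            raise ValueError("mode 'free_IDR' requires a non-empty idr grid")
        idr_values = list(idr_grid)
    else:
        idr_values = [None]

    rows = []
    for share in share_grid:
        for idr in idr_values:
            for rho in rho_grid:
                p = params_from_share(
                    share, mode, rho_UV=rho, totals=totals, idr=idr, **mode_kwargs
                )
                realized_idr = (p.sigma_U**2 / p.mu_U) / (p.sigma_V**2 / p.mu_V)
                flag = ""
                try:
                    value = expected_leverage(p).expected_L
                except ValueError:
                    value, flag = np.nan, "log_undefined"
                rows.append(
                    {
                        "protein_share": share,
                        "idr": realized_idr,
                        "rho_uv": rho,
                        "expected_L": value,
                        "flag": flag,
                    }
                )
    return pd.DataFrame(rows)
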