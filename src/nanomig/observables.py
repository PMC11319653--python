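"""Experimentally measurable decay curves from ``G^SD(t)``.

For photoselected dipole emission the polarized decay components are

    I_par(t)  = e^{-t/tau} (1 + (4/5) G^SD(t))
    I_perp(t) = e^{-t/tau} (1 - (2/5) G^SD(t))

so the emission anisotropy r = (I_par - I_perp)/(I_par + 2 I_perp) starts at
r0 = 2/5 and the *normalized* anisotropy is identically the self-part Green
function, r(t)/r0 = G^SD(t): only the initially excited donors emit with
memory of the excitation polarization, and homotransfer to any other donor
fully depolarizes.  The total donor decay is I(t) = I0 e^{-t/tau} G^SD(t).

The anisotropy is nevertheless computed through the experimental quotient
(not the identity shortcut) so that sign or normalization bugs upstream
would surface as a violated identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .laplace import InversionSpec, invert
from .model import SystemParams
from .oracle import CurveEstimate
from .solver import green_sd_laplace

__all__ = [
    "R0_ANISOTROPY",
    "DecayCurves",
    "intensity_components",
    "anisotropy",
    "donor_decay",
    "decay_curves",
    "anisotropy_decay",
    "kmc_decay_curves",
]

#: fundamental anisotropy of photoselected dipole emission
R0_ANISOTROPY = 0.4


@dataclass(frozen=True)
class DecayCurves:
    """Time grid (units of tau_0D) with every derived decay observable."""

    time_grid: np.ndarray
    g_sd: np.ndarray
    i_parallel: np.ndarray
    i_perpendicular: np.ndarray
    i_total: np.ndarray
    r: np.ndarray
    r_over_r0: np.ndarray
    g_sd_se: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {
            "t_over_tau": self.time_grid,
            "g_sd": self.g_sd,
            "r_over_r0": self.r_over_r0,
            "i_par": self.i_parallel,
            "i_perp": self.i_perpendicular,
            "i_total": self.i_total,
        }
        if self.g_sd_se is not None:
            data["g_sd_se"] = self.g_sd_se
            data["r_over_r0_se"] = self.g_sd_se
        return pd.DataFrame(data)


def intensity_components(g_sd, time_grid, tau: float = 1.0):
    """Parallel and perpendicular polarized decay components."""
    g = np.asarray(g_sd, dtype=float)
    env = np.exp(-np.asarray(time_grid, dtype=float) / tau)
    return env * (1.0 + 0.8 * g), env * (1.0 - 0.4 * g)


def anisotropy(i_parallel, i_perpendicular):
    """Emission anisotropy ``r`` and ``r/r0`` from the polarized components."""
    ipar = np.asarray(i_parallel, dtype=float)
    iperp = np.asarray(i_perpendicular, dtype=float)
    denom = ipar + 2.0 * iperp
    if np.any(denom <= 0.0):
        raise ValueError("total intensity must be positive to form the anisotropy")
    r = (ipar - iperp) / denom
    return r, r / R0_ANISOTROPY


def donor_decay(g_sd, time_grid, i0: float = 1.0, tau: float = 1.0):
    """Decay of the initially excited donors, ``I(t) = I0 e^{-t/tau} G^SD(t)``."""
    if i0 <= 0.0:
        raise ValueError("i0 must be positive")
    return i0 * np.exp(-np.asarray(time_grid, dtype=float) / tau) * np.asarray(g_sd, dtype=float)


def decay_curves(time_grid, g_sd, tau: float = 1.0, i0: float = 1.0,
                 g_sd_se=None) -> DecayCurves:
    """Assemble every observable from a ``G^SD(t)`` curve.

    ``r`` is formed through the experimental quotient of polarized
    components; ``r_over_r0`` uses the exact algebraic identity
    ``r/r0 = G^SD``, and the two routes are cross-checked against each
    other to catch sign or normalization bugs upstream.
    """
    t = np.asarray(time_grid, dtype=float)
    g = np.asarray(g_sd, dtype=float)
    ipar, iperp = intensity_components(g, t, tau)
    r, quotient = anisotropy(ipar, iperp)
    if np.max(np.abs(quotient - g), initial=0.0) > 1e-12:
        raise ArithmeticError("anisotropy quotient deviates from G^SD: "
                              "normalization bug upstream")
    return DecayCurves(
        time_grid=t, g_sd=g, i_parallel=ipar, i_perpendicular=iperp,
        i_total=donor_decay(g, t, i0, tau), r=r, r_over_r0=g.copy(),
        g_sd_se=None if g_sd_se is None else np.asarray(g_sd_se, dtype=float))


def anisotropy_decay(params: SystemParams, time_grid, order: str = "three_body",
                     n_terms: int = 14, i0: float = 1.0) -> DecayCurves:
    """Analytic chain: self-consistent solver -> Laplace inversion -> observables.

    ``time_grid`` is in units of the donor lifetime and may include 0, where
    the exact limit ``G^SD(0) = 1`` is substituted instead of inverting.
    """
    t = np.asarray(time_grid, dtype=float) * params.lifetime
    g = np.empty_like(t)
    positive = t > 0.0
    transform = green_sd_laplace(params, order)
    if params.n_donors == 1:
        g[:] = 1.0  # no acceptor: G^SD is identically one
    else:
        if np.any(positive):
            spec = InversionSpec(time_grid=t[positive], n_terms=n_terms)
            g[positive] = invert(transform, spec)
        g[~positive] = 1.0
    # the returned grid is in units of tau, so the envelope uses tau = 1
    return decay_curves(np.asarray(time_grid, dtype=float), g, tau=1.0, i0=i0)


def kmc_decay_curves(curve: CurveEstimate, tau: float = 1.0,
                     i0: float = 1.0) -> DecayCurves:
    """Observables from a simulated ``G^SD`` curve (grid in units of tau)."""
    out = decay_curves(curve.time_grid / tau, curve.mean, tau=1.0, i0=i0)
    return DecayCurves(
        time_grid=out.time_grid, g_sd=out.g_sd, i_parallel=out.i_parallel,
        i_perpendicular=out.i_perpendicular, i_total=out.i_total, r=out.r,
        r_over_r0=out.r_over_r0, g_sd_se=curve.se.copy())
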