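"""Self-consistent solution for the Laplace-domain Green function.

Probability conservation ties the self-part and cross-part Green functions
together through the closure

    eps * [ G^SD(eps) + G^DD(k=0, eps) ] = 1,

and topological reduction expresses ``G^DD`` through the loop- and
node-free diagram sum ``Sigma^DD``, giving

    G^SD(eps) = (1/eps) / (1 + Sigma^DD / (eps * (G^SD)^2)).

With the planar closed forms of :mod:`nanomig.diagrams` and the substitution
``x = (G^SD / tau)**(1/3)`` this becomes a cubic,

    x^3 + a2 x^2 + a1 x + a0 = 0,
    a2 = -(N-1)(N-2) C3 xi^4 / (eps tau)      (zero at two-body order)
    a1 =  (N-1) (2^(1/3) sqrt(3) pi / 36) xi^2 / (eps tau)
    a0 = -1 / (eps tau),

solved here by Cardano's formulas with an explicit admissibility contract
on the root (positive, ``eps * G^SD <= 1``) instead of blind evaluation, so
floating-point sign flips of the discriminant near parameter boundaries
cannot select an unphysical branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .diagrams import THREE_BODY_COEFFICIENT, TWO_BODY_PREFACTOR, sigma_total
from .model import SystemParams

__all__ = [
    "CubicCoefficients",
    "LaplaceGreenSD",
    "cubic_coefficients",
    "solve_cardano",
    "green_sd_laplace",
    "green_dd_laplace",
]


@dataclass(frozen=True)
class CubicCoefficients:
    """Coefficients of ``x^3 + a2 x^2 + a1 x + a0 = 0``, ``x = (G^SD/tau)^(1/3)``."""

    a2: float
    a1: float
    a0: float

    def residual(self, x: float) -> float:
        return ((x + self.a2) * x + self.a1) * x + self.a0


def cubic_coefficients(params: SystemParams, order: str, eps: float) -> CubicCoefficients:
    """Cubic coefficients at Laplace variable ``eps > 0``."""
    if eps <= 0.0:
        raise ValueError("eps must be positive")
    if order not in ("two_body", "three_body"):
        raise ValueError(f"unknown order {order!r}")
    n, xi = params.n_donors, params.xi
    et = eps * params.lifetime
    a2 = (-(n - 1) * (n - 2) * THREE_BODY_COEFFICIENT * xi ** 4 / et
          if order == "three_body" else 0.0)
    a1 = (n - 1) * TWO_BODY_PREFACTOR * xi ** 2 / et
    a0 = -1.0 / et
    return CubicCoefficients(a2=a2, a1=a1, a0=a0)


def _real_roots(c: CubicCoefficients) -> list[float]:
    """All real roots by Cardano / trigonometric formulas."""
    p = c.a1 - c.a2 ** 2 / 3.0
    q = 2.0 * c.a2 ** 3 / 27.0 - c.a2 * c.a1 / 3.0 + c.a0
    shift = -c.a2 / 3.0
    disc = (q / 2.0) ** 2 + (p / 3.0) ** 3
    if disc > 0.0:  # one real root
        s = math.sqrt(disc)
        return [math.cbrt(-q / 2.0 + s) + math.cbrt(-q / 2.0 - s) + shift]
    if p == 0.0:    # triple root
        return [math.cbrt(-q) + shift]
    # three real roots (possibly degenerate): trigonometric form
    r = 2.0 * math.sqrt(-p / 3.0)
    arg = 3.0 * q / (p * r)
    theta = math.acos(min(1.0, max(-1.0, arg)))
    return [r * math.cos((theta - 2.0 * math.pi * k) / 3.0) + shift for k in range(3)]


def solve_cardano(coeffs: CubicCoefficients, hint: float | None = None) -> float:
    """The admissible real root ``x`` of the cubic.

    The physical branch must satisfy ``x > 0`` and ``eps tau x^3 <= 1``
    (equivalently ``eps G^SD <= 1``: no more probability than was put in).
    When rounding produces several admissible roots the one closest to
    ``hint`` (a neighbouring solution on an ``eps`` grid) is taken, else the
    largest.  The returned root is Newton-polished to residual below
    ``1e-12 * max(1, |a0|)``.
    """
    bound = -coeffs.a0  # = 1/(eps tau) >= x^3
    cands = [x for x in _real_roots(coeffs)
             if x > 0.0 and x ** 3 <= bound * (1.0 + 1e-8)]
    if not cands:
        raise ArithmeticError(
            f"no admissible root: roots={_real_roots(coeffs)!r}, coeffs={coeffs!r}")
    if hint is not None and len(cands) > 1:
        x = min(cands, key=lambda v: abs(v - hint))
    else:
        x = max(cands)
    for _ in range(3):  # Newton polish
        f = coeffs.residual(x)
        df = (3.0 * x + 2.0 * coeffs.a2) * x + coeffs.a1
        if df == 0.0:
            break
        step = f / df
        x -= step
        if abs(step) <= 1e-16 * abs(x):
            break
    if abs(coeffs.residual(x)) > 1e-12 * max(1.0, abs(coeffs.a0)):
        raise ArithmeticError(
            f"root polish failed: x={x!r}, residual={coeffs.residual(x)!r}, "
            f"coeffs={coeffs!r}")
    return x


@dataclass(frozen=True)
class LaplaceGreenSD:
    """Evaluator ``eps -> G^SD(eps)`` on the positive real axis.

    Calling with an array evaluates elementwise, threading each solution as
    the continuity hint for its neighbour.  Satisfies ``0 < eps G^SD <= 1``
    and ``eps G^SD -> 1`` as ``eps -> inf`` (the excitation starts on
    donor 1 with certainty).
    """

    params: SystemParams
    order: str = "three_body"

    def x(self, eps: float, hint: float | None = None) -> float:
        return solve_cardano(cubic_coefficients(self.params, self.order, eps), hint)

    def __call__(self, eps):
        if np.ndim(eps) == 0:
            return self.params.lifetime * self.x(float(eps)) ** 3
        eps = np.asarray(eps, dtype=float)
        out = np.empty(eps.shape)
        flat, oflat = eps.ravel(), out.ravel()
        # solve from the largest eps down so the continuity hint starts on
        # the unambiguous asymptotic branch x ~ (eps tau)^(-1/3)
        order = np.argsort(flat)[::-1]
        hint = None
        for i in order:
            hint = self.x(float(flat[i]), hint)
            oflat[i] = self.params.lifetime * hint ** 3
        return out


def green_sd_laplace(params: SystemParams, order: str = "three_body") -> LaplaceGreenSD:
    """Self-consistent ``G^SD(eps)`` evaluator at the given truncation order."""
    if order not in ("two_body", "three_body"):
        raise ValueError(f"unknown order {order!r}")
    return LaplaceGreenSD(params=params, order=order)


def green_dd_laplace(params: SystemParams, order: str, eps):
    """Cross-part Green function ``G^DD(k=0, eps)`` via node/loop removal.

    ``G^DD = Sigma / (1 - Sigma/G^SD)`` evaluated at the solved ``G^SD``
    (the same branch the ``G^SD`` evaluator selects, so the pair satisfies
    the conservation closure ``eps (G^SD + G^DD) = 1`` to machine
    precision).
    """
    g_all = green_sd_laplace(params, order)(eps)

    def one(g: float, e: float) -> float:
        sigma = sigma_total(params.n_donors, params.xi, g, params.lifetime,
                            order=order).value
        denom = 1.0 - sigma / g
        if abs(denom) < 1e-14:
            raise ArithmeticError(f"node renormalization singular at eps={e!r}")
        return sigma / denom

    if np.ndim(eps) == 0:
        return one(float(g_all), float(eps))
    eps = np.asarray(eps, dtype=float)
    flat = np.array([one(float(g), float(e))
                     for g, e in zip(np.ravel(g_all), eps.ravel())])
    return flat.reshape(eps.shape)
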