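"""Exact propagation of the hopping master equation for small systems.

Because the generator ``W`` is real symmetric, ``exp(t W)`` is evaluated by
a single eigendecomposition per configuration; the result is exact to
numerical precision and serves as the ground-truth oracle both for the
kinetic Monte-Carlo simulator and for the analytic Green-function solver.

``G^SD(t)``, the probability that the excitation occupies the initially
excited donor at time ``t`` (natural decay factored out), is the diagonal
element ``[exp(t W)]_11`` averaged over random donor configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import RateMatrix, SystemParams, build_rate_matrix, sample_configuration

__all__ = [
    "OccupationProbabilities",
    "CurveEstimate",
    "propagate_master_equation",
    "ensemble_green_sd",
]

#: largest donor count for which the dense oracle will run
MAX_ORACLE_DONORS = 200


@dataclass(frozen=True)
class OccupationProbabilities:
    """Occupation probabilities ``P[t, i] = P_{x_i x_1}(t)`` on a time grid."""

    time_grid: np.ndarray
    probs: np.ndarray  # shape (n_times, n_donors)


@dataclass(frozen=True)
class CurveEstimate:
    """Ensemble mean of a time-dependent observable with standard errors."""

    time_grid: np.ndarray
    mean: np.ndarray
    se: np.ndarray


def _validated_grid(time_grid) -> np.ndarray:
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("time grid must be a non-empty 1-D array")
    if np.any(t < 0.0) or np.any(np.diff(t) < 0.0):
        raise ValueError("time grid must be nonnegative and ascending")
    return t


def propagate_master_equation(W: RateMatrix, time_grid) -> OccupationProbabilities:
    """Column 1 of ``exp(t W)`` on a time grid, via symmetric eigendecomposition."""
    t = _validated_grid(time_grid)
    lam, vec = np.linalg.eigh(W.entries)
    lam = np.minimum(lam, 0.0)  # generator spectrum is nonpositive; clip rounding
    amp = vec * vec[0]          # amp[i, m] = V[i, m] * V[0, m]
    probs = np.exp(np.outer(t, lam)) @ amp.T
    return OccupationProbabilities(time_grid=t, probs=probs)


def green_sd_single(W: RateMatrix, time_grid) -> np.ndarray:
    """``[exp(t W)]_11`` for one configuration (no ensemble average)."""
    t = _validated_grid(time_grid)
    lam, vec = np.linalg.eigh(W.entries)
    lam = np.minimum(lam, 0.0)
    return np.exp(np.outer(t, lam)) @ (vec[0] ** 2)


def ensemble_green_sd(params: SystemParams, n_configs: int, time_grid, seed,
                      r_min: float = 0.0) -> CurveEstimate:
    """Ensemble-averaged ``G^SD(t)`` over random configurations, with SE.

    Averages ``[exp(t W)]_11`` over ``n_configs`` independent donor
    configurations; the standard error is the between-configuration sample
    standard deviation divided by ``sqrt(n_configs)``.  Refuses systems with
    more than ``MAX_ORACLE_DONORS`` donors (use the KMC simulator there).
    """
    if params.n_donors > MAX_ORACLE_DONORS:
        raise ValueError(
            f"dense oracle limited to N <= {MAX_ORACLE_DONORS} donors "
            f"(got {params.n_donors}); use the KMC simulator for larger systems")
    if n_configs < 1:
        raise ValueError("n_configs must be >= 1")
    t = _validated_grid(time_grid)
    seed = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    children = seed.spawn(n_configs)
    curves = np.empty((n_configs, t.size))
    for c, child in enumerate(children):
        config = sample_configuration(params, np.random.default_rng(child))
        W = build_rate_matrix(config, params, r_min=r_min)
        curves[c] = green_sd_single(W, t)
    mean = curves.mean(axis=0)
    if n_configs > 1:
        se = curves.std(axis=0, ddof=1) / np.sqrt(n_configs)
    else:
        se = np.zeros_like(mean)
    return CurveEstimate(time_grid=t, mean=mean, se=se)
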