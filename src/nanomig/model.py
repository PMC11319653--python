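"""Sphere geometry, Förster transfer rates, and the master-equation generator.

A system is ``N`` chemically identical chromophores ("donors") attached at
independent, area-uniform random positions on the surface of a spherical
nanoparticle of radius ``R``.  After pulsed excitation of donor 1 the
excitation performs an incoherent random walk over the donors, hopping with
the Förster dipole-dipole rate

    w(r) = (1/tau_0D) * (R0 / r)**6,

where ``R0`` is the critical (Förster) radius at which a single transfer
step is as fast as spontaneous decay, ``tau_0D`` the unquenched donor
lifetime, and ``r`` the *chord* (through-space) distance between the two
donors -- dipole coupling acts through space, not along the surface.

The pure-hopping dynamics (natural decay factored out by the substitution
P' = P * exp(-t/tau_0D)) is the master equation dP/dt = W P with the
generator ``W`` built here: W[j, k] = w(r_jk) for j != k and columns summing
to zero.  The dimensionless ratio ``xi = R0 / R`` controls migration
strength relative to nanoparticle size.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "SystemParams",
    "DonorConfiguration",
    "RateMatrix",
    "sample_configuration",
    "chord_distance",
    "forster_rate",
    "build_rate_matrix",
]


@dataclass(frozen=True)
class SystemParams:
    """Physical specification of one donor-coated nanoparticle.

    Parameters
    ----------
    n_donors:
        Number of attached donors, ``N >= 1``.  Donor 1 (index 0) is by
        convention the initially excited one.
    radius:
        Nanoparticle radius ``R`` (length units are arbitrary but must be
        shared with ``critical_radius``).
    critical_radius:
        Förster critical radius ``R0`` of the donor-donor pair.
    lifetime:
        Unquenched donor lifetime ``tau_0D``; sets the time unit.
    """

    n_donors: int
    radius: float = 1.0
    critical_radius: float = 1.0
    lifetime: float = 1.0

    def __post_init__(self) -> None:
        if int(self.n_donors) != self.n_donors or self.n_donors < 1:
            raise ValueError(f"n_donors must be a positive integer, got {self.n_donors}")
        object.__setattr__(self, "n_donors", int(self.n_donors))
        for name in ("radius", "critical_radius", "lifetime"):
            value = float(getattr(self, name))
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
            object.__setattr__(self, name, value)

    @classmethod
    def from_xi(cls, n_donors: int, xi: float, radius: float = 1.0,
                lifetime: float = 1.0) -> "SystemParams":
        """Construct from the dimensionless migration parameter ``xi = R0/R``."""
        return cls(n_donors=n_donors, radius=radius,
                   critical_radius=xi * radius, lifetime=lifetime)

    @property
    def xi(self) -> float:
        """Dimensionless ratio ``R0 / R``."""
        return self.critical_radius / self.radius

    @property
    def surface_area(self) -> float:
        """Sphere surface area ``S = 4 pi R^2``."""
        return 4.0 * np.pi * self.radius ** 2


@dataclass(frozen=True)
class DonorConfiguration:
    """One realization of the random attachment: ``N`` points on the sphere.

    ``positions`` has shape ``(N, 3)``; row 0 is the initially excited donor.
    Every row must lie on the sphere of radius ``radius`` to within 1e-12
    relative tolerance.
    """

    positions: np.ndarray
    radius: float
    seed: int | None = None

    def __post_init__(self) -> None:
        pos = np.ascontiguousarray(np.atleast_2d(np.asarray(self.positions, dtype=float)))
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise ValueError(f"positions must have shape (N, 3), got {pos.shape}")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, self.radius, rtol=1e-12, atol=0.0):
            worst = int(np.argmax(np.abs(norms - self.radius)))
            raise ValueError(
                f"donor {worst + 1} is off the sphere: |r| = {norms[worst]!r}, "
                f"R = {self.radius!r}")
        object.__setattr__(self, "positions", pos)

    @property
    def n_donors(self) -> int:
        return self.positions.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        """Dense matrix of pairwise chord distances (zeros on the diagonal)."""
        return squareform(pdist(self.positions))

    def to_table(self) -> str:
        """Plain-text export: header with N, R, seed, then one x y z row per donor."""
        buf = io.StringIO()
        buf.write(f"# n_donors={self.n_donors} radius={self.radius!r} seed={self.seed}\n")
        buf.write("# x y z (row 1 = initially excited donor)\n")
        for row in self.positions:
            buf.write("%.17g %.17g %.17g\n" % tuple(row))
        return buf.getvalue()

    @classmethod
    def from_table(cls, text: str) -> "DonorConfiguration":
        header = {}
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        key, _, val = token.partition("=")
                        header[key] = val
                continue
            rows.append([float(v) for v in line.split()])
        radius = float(header["radius"])
        seed = None if header.get("seed") in (None, "None") else int(header["seed"])
        return cls(positions=np.array(rows), radius=radius, seed=seed)


@dataclass(frozen=True)
class RateMatrix:
    """Generator ``W`` of the pure-hopping master equation.

    Off-diagonal ``W[j, k] = w(r_jk) >= 0`` is the rate from donor ``k`` to
    donor ``j``; the diagonal holds minus the column sums, so each column
    sums to zero (probability conservation).  ``W`` is symmetric because the
    Förster rate depends only on distance.
    """

    entries: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.entries, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"rate matrix must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("rate matrix has non-finite entries")
        off = w - np.diag(np.diag(w))
        if np.any(off < 0.0):
            raise ValueError("off-diagonal transfer rates must be nonnegative")
        scale = max(off.max(initial=0.0), 1.0)
        colsums = w.sum(axis=0)
        if np.any(np.abs(colsums) > 1e-10 * scale):
            raise ValueError("columns of the generator must sum to zero")
        object.__setattr__(self, "entries", w)

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    @property
    def outflow(self) -> np.ndarray:
        """Total transfer rate out of each donor (= minus the diagonal)."""
        return -np.diag(self.entries)


def sample_configuration(params: SystemParams, seed) -> DonorConfiguration:
    """Draw ``N`` independent, area-uniform donor positions on the sphere.

    ``seed`` may be an int, a :class:`numpy.random.SeedSequence`, or a
    :class:`numpy.random.Generator`; a fixed seed gives identical output.
    """
    rng = np.random.default_rng(seed)
    vec = rng.standard_normal((params.n_donors, 3))
    norms = np.linalg.norm(vec, axis=1)
    while np.any(norms == 0.0):  # pragma: no cover - probability zero
        bad = norms == 0.0
        vec[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(vec, axis=1)
    pos = params.radius * vec / norms[:, None]
    # renormalize exactly so the on-sphere invariant holds to 1e-12
    pos *= params.radius / np.linalg.norm(pos, axis=1)[:, None]
    return DonorConfiguration(
        positions=pos, radius=params.radius,
        seed=seed if isinstance(seed, (int, np.integer)) else None)


def chord_distance(p, q) -> float:
    """Euclidean (through-space) distance between two points on the sphere."""
    return float(np.linalg.norm(np.asarray(p, dtype=float) - np.asarray(q, dtype=float)))


def forster_rate(r, params: SystemParams):
    """Förster transfer rate ``w(r) = (1/tau_0D) (R0/r)**6``.

    Accepts scalars or arrays; ``r`` must be strictly positive (a zero
    distance means coincident donors, for which the rate diverges).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("coincident donors: transfer distance must be > 0")
    out = (params.critical_radius / r) ** 6 / params.lifetime
    return out if out.ndim else float(out)


def build_rate_matrix(config: DonorConfiguration, params: SystemParams,
                      r_min: float = 0.0) -> RateMatrix:
    """Build the master-equation generator for one donor configuration.

    ``r_min`` optionally clips pair distances from below before evaluating
    the ``r**-6`` rate; the default 0 applies no exclusion (the model has
    none), the clip exists only to guard against numerically absurd rates
    from near-coincident samples.
    """
    n = config.n_donors
    if n == 1:
        return RateMatrix(entries=np.zeros((1, 1)))
    dist = cdist(config.positions, config.positions)
    off = ~np.eye(n, dtype=bool)
    if np.any(dist[off] == 0.0):
        j, k = np.argwhere((dist == 0.0) & off)[0]
        raise ValueError(f"coincident donors {j + 1} and {k + 1}: zero chord distance")
    if r_min > 0.0:
        dist[off] = np.maximum(dist[off], r_min)
    w = np.zeros((n, n))
    w[off] = forster_rate(dist[off], params)
    np.fill_diagonal(w, -w.sum(axis=0))
    return RateMatrix(entries=w)
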