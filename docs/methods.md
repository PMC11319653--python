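# Methods

## Model

`N` point-like, chemically identical chromophores (donors) are attached
independently and area-uniformly to the surface of a sphere of radius `R`.
Donor 1 is excited at `t = 0`. The excitation performs an incoherent random
walk with pairwise Förster rates

    w(r) = (1/τ₀D) (R₀/r)⁶,

where `r` is the **chord** (through-space) distance between attachment
points: dipole–dipole coupling acts through space, and only the chord
convention reproduces the planar-limit closed form of the two-body diagram
sum (certified to 1e-6 by a test). Orientational averaging is absorbed into
`R₀`; rotational diffusion, acceptor traps, exciton–exciton annihilation
and non-uniform (clustered) attachment are outside the model. Natural decay
is factored out of the hopping dynamics by the substitution
`P′ = P · exp(−t/τ₀D)` and re-enters analytically in the observables; the
generator of the remaining pure-hopping master equation is the symmetric
matrix `W` with `W[j,k] = w(r_jk)` off the diagonal and columns summing to
zero. No minimum-approach distance is imposed by default (`r_min` exists
only as an optional numerical guard and defaults to 0).

All times are quoted in units of `τ₀D`; the physics depends on `N` and on
the dimensionless migration strength `ξ = R₀/R`.

## Analytic channel

The self-part Green function `G^SD(t)` — the probability that the
excitation occupies donor 1, ensemble-averaged over attachments — is
obtained in the Laplace domain from the probability-conservation closure

    ε [Ĝ^SD(ε) + Ĝ^DD(0, ε)] = 1,    Ĝ^DD = Σ̂ / (1 − Σ̂/Ĝ^SD),

where `Σ̂(0, ε, Ĝ^SD)` is the loop- and node-free (topologically reduced)
diagram sum, truncated at two- or three-body order.

**Planar scaling limit.** With `u = 2 Ĝ w(r)` and the substitution
`r = (2 Ĝ R₀⁶/τ)^{1/6} s`, every diagram kernel becomes parameter-free and
is concentrated at separations `≪ R`, so the sphere may be replaced by its
tangent plane. Each 2-D integral contributes a factor `a^{1/3}`,
`a = 2ĜR₀⁶/τ`, which is the origin of the characteristic `ξ²`, `ξ⁴`
scalings. The radial kernel `∫₀^∞ s ds/(s⁶+1) = π/(3√3)` gives in closed
form:

- the two-body sum `Σ̂₂ = (N−1)(Ĝ/36)·2^{1/3}√3π·ξ²(Ĝ/τ)^{1/3}`
  (prefactor `2^{1/3}√3π/36 = 0.19043700`);
- the loop term of the three-body sum, `L₃/pref = −4π⁴/81`, via the pair
  weight `B₂ = −πĜa^{1/3}·π/(3√3)`;
- the node term, `N₃/pref = π⁴/27` (the double integral factorizes at
  `k = 0` after translating the third donor's coordinate).

Only the all-multigraph term `A₃` needs numerical quadrature: after fixing
donor 1 at the origin and using rotational symmetry it is a 3-variable
integral over (two radii, one included angle), evaluated with an adaptive
radial rule and a Gauss–Legendre angular rule whose nodes are clustered
toward zero angle (where donors 2 and 3 nearly coincide; the integrand is
bounded there but sharply varying). The two-body subtraction inside `A₃`
makes the tail integrable. Combining the three sums yields the three-body
coefficient

    C₃ = −(2^{2/3}/16π²) (I_A/2 + π⁴/81) = 0.0095366 ± 0.001%,

computed by `three_body_coefficient()` with an explicit self-convergence
check (finer angular rule + tighter radial tolerance; failure raises with
both estimates). The closed-form evaluators use the conventional rounded
constant 0.00954125, which agrees with the converged quadrature to 0.05%.
The quadrature deliberately runs in *dimensional* variables and divides
the scale factor out afterwards, so the scaling invariance of `C₃` under
changes of `Ĝ, τ, R₀` is a testable property rather than an assumption.
The `(N−1)(N−2)` grouping of the whole three-body correction follows the
combined closed form (the node term alone would carry `(N−1)²`).

**Cubic and root selection.** Substituting `x = (Ĝ^SD/τ)^{1/3}` turns the
closure into `x³ + a₂x² + a₁x + a₀ = 0` with
`a₂ = −(N−1)(N−2)C₃ξ⁴/(ετ)`, `a₁ = (N−1)·0.190437·ξ²/(ετ)`,
`a₀ = −1/(ετ)`. Roots come from Cardano's formulas (trigonometric form
when three are real) plus one Newton polish; the *physical* root must be
positive with `ετx³ ≤ 1` (no more occupancy than probability). On grids of
`ε` the previous solution is threaded as a continuity hint, starting from
the largest `ε`, where the branch `x ≈ (ετ)^{−1/3}` is unambiguous.

**Validity boundary.** At strong migration the negative three-body term
can overpower the series (`Σ̂ < 0`), and below a parameter-dependent `ε`
the cubic's unique real root violates the probability bound — empirically
below `ετ ≈ 0.5` at `N = 100, ξ = 0.5`, and progressively lower for weaker
migration (irrelevant for `ξ ≤ 0.25` over the usual 5-lifetime window).
The solver refuses there with a diagnostic carrying all roots;
`sigma_total` warns when `Σ̂ < 0`. Nothing is clamped. The conservation
audit `ε(Ĝ^SD+Ĝ^DD) = 1` is exercised on `ετ ∈ [1, 100]`, which the whole
tested `(N, ξ)` grid supports.

**Laplace inversion.** Gaver–Stehfest is the default because it samples
`Ĝ^SD` only on the positive real axis, avoiding complex branch tracking of
the Cardano root. Weights are exact rationals; summation runs in mpmath
extended precision (2.5 digits per term), so accuracy is limited by the
precision of the transform values: with the float64 cubic solver the
default 14 terms give ~1e-4 absolute accuracy on decay curves, while
analytic transforms evaluated in `mpf` arithmetic reach the 1e-4 *relative*
contract at 32 terms. A cancellation guard raises when the estimated noise
makes a value meaningless rather than returning garbage. `t = 0` is never
inverted; the exact limit `G^SD(0) = 1` is substituted. A fixed-Talbot rule
is included for complex-capable transforms.

**Observables.** `I∥ = e^{−t/τ}(1 + 4G/5)`, `I⊥ = e^{−t/τ}(1 − 2G/5)`,
`r = (I∥−I⊥)/(I∥+2I⊥)`, `r₀ = 2/5`, and the donor decay
`I(t) = I₀e^{−t/τ}G^SD(t)`. The identity `r/r₀ = G^SD` is exact;
`decay_curves` computes the quotient route as an internal cross-check (to
1e-12) and returns the identity value.

## Stochastic channel (kinetic Monte Carlo)

Gillespie simulation of the pure-hopping jump process: exponential dwell
with the current donor's total outflow, destination proportional to rate.
Decay is never a simulated channel — observables weight trajectories
analytically, or sample an emission time `T ~ Exponential(τ₀D)` (the
lifetime-weighted displacement convention; the time-resolved `⟨r²(t)⟩`
curve is also available, and the quadrature identity
`⟨r²(T)⟩ = ∫(1/τ)e^{−t/τ}⟨r²(t)⟩dt` is verified in a test).

**Exact fast-cluster aggregation.** The `r⁻⁶` rate is heavy-tailed: donor
pairs at small separation exchange the excitation `~(ξR/d)⁶` times per
lifetime, making literal event-by-event simulation unboundedly expensive.
Whenever a donor's strongest link exceeds `10³/τ₀D` (the `fast_factor`
knob), the engine grows a cluster greedily along links above the threshold
(capped at 12 members) and replaces the visit by one exactly solved
sojourn: the process restricted to a cluster `C` until first escape is
governed by the principal submatrix `W[C,C]` of the full generator, whose
small symmetric eigendecomposition (cached per cluster) provides the exact
survival function (inverse-CDF sampled by safeguarded Newton), escape
hazards, escape-channel distribution, and conditional within-sojourn
occupancies (used to Rao-Blackwellize occupancy and displacement
estimates). The aggregated chain is equal in distribution to literal
Gillespie for any threshold; unbiasedness is tested against the exact
resolvent identity `E[f(X(T))] = (1/τ)fᵀ(I/τ−W)^{−1}e₁` at thresholds from
"aggregate everything" to "almost never", and the full `G^SD(t)` curve
against the matrix-exponential oracle. The threshold only trades
per-event cost against event count.

**Ensembles and errors.** Fresh configurations × multiple trajectories per
configuration; curve standard errors are the between-configuration spread
of per-configuration means (which dominates and conservatively includes
within-configuration noise); displacement standard errors come from a
bootstrap over configurations. All estimators accept one integer seed;
per-configuration substreams derive from it deterministically.

## Reference conditions and problem sizes

The displacement ensembles follow the reference conditions: `ξ = 1, N =
50` (1000 × 10), `ξ = 0.1, N = 50` (2000 × 5), `ξ = 0.1, N = 1000`
(200 × 5). With these the lifetime-weighted relative RMS displacement
converges to 1.376 R₀ at `ξ = 1, N = 50` (the equidistribution limit is
`√(2(N−1)/N) ≈ 1.40` in units of `R`), 0.035 R at `ξ = 0.1, N = 50`, and
0.19 R at `ξ = 0.1, N = 1000` — migration is delocalized on small
particles and local on large ones. Test-suite versions of the slower
ensembles run at reduced counts chosen so that three standard deviations
of estimator noise stay inside the asserted bands.

## What the synthetic ensembles do and do not show

The generator realizes exactly the model's assumptions: uniform
attachment, point dipoles with orientation pre-averaged into `R₀`, a
static configuration per trajectory set, single excitation. Passing tests
therefore validate the solver/simulator pair *within this model*; they say
nothing about orientational dynamics, donor photobleaching, spectral
heterogeneity, surface-linker geometry, or metal-core plasmonic effects in
real nanoparticle preparations.

## Known limitations

- The three-body truncation breaks down at strong migration and long
  times (`Σ̂ < 0`); the solver refuses rather than extrapolating.
- The dense oracle stops at `N = 200` donors (eigendecomposition cost);
  beyond that only the KMC channel is available.
- Gaver–Stehfest with the float64 solver resolves decay values down to
  ~1e-4 absolute; deeper tails require a higher-precision transform.
- The `k ≠ 0` Fourier structure of the diagram sums (needed for a
  diffusion coefficient) is not implemented.
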