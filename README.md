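# nanomig

Excitation energy migration among identical chromophores on the surface of
a spherical nanoparticle: a self-consistent Green-function theory and an
exact kinetic Monte-Carlo (KMC) simulator for Förster homotransfer.

## The problem

Attach `N` identical fluorophores ("donors") at random to a nanoparticle of
radius `R`. After pulsed excitation of one donor the excitation hops
between donors by the Förster dipole–dipole mechanism with rate

```
w(r) = (1/τ₀D) (R₀/r)⁶
```

(`r` the through-space chord distance, `R₀` the Förster critical radius,
`τ₀D` the unquenched lifetime). Because only the originally excited donor
remembers the excitation polarization, the emission anisotropy decays as
the excitation migrates:

```
r(t)/r₀ = G^SD(t),
```

where `G^SD(t)` is the ensemble-averaged probability that the excitation
still (or again) occupies the initially excited donor. `G^SD` measures
migration strength directly and depends on `N` and on the dimensionless
ratio `ξ = R₀/R` — the key design parameters of antenna-like fluorescent
nanostructures. The package is for photophysicists and nanomaterials
designers who need these decays quantitatively, not just in the weak-
migration limit.

## What the package computes

**Analytic channel** — the Laplace-domain self-part Green function
`Ĝ^SD(ε)` solves the self-consistent closure

```
ε [Ĝ^SD + Ĝ^DD(k=0, ε)] = 1,      Ĝ^DD = Σ̂^DD / (1 − Σ̂^DD/Ĝ^SD),
```

with the loop- and node-free diagram sum truncated at two- or three-body
order. In the planar scaling limit

```
Σ̂^DD ≈ (N−1) (Ĝ/36) 2^{1/3}√3 π ξ² (Ĝ/τ₀D)^{1/3}
        − C₃ (N−1)(N−2) Ĝ ξ⁴ (Ĝ/τ₀D)^{2/3},     C₃ ≈ 0.0095412,
```

which turns the closure into a cubic in `x = (Ĝ^SD/τ₀D)^{1/3}`, solved by
Cardano's formulas; `G^SD(t)` follows by Gaver–Stehfest inversion and the
observables (polarized intensities, anisotropy, donor decay) algebraically.
The coefficient `C₃` is not a fitted number: `three_body_coefficient()`
recomputes it from the underlying three-donor integrals.

**Stochastic channel** — an exact KMC (Gillespie) simulation of the same
master equation, with near-degenerate donor clusters aggregated into
analytically solved sojourns (exact in distribution; see
`docs/methods.md`). It estimates `G^SD(t)` with standard errors and the
mean-squared excitation displacement, lifetime-weighted:
`⟨r²⟩^{1/2}/R₀` at an exponential emission time.

A dense matrix-exponential oracle (`N ≤ 200`) ties the two channels
together in the test suite.

## Worked example

```python
import numpy as np
from nanomig import SystemParams, anisotropy_decay, estimate_green_sd

params = SystemParams.from_xi(n_donors=50, xi=0.25)
grid = np.linspace(0.0, 5.0, 6)              # units of the donor lifetime

theory = anisotropy_decay(params, grid, order="three_body")
sim = estimate_green_sd(params, n_configs=200, n_traj_per_config=20,
                        time_grid=grid, seed=7)
for t, a, k, s in zip(grid, theory.r_over_r0, sim.mean, sim.se):
    print(f"t/tau={t:3.0f}  r/r0 theory={a:.3f}  KMC={k:.3f} +- {s:.3f}")
```

prints

```
t/tau=  0  r/r0 theory=1.000  KMC=1.000 +- 0.000
t/tau=  1  r/r0 theory=0.526  KMC=0.531 +- 0.018
t/tau=  2  r/r0 theory=0.447  KMC=0.449 +- 0.018
t/tau=  3  r/r0 theory=0.399  KMC=0.403 +- 0.017
t/tau=  4  r/r0 theory=0.365  KMC=0.365 +- 0.017
t/tau=  5  r/r0 theory=0.339  KMC=0.337 +- 0.016
```

— at `ξ = 0.25` with 50 donors roughly half the anisotropy is lost within
one lifetime, and the analytic three-body curve tracks the simulation
within its error bars over the whole window.

The same pipelines are scriptable from the shell:

```
nanomig solve    --n-donors 50 --xi 0.25 --out decay.csv
nanomig simulate --n-donors 50 --xi 0.25 --seed 1 --out kmc.csv
nanomig msd      --n-donors 50 --xi 1.0  --seed 1 --out msd.json
nanomig coefficient --rel-tol 1e-3
nanomig figure1  --out anisotropy_sweep.csv
nanomig figure2  --out msd_sweep.csv
```

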