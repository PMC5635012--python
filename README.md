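# geltrap

Biogels such as mucus, basement membranes and Matrigel® can stop viruses
and nanoparticles that are far smaller than their mesh spacing — but only
through adhesion, not steric obstruction.  A powerful way to make a gel
adhesive against many different particles is a **third-party molecular
anchor** (e.g. an IgG antibody) with affinity for both the particle and
the matrix.  `geltrap` implements a quantitative model of this mechanism
for people designing or analyzing such systems: which anchor kinetics,
concentrations, and gel geometries actually immobilize particles, and how
to read trapping out of particle-tracking microscopy.

The central, counterintuitive result the model makes quantitative: anchors
with *weak, rapidly exchanging* matrix bonds trap far better than anchors
glued permanently to the matrix, because fast exchange lets many anchors
accumulate on a diffusing particle before any single crosslink matters.

## The model

A particle with `N` independent binding sites carries `n` anchors, `s` of
which simultaneously bind the immobile matrix (a `(n, s)` continuous-time
Markov chain).  Free anchors bind the particle at the Smoluchowski rate
`k_on = (D_P + D_A) φ [A] R₀` and matrix-bound ones at
`k'_on = (D_P + D_M)(1 − φ)[A] R₀`, where `φ = a_off/(a_on + a_off)` is the
free-anchor fraction; anchors unbind the particle at `k_off` and exchange
with the matrix at `a_on`, `a_off`.  The particle diffuses only while
`s = 0`, so its long-time effective diffusivity is the stationary
free-state probability:

```
D_eff / D_P = Σₙ ρ(0|n) ρ(n),      ρ(0|n) = D_A C αⁿ / ((D_A C − D_P) αⁿ + D_P),
α = a_off / (C a_on + a_off),      ρ(n) ∝ C(N,n) Πⱼ<ₙ κ(j) / k_offⁿ,
κ(n) = k_on + ρ(0|n) k'_on,
```

valid in the quasi-steady-state regime `τ_AM ≪ τ_AP ≪ τ_L`
(anchor–matrix exchange ≪ anchor–particle exchange ≪ diffusive crossing
time `L²/2D_P`).  The package provides:

- `params` — parameter containers, unit conversions (µg/mL ↔ µm⁻³, anchor
  spacing), dimensionless knobs, the three timescales, and a report on the
  six operating-regime conditions;
- `chain` — the exact `(n, s)` generator and its stationary solve (the
  brute-force oracle for everything else);
- `qss` — the closed forms above, the optimal-affinity search, and the
  finite-matrix-site competition model for saturation and multi-species
  trapping robustness;
- `ssa` — Gillespie simulation with the time-fraction `D_eff` estimator,
  and a spatial switching-diffusion first-passage simulator;
- `transport` — the slab absorption-probability series and parameter-sweep
  grids;
- `sensitivity` — finite-difference sensitivities of `log(D_eff/D_P)`;
- `tracking` — a synthetic trajectory generator (20 s videos, 66.7 ms
  frames, 10 nm noise) and the multiple-particle-tracking analysis
  (time-averaged MSD, geometric ensemble MSD, `D_eff` at lag 0.2667 s,
  diffusive exponent, mobile fraction at the 10^-1.5 µm²/s cutoff).

## Worked example

```python
from geltrap import (DimensionlessParameters, from_dimensionless,
                     d_eff_qss, d_eff_exact, gillespie)

dp = DimensionlessParameters(d_ratio=20.0, N=15, tau_ratio=20.0,
                             conc_dimless=10.0, phi=0.3)
p = from_dimensionless(dp)          # k_off = 1 /s, D_P = 1 µm²/s scales
print(d_eff_qss(p))                 # 0.000274
print(d_eff_exact(p))               # 0.000272
print(gillespie(p, max_transitions=300_000, seed=1).d_eff_ratio)  # 0.00077 ± 0.00044
```

Three engines, one number: with 15 binding sites, a trapping-active anchor
concentration, and fast matrix exchange (`τ_AP/τ_AM = 20`, 30% of anchors
free), the particle spends ~0.03% of its time free — a 99.97% reduction in
effective diffusivity.  Flip to permanently bound anchors
(`phi=0, tau_ratio=0.01, conc_dimless=2`) and the chain collapses to a
two-state balance with `D_eff/D_P = 1/(1 + N·conc/21) = 0.412`: barely a
59% reduction, because each particle can reach only one immobilized anchor
at a time.

The `examples/` scripts walk through each capability (effective
diffusivity, optimal anchor affinity, gel-layer penetration, multi-species
capacity, particle tracking) and print annotated numbers; the `geltrap`
command exposes the same operations from the shell
(`geltrap deff --engine exact --phi 0 --conc 2`, `geltrap sweep --figure 2a
--out grid.csv`, `geltrap tracks simulate ...`).

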