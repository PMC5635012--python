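# Methods

## Model

One nanoparticulate with `N` independent anchor-binding sites moves through
a gel whose matrix sites (concentration `[M]`, diffusivity ≈ 0) bind small
mobile anchors (concentration `[A]`, diffusivity `D_A ≫ D_P`).  The state
`(n, s)` counts particle-bound anchors and particle–anchor–matrix
crosslinks.  Six channels (see `chain`): anchor accumulation at
`(N−n)k_on`, capture of a free particle by a matrix-bound anchor at
`(N−n)k'_on` gated on `s = 0`, particle release at `(n−s)k_off` and
`s·k_off`, and crosslink formation/release at `g(s)(n−s)a_on` / `s·a_off`
with `g(0) = D_P/D_A` (the whole complex must diffuse to the matrix) and
`g(s≥1) = C` (intra-complex binding; `C = 1` throughout by default, since
intra-complex dissociation is taken equal to bulk dissociation and the
binding-rate rescaling is unknown of order one).  Bonds are independent;
`[A]` is treated as an unbleached bulk reservoir (no depletion by binding);
the encounter parameter `R₀` is lumped (any 4π geometric factor absorbed),
so `(D_P + D_A)[A]R₀` is a rate.

Assumptions worth keeping in mind: a particle never bridges two
*independently* immobilized anchors (reasonable below ~250 µg/mL for an
IgG-sized anchor, where mean spacing exceeds the particle diameter — see
`anchor_spacing`), and the matrix is static on all kinetic timescales.

## Timescale reduction

With `τ_AM = 1/(a_on+a_off) ≪ τ_AP = 1/(D_A[A]R₀ + k_off) ≪ τ_L = L²/2D_P`,
`s` equilibrates at fixed `n` to the birth–death stationary law `ρ(s|n)`
(closed form with `α = a_off/(C a_on + a_off)`), and `n` to
`ρ(n) ∝ C(N,n) Π_{j<n} κ(j)/k_off^n`.  The homogenized diffusivity is
`D_eff = D_P Σ_n ρ(0|n)ρ(n)`.

The `s`-averaged accumulation rate is implemented as

    κ(n) = k_on + ρ(0|n) · k'_on .

Averaging the forward `n`-transitions over `ρ(s|n)` forces this placement:
free-anchor binding (`k_on`) proceeds from every `s`, while matrix-bound
capture (`k'_on`) carries the `δ_{s,0}` gate.  The placement was verified
against the exact chain: at `τ_AP/τ_AM = 10³–10⁴` the reduction matches
the stationary free-state probability to < 0.3% across randomized
parameter sets, including the `φ = 0` limit where the chain collapses to a
two-state balance (`D_eff/D_P = 1/(1 + N·k'_on/k_off)`).  Putting the gate
on `k_on` instead breaks this agreement by orders of magnitude.

Numerics: `ρ(n)` products are accumulated in log space (log-gamma
binomials), so `N` up to hundreds and strongly trapping rates cannot
overflow; `ρ(n)` is renormalized after exponentiation, and the `α = 1`
limit short-circuits to `D_eff/D_P = 1` exactly.  The exact chain
((N+1)(N+2)/2 states) is solved densely by least squares on `[Gᵀ; 1]`;
`k_off = 0` makes the chain reducible and is answered explicitly with the
absorbing-limit distribution rather than a spurious null vector.

## Engines and when they apply

- `d_eff_qss`: closed form; requires `τ_AM ≪ τ_AP`.  Note it depends on the
  kinetics only through `α` and `φ`, never through the timescale ratio
  itself.
- `d_eff_exact`: stationary solve of the full chain; valid at any
  `τ_AP/τ_AM` and the default engine wherever slow matrix exchange matters
  (optimal-affinity scans, sensitivities, multi-species competition).
- `gillespie`: unbiased time-fraction estimator `D_P·t_free/t_total` from
  state (0,0); no burn-in is discarded (the estimator is a long-run time
  average and the runs are long); standard errors by 20-batch means.

## Spatial first passage

`simulate_spatial` couples the chain to 1-D Brownian motion on `[0, L]`,
reflecting at the entry face (deposition on the gel's outer surface) and
absorbing at `L`; the particle starts at `x = 0` in state `(0,0)` and moves
only while `s = 0`.  Free dwells advance in substeps of at most `τ_L/100`
with the exact Brownian-bridge crossing probability
`exp(−(L−x₀)(L−x₁)/(D_P Δt))` applied per substep, which removes the
leading missed-crossing bias analytically instead of by brute-force step
refinement.  The homogenized series
`P = 1 − Σ_k 4(−1)^k/((2k+1)π)·exp(−D_eff(2k+1)²π²T/4L²)` (truncated when
the next term < 1e-12) agrees with the simulator within Monte-Carlo error
whenever `τ_AM, τ_AP ≪ τ_L`.  Dimensional penetration numbers default to
`D_P = 2 µm²/s` — the Stokes–Einstein scale of a ~200 nm particle in
watery gel fluid at 37 °C — and always state it, since penetration (unlike
`D_eff/D_P`) is not scale-invariant.

## Dimensionless knobs

Sweeps use `(D_A/D_P, N, τ_AP/τ_AM, [A](D_P+D_A)R₀/k_off, φ, C)` with
`k_off = 1 s⁻¹`, `D_P = 1 µm²/s` as unit scales; every reported ratio is
invariant to the scales.  The concentration knob is deliberately the
φ-independent combination (not `[A]k_on/k_off`, which vanishes with φ and
would degenerate the φ = 0 axis).  The diffusivity-ratio knob in
sensitivities and figure-style grids is varied at fixed *physical* `[A]R₀`
(i.e. the concentration knob is rescaled by `(1+d)`), because varying it
at fixed dimensionless concentration silently dilutes the anchors and
flips the sign of the mobility benefit.  Sensitivities are central
differences of `log(D_eff/D_P)` with step-halving until successive
estimates agree to 1% (unit lattice differences for `N`); both the
absolute-step derivative and the per-log-parameter form are reported since
the normalization convention is a free choice.

## Matrix-site competition and multi-species capacity

A matrix binding site is modeled as an independent two-state unit loaded
by the total anchor pool `[A_T]`: unoccupied a fraction
`ξ = a_off/((A_T/M)a_on + a_off)` of the time.  Competition rescales every
anchor's matrix on-rate to `ξ·a_on` (and thereby the intra-complex rate to
`C·ξ·a_on`), with the focal species keeping its own concentration in the
encounter rates.  For `[A_T] ≫ [M]` this reduces to the saturated-regime
asymptotics (`φ → 1 − [M]/[A_T]`, `α → 1 − C[M]/[A_T]`,
`τ_AM → 1/a_off`), implemented verbatim in `saturated_regime`; for
`[A_T] → 0` it returns the dilute model.  The per-site law ignores anchor
conservation, so below `[A_T] ≈ [M]` it overstates occupancy for very
high-affinity anchors — which is precisely the regime where long-lived
anchor–matrix bonds monopolize sites; it is used continuously rather than
with a hard dilute/saturated switch to keep `D_eff(m)` monotone in the
species count.

`species_capacity` fixes the study condition as: each species dosed at the
minimum concentration reaching a single-species `D_eff/D_P` of 0.02 (a 98%
reduction — comfortably "trapping-active", and ≈1 µg/mL for IgG-scale
anchors at the default `R₀` and `[M] = 10⁵ µm⁻³`, i.e. a 2% w/v gel with
10 sites per 500 kDa matrix molecule) at its optimal `φ`; capacity is the
largest species count at which the focal `D_eff/D_P` is still within 2× of
its single-species value, found by monotone bisection with the exact-chain
engine.  Equal-potency dosing is what makes the comparison between kinetic
regimes meaningful: slow-exchange anchors need ~5× the concentration to
reach the same potency and then monopolize sites, so their capacity
(~1.6×10³ species) is ~36-fold below that of fast-exchange anchors
(~5.6×10⁴) under identical gels.

## Synthetic tracking data

`generate_tracks` emulates the video parameters: 20 s tracks at 66.7 ms
(300 frames) with 10 nm i.i.d. Gaussian localization noise per coordinate.
Each track runs the exact chain and integrates the free time per frame
interval; frame-to-frame displacements are Gaussian with per-axis variance
`2 D_P × (free time)`, which is exact for gated Brownian motion — there is
no time-discretization error in the dynamics.  What the generator does
*not* emulate: detection dropouts and track splitting, depth-of-field
escape, motion blur within the exposure, static/dynamic error correlation,
or gel heterogeneity (a single parameter set per ensemble).  Pipeline
closure on synthetic data therefore validates the analysis conventions and
the model's time-fraction interpretation of `D_eff`, not the detection
stage of a real tracking experiment.

Analysis conventions: 2-D `D_eff = MSD(τ)/4τ` at the reference lag of 4
frames (0.2667 s), which entails the 5-frame minimum track length; mobile
iff `D_eff ≥ 10^-1.5 µm²/s` (boundary inclusive, compared against a single
module-level constant); geometric ensemble means with MSDs floored at the
noise floor `4σ² = 4×10⁻⁴ µm²` before taking logs; diffusive exponent from
a least-squares line on log MSD–log τ over lags 1–10.  The binding chain's
`α` and the MSD exponent are distinct quantities; the latter is named
"diffusive exponent" throughout.

## Problem sizes

Defaults were chosen so the whole suite runs on one core in about a
minute: randomized cross-engine checks use 12–20 parameter sets with
N ≤ 15; Gillespie verification runs 1.2×10⁵ transitions (the acceptance
script uses 10⁶); spatial-vs-series checks run 250–800 particles on
few-µm layers with fast kinetics (`τ_AP ≈ τ_L/30`), where homogenization
error is well inside Monte-Carlo error; tracking closure uses 60–200
tracks.  All stochastic tests compare at 3 standard errors.

## Known limitations

- The QSS engine silently loses accuracy as `τ_AP/τ_AM → 1` and below;
  use the exact engine there (the package does, by default, wherever it
  matters).
- Competition between anchor species assumes identical kinetics and
  independent sites; heterogeneous anchor mixtures and cooperative or
  multivalent matrix binding are out of scope.
- The spatial model is 1-D with a static, homogeneous layer; advective
  clearance (e.g. mucus turnover) and 3-D microstructure are not modeled.
- `[A]` never depletes: trapping many particles at once with scarce
  anchors is outside the model's assumptions.
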