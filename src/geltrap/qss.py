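"""Quasi-steady-state reduction of the binding chain to an effective diffusivity.

When anchor-matrix exchange is much faster than anchor-particle exchange
(tau_AM << tau_AP), the crosslink count ``s`` equilibrates at fixed anchor
count ``n``, and ``n`` in turn equilibrates before the particle moves a
matrix-layer distance (tau_AP << tau_L).  Averaging the chain over the two
fast variables leaves ordinary diffusion with

    D_eff / D_P = sum_n rho(0|n) rho(n),

where ``rho(0|n)`` is the conditional probability that none of the ``n``
particle-bound anchors touches the matrix, and ``rho(n)`` the quasi-steady
distribution of the anchor count.  Closed forms:

    alpha     = a_off / (C a_on + a_off)
    rho(0|n)  = D_A C alpha^n / ((D_A C - D_P) alpha^n + D_P)
    rho(s|n)  = D_P binom(n,s) (1-alpha)^s alpha^(n-s)
                / ((D_A C - D_P) alpha^n + D_P),          s >= 1
    kappa(n)  = k_on + rho(0|n) k_on'
    rho(n)    prop. binom(N,n) prod_{j<n} kappa(j) / k_off^n.

``kappa(n)`` is the s-averaged anchor-accumulation rate: free anchors bind
at ``k_on`` from every s, while capture by a matrix-bound anchor (``k_on'``)
requires the particle to be free, hence the ``rho(0|n)`` weight on the
``k_on'`` term.  With this placement the reduction converges to the exact
chain's stationary free-state probability as tau_AP/tau_AM -> infinity.

The module also covers the crowded-matrix regime: when many anchor species
share a finite pool of matrix binding sites, the per-site occupancy rescales
each anchor's matrix on-rate, which is how the robustness of trapping
against many simultaneous species is quantified.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .params import (
    DimensionlessParameters,
    TrappingParameters,
    from_dimensionless,
    smoluchowski_rates,
)


def _log_binom(n: int, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rho_s_given_n(
    n: int, alpha: float, D_A: float, D_P: float, C: float = 1.0
) -> np.ndarray:
    """Conditional stationary distribution of the crosslink count s given n.

    ``alpha`` is the intra-complex unbound probability
    a_off/(C a_on + a_off); with C = 1 it equals the free fraction φ.
    Returns an array of length n + 1 summing to 1.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if D_A <= 0 or D_P < 0:
        raise ValueError("need D_A > 0 and D_P >= 0")
    if n == 0:
        return np.ones(1)
    out = np.zeros(n + 1)
    if alpha == 0.0:
        out[n] = 1.0  # crosslinks never release: all n anchors matrix-bound
        return out
    denom = (D_A * C - D_P) * alpha**n + D_P
    out[0] = D_A * C * alpha**n / denom
    if alpha < 1.0:
        s = np.arange(1, n + 1)
        log_terms = (
            _log_binom(n, s.astype(float))
            + s * math.log1p(-alpha)
            + (n - s) * math.log(alpha)
        )
        out[1:] = D_P * np.exp(log_terms) / denom
    return out


@dataclass(frozen=True)
class QSSResult:
    """All pieces of the quasi-steady-state reduction for one parameter set."""

    alpha: float
    rho_s: np.ndarray  # (N+1, N+1) lower-triangular rows rho(s|n)
    rho_n: np.ndarray  # length N+1
    kappa: np.ndarray  # length N+1, s-averaged accumulation rate per site
    d_eff_ratio: float
    log_normalization: float

    @property
    def rho_0_given_n(self) -> np.ndarray:
        return self.rho_s[:, 0]

    def to_dataframe(self) -> pd.DataFrame:
        N = len(self.rho_n) - 1
        rows = []
        for n in range(N + 1):
            for s in range(n + 1):
                rows.append((n, s, self.rho_s[n, s], self.rho_n[n]))
        return pd.DataFrame(rows, columns=["n", "s", "rho_s_given_n", "rho_n"])


def qss_reduction(p: TrappingParameters) -> QSSResult:
    """Full quasi-steady-state reduction for parameters ``p``.

    Products over ``kappa`` are accumulated in log space so that large N
    and strongly trapping rates cannot overflow.
    """
    if p.k_off <= 0:
        raise ValueError("rho(n) undefined for k_off == 0")
    alpha = p.alpha
    N = p.N
    k_on, k_on_prime = smoluchowski_rates(p)
    rho_s = np.zeros((N + 1, N + 1))
    for n in range(N + 1):
        rho_s[n, : n + 1] = rho_s_given_n(n, alpha, p.D_A, p.D_P, p.C)
    kappa = k_on + rho_s[:, 0] * k_on_prime
    log_w = np.zeros(N + 1)
    for n in range(1, N + 1):
        if kappa[n - 1] <= 0:
            log_w[n:] = -np.inf
            break
        log_w[n] = (
            log_w[n - 1]
            + math.log(N - n + 1) - math.log(n)
            + math.log(kappa[n - 1]) - math.log(p.k_off)
        )
    log_norm = np.logaddexp.reduce(log_w)
    rho_n = np.exp(log_w - log_norm)
    rho_n /= rho_n.sum()
    # alpha = 1: no crosslink is ever held, so the particle is free with
    # probability one regardless of rho(n); keep the limit exact
    d_eff = 1.0 if alpha == 1.0 else float(np.dot(rho_s[:, 0], rho_n))
    return QSSResult(
        alpha=alpha, rho_s=rho_s, rho_n=rho_n, kappa=kappa,
        d_eff_ratio=d_eff, log_normalization=-log_norm,
    )


def rho_n(p: TrappingParameters) -> np.ndarray:
    """Quasi-steady-state distribution of the particle-bound anchor count."""
    return qss_reduction(p).rho_n


def d_eff_qss(p: TrappingParameters) -> float:
    """Effective diffusivity ratio D_eff/D_P from the closed-form reduction."""
    return qss_reduction(p).d_eff_ratio


# -- optimal anchor-matrix affinity ----------------------------------------


@dataclass(frozen=True)
class PhiOptimum:
    phi_star: float
    d_eff_min: float
    interior: bool
    degenerate: bool
    phi_grid: np.ndarray
    d_eff_grid: np.ndarray


def phi_minimizer(
    dp: DimensionlessParameters,
    resolution: int = 201,
    engine: str = "qss",
) -> PhiOptimum:
    """Grid-search the free-anchor fraction minimizing D_eff/D_P.

    For a single binding site (N = 1) the minimum sits at φ = 0 (permanent
    anchors are best); with many sites and fast matrix exchange the optimum
    is interior, typically φ* ~ 0.2-0.4.  ``engine`` selects the
    closed-form reduction ('qss') or the exact chain ('exact'), which also
    resolves the slow-exchange regime where the reduction does not apply.
    """
    from .chain import d_eff_exact  # local import to avoid cycle at import time

    evaluate = {"qss": d_eff_qss, "exact": d_eff_exact}[engine]
    phis = np.linspace(0.0, 1.0, resolution)
    vals = np.array([evaluate(from_dimensionless(dp.with_(phi=float(ph)))) for ph in phis])
    i = int(np.argmin(vals))
    degenerate = bool(np.ptp(vals) < 1e-12)
    return PhiOptimum(
        phi_star=float(phis[i]),
        d_eff_min=float(vals[i]),
        interior=bool(0 < i < resolution - 1 and not degenerate),
        degenerate=degenerate,
        phi_grid=phis,
        d_eff_grid=vals,
    )


# -- crowded matrix: saturation and multi-species robustness ---------------


@dataclass(frozen=True)
class SaturatedRegime:
    """Asymptotic rates and D_eff when anchors far outnumber matrix sites.

    For total anchor concentration [A_T] >> [M], the fraction of time a
    matrix site is unoccupied is

        xi = a_off / ((A_T/M) a_on + a_off)  ~  a_off [M] / (a_on [A_T]),

    so a free anchor binds the matrix at ``a_on' = xi a_on`` and the
    intra-complex rate becomes ``a_on'' = C a_off [M]/[A_T]``.  The
    effective free fraction and unbound-site probability follow as
    phi ~ 1 - [M]/[A_T] and alpha ~ 1 - C [M]/[A_T], and the anchor-matrix
    timescale relaxes to roughly 1/a_off.
    """

    conc_A_total: float
    xi: float
    xi_approx: float
    a_on_prime: float
    a_on_intra: float
    tau_AM_saturated: float
    phi_eff: float
    alpha_eff: float
    d_eff_ratio: float


def saturated_regime(p: TrappingParameters, conc_A_total: float) -> SaturatedRegime:
    """Evaluate the saturated-matrix asymptotics for total anchor load ``conc_A_total``.

    ``p`` describes the focal species; its own concentration ``p.conc_A``
    is the per-species concentration entering the encounter rates.  A
    warning is issued when [A_T] < [M], outside the regime of validity.
    """
    if conc_A_total <= 0 or p.conc_M <= 0:
        raise ValueError("conc_A_total and conc_M must be > 0")
    ratio = conc_A_total / p.conc_M  # [A_T]/[M]
    if ratio < 1.0:
        warnings.warn(
            "saturated-regime formulas assume [A_T] >> [M]; "
            f"got [A_T]/[M] = {ratio:.3g}", stacklevel=2)
    denom = ratio * p.a_on + p.a_off
    xi = p.a_off / denom if denom > 0 else 1.0
    xi_approx = p.a_off / (ratio * p.a_on) if p.a_on > 0 else math.inf
    r = 1.0 / ratio  # [M]/[A_T]
    phi_eff = max(0.0, 1.0 - r)
    alpha_eff = max(0.0, 1.0 - p.C * r)
    a_on_prime = xi * p.a_on
    a_on_intra = p.C * p.a_off * r
    tau_AM_sat = 1.0 / ((1.0 + r) * p.a_off) if p.a_off > 0 else math.inf
    # D_eff via the reduction with the substituted phi/alpha and the focal
    # species' own concentration
    k_scale = p.conc_AR0
    k_on = (p.D_P + p.D_A) * phi_eff * k_scale
    k_on_prime = (p.D_P + p.D_M) * (1.0 - phi_eff) * k_scale
    d_eff = _d_eff_from_pieces(p.N, alpha_eff, k_on, k_on_prime, p.k_off, p.D_A, p.D_P, p.C)
    return SaturatedRegime(
        conc_A_total=conc_A_total, xi=xi, xi_approx=xi_approx,
        a_on_prime=a_on_prime, a_on_intra=a_on_intra,
        tau_AM_saturated=tau_AM_sat, phi_eff=phi_eff, alpha_eff=alpha_eff,
        d_eff_ratio=d_eff,
    )


def _d_eff_from_pieces(N, alpha, k_on, k_on_prime, k_off, D_A, D_P, C) -> float:
    rho0 = np.array([rho_s_given_n(n, alpha, D_A, D_P, C)[0] for n in range(N + 1)])
    kappa = k_on + rho0 * k_on_prime
    log_w = np.zeros(N + 1)
    for n in range(1, N + 1):
        if kappa[n - 1] <= 0:
            log_w[n:] = -np.inf
            break
        log_w[n] = (
            log_w[n - 1] + math.log(N - n + 1) - math.log(n)
            + math.log(kappa[n - 1]) - math.log(k_off)
        )
    rho = np.exp(log_w - np.logaddexp.reduce(log_w))
    return float(np.dot(rho0, rho))


def competition_parameters(p: TrappingParameters, n_species: int) -> TrappingParameters:
    """Focal-species parameters when ``n_species`` identical anchor species compete.

    Each matrix binding site is modeled as an independent two-state unit
    bombarded by the total anchor pool [A_T] = n_species * [A]: it is
    unoccupied a fraction

        xi = a_off / ((A_T/M) a_on + a_off)

    of the time, which rescales every anchor's matrix on-rate to
    ``xi a_on``.  This reduces, for [A_T] >> [M], to the saturated-regime
    asymptotics; for [A_T] -> 0 it returns ``p`` unchanged.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    u = n_species * p.conc_A / p.conc_M
    denom = u * p.a_on + p.a_off
    xi = p.a_off / denom if denom > 0 else 1.0
    return p.with_(a_on=xi * p.a_on)


def species_sweep(
    p: TrappingParameters,
    species_counts: np.ndarray | list[int],
    engine: str = "exact",
) -> pd.DataFrame:
    """Focal-species D_eff/D_P as identical competitor species are added.

    Competition only hurts: the focal D_eff/D_P is nondecreasing in the
    species count.  ``engine`` is 'exact' (stationary chain solve; resolves
    slow anchor-matrix kinetics) or 'qss'.
    """
    from .chain import d_eff_exact

    evaluate = {"qss": d_eff_qss, "exact": d_eff_exact}[engine]
    rows = []
    for m in species_counts:
        pm = competition_parameters(p, int(m))
        rows.append({
            "n_species": int(m),
            "conc_A_total": m * p.conc_A,
            "occupancy_load": m * p.conc_A / p.conc_M,
            "d_eff_ratio": evaluate(pm),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SpeciesCapacity:
    """How many co-existing anchor species a gel supports per panel of kinetics."""

    tau_ratio: float
    conc_dimless: float
    conc_A_per_species: float
    phi_star: float
    d_eff_single: float
    capacity: int
    threshold: float


def species_capacity(
    tau_ratio: float,
    d_ratio: float = 20.0,
    N: int = 20,
    conc_M: float = 1.0e5,
    R0: float = 10.0 / (21.0 * 4.0),
    C: float = 1.0,
    design_potency: float = 0.02,
    loss_factor: float = 2.0,
    phi_resolution: int = 30,
    max_species: int = 5_000_000,
    engine: str = "exact",
) -> SpeciesCapacity:
    """Number of simultaneously trapped species before potency degrades.

    The study condition: each anchor species is dosed at the minimum
    concentration achieving a single-species D_eff/D_P of
    ``design_potency`` at its optimal free fraction (the "sufficient for
    trapping" dose; the default 0.02 corresponds to a 98% reduction and
    lands at roughly 1 µg/mL for IgG-like anchors with the default
    ``R0``).  The capacity is the largest species count at which the focal
    species' D_eff/D_P is still within ``loss_factor`` times its
    single-species value.  Slow anchor-matrix exchange both demands more
    anchor per species and monopolizes matrix sites, collapsing the
    capacity by orders of magnitude relative to fast exchange.
    """
    from .chain import d_eff_exact

    evaluate = {"qss": d_eff_qss, "exact": d_eff_exact}[engine]
    phis = np.linspace(0.001, 0.95, phi_resolution)

    def best_over_phi(conc: float) -> tuple[float, float]:
        best_phi, best_val = 0.0, np.inf
        for ph in phis:
            dp = DimensionlessParameters(
                d_ratio=d_ratio, N=N, tau_ratio=tau_ratio,
                conc_dimless=conc, phi=float(ph), C=C)
            val = evaluate(from_dimensionless(dp, R0=R0, conc_M=conc_M))
            if val < best_val:
                best_phi, best_val = float(ph), val
        return best_phi, best_val

    # minimum trapping-sufficient concentration (bisect in log space)
    lo, hi = 0.05, 200.0
    if best_over_phi(hi)[1] > design_potency:
        raise ValueError(
            f"design potency {design_potency} unreachable at tau_ratio={tau_ratio}")
    for _ in range(40):
        mid = math.sqrt(lo * hi)
        if best_over_phi(mid)[1] <= design_potency:
            hi = mid
        else:
            lo = mid
    conc_star = hi
    phi_star, d_single = best_over_phi(conc_star)
    dp = DimensionlessParameters(
        d_ratio=d_ratio, N=N, tau_ratio=tau_ratio,
        conc_dimless=conc_star, phi=phi_star, C=C)
    p = from_dimensionless(dp, R0=R0, conc_M=conc_M)
    threshold = loss_factor * d_single

    def deff_at(m: int) -> float:
        return evaluate(competition_parameters(p, m))

    if deff_at(max_species) <= threshold:
        return SpeciesCapacity(tau_ratio, conc_star, p.conc_A, phi_star,
                               d_single, max_species, threshold)
    mlo, mhi = 1, max_species  # D_eff nondecreasing in m: bisect
    while mhi - mlo > 1:
        mm = min(max(mlo + 1, int(math.sqrt(mlo * mhi))), mhi - 1)
        if deff_at(mm) <= threshold:
            mlo = mm
        else:
            mhi = mm
    return SpeciesCapacity(
        tau_ratio=tau_ratio, conc_dimless=conc_star,
        conc_A_per_species=p.conc_A, phi_star=phi_star,
        d_eff_single=d_single, capacity=mlo, threshold=threshold,
    )
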