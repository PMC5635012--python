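"""Penetration of a particle across a gel layer from the homogenized equation.

Once the binding chain is averaged out, the particle diffuses with
D_eff <= D_P.  The probability that a particle deposited on the outer face
of a layer of thickness L crosses it within time T (reflecting boundary at
the entry face x = 0, absorbing at x = L) follows from the classical
eigenfunction expansion of the survival probability:

    P_absorb(T) = 1 - sum_{k>=0} 4 (-1)^k / ((2k+1) pi)
                      * exp(-D_eff (2k+1)^2 pi^2 T / (4 L^2)).

A low absorption probability means an effective diffusional barrier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import DimensionlessParameters, from_dimensionless
from .qss import d_eff_qss


@dataclass(frozen=True)
class PenetrationResult:
    """Absorption probability of the slab first-passage problem."""

    d_eff: float
    L: float
    T: float
    probability: float
    n_terms: int
    truncation_bound: float

    def __float__(self) -> float:
        return self.probability


def penetration_probability(
    d_eff: float, L: float, T: float, tol: float = 1e-12, max_terms: int = 100_000
) -> PenetrationResult:
    """Probability of crossing a layer of thickness ``L`` within time ``T``.

    The alternating series is truncated once the next term falls below
    ``tol``; at T = 0 the result is exactly 0.  The probability is
    nondecreasing in T and D_eff and nonincreasing in L.
    """
    if d_eff < 0 or L <= 0 or T < 0:
        raise ValueError("need d_eff >= 0, L > 0, T >= 0")
    if T == 0 or d_eff == 0:
        return PenetrationResult(d_eff, L, T, 0.0, 0, 0.0)
    survival = 0.0
    k = 0
    rate0 = d_eff * math.pi**2 * T / (4.0 * L**2)
    while k < max_terms:
        term = 4.0 * (-1) ** k / ((2 * k + 1) * math.pi) * math.exp(-rate0 * (2 * k + 1) ** 2)
        survival += term
        k += 1
        nxt = 4.0 / ((2 * k + 1) * math.pi) * math.exp(-rate0 * (2 * k + 1) ** 2)
        if nxt < tol:
            break
    prob = min(1.0, max(0.0, 1.0 - survival))
    return PenetrationResult(d_eff, L, T, prob, k, nxt)


def penetration_sweep(
    dp_base: DimensionlessParameters,
    phi: np.ndarray | list[float] | None = None,
    tau_ratio: np.ndarray | list[float] | None = None,
    conc: np.ndarray | list[float] | None = None,
    L: np.ndarray | list[float] | None = None,
    D_P: float = 2.0,
    T: float = 7200.0,
    engine: str = "qss",
) -> pd.DataFrame:
    """Tidy grid of D_eff/D_P and absorption probability over parameter axes.

    Every combination of the supplied axes (any omitted axis collapses to
    the value in ``dp_base``) is realized through the dimensionless map,
    reduced to D_eff with the chosen engine ('qss' or 'exact'), and pushed
    through the slab series at the stated physical D_P, L and T.  The
    physical D_P only matters here: penetration, unlike D_eff/D_P, is
    quoted for a concrete particle, and ~2 µm²/s is the
    Stokes-Einstein scale of a ~200 nm particle in watery gel fluid at
    body temperature.
    """
    from .chain import d_eff_exact

    evaluate = {"qss": d_eff_qss, "exact": d_eff_exact}[engine]
    phis = np.atleast_1d(phi if phi is not None else dp_base.phi).astype(float)
    taus = np.atleast_1d(tau_ratio if tau_ratio is not None else dp_base.tau_ratio).astype(float)
    concs = np.atleast_1d(conc if conc is not None else dp_base.conc_dimless).astype(float)
    Ls = np.atleast_1d(L if L is not None else 50.0).astype(float)
    rows = []
    for tr in taus:
        for cc in concs:
            for ph in phis:
                dp = dp_base.with_(phi=float(ph), tau_ratio=float(tr), conc_dimless=float(cc))
                ratio = evaluate(from_dimensionless(dp))
                for ll in Ls:
                    prob = penetration_probability(ratio * D_P, float(ll), T).probability
                    rows.append({
                        "phi": float(ph), "tau_ratio": float(tr), "conc": float(cc),
                        "L": float(ll), "T": T, "D_P": D_P,
                        "d_eff_ratio": ratio, "p_absorb": prob,
                    })
    return pd.DataFrame(rows)
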