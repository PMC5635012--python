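"""Model parameters for anchor-mediated trapping of nanoparticulates in biogels.

The model has three reactive species: freely diffusing nanoparticulates P
(viruses, nanoparticles) with ``N`` independent anchor-binding sites, small
mobile molecular anchors A (e.g. IgG) that bind both the particle and the
gel, and immobile matrix binding sites M (mucin fibers, laminin, ...).
Anchors exchange with the matrix at rates ``a_on``/``a_off`` and with the
particle at Smoluchowski encounter-limited on-rates and unbind rate
``k_off``.  A particle is trapped whenever at least one of its bound anchors
is simultaneously bound to the matrix.

This module defines the parameter containers, unit conversions, derived
rates and timescales, and the dimensionless parameterization used for all
parameter sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

AVOGADRO = 6.02214076e23

#: Default particle volume (µm³): a 200 nm-diameter sphere.
DEFAULT_PARTICLE_VOLUME = 4.0 / 3.0 * math.pi * 0.1**3


class UndefinedParameterError(ValueError):
    """A quantity is undefined for the supplied rates (e.g. 0/0)."""


@dataclass(frozen=True)
class TrappingParameters:
    """Physical rates, diffusivities, concentrations and geometry.

    Units: diffusivities µm²/s, concentrations µm⁻³, rates 1/s, lengths µm,
    times s.  ``R0`` is the effective encounter parameter of the
    Smoluchowski relation, lumped so that ``(D_P + D_A) * conc_A * R0`` has
    units of 1/s (any geometric 4π factor is absorbed into ``R0``).

    ``D_M`` defaults to zero: the polymer matrix is effectively immobile.
    ``C`` rescales the intra-complex anchor-matrix binding rate relative to
    the bulk rate and defaults to 1.
    """

    D_P: float = 1.0
    D_A: float = 20.0
    D_M: float = 0.0
    conc_A: float = 0.0
    conc_M: float = 1.0e5
    R0: float = 1.0
    a_on: float = 0.0
    a_off: float = 0.0
    k_off: float = 1.0
    C: float = 1.0
    N: int = 15
    V_P: float = DEFAULT_PARTICLE_VOLUME
    L: float = 50.0
    T: float = 7200.0

    def __post_init__(self) -> None:
        nonneg = (
            "D_P", "D_A", "D_M", "conc_A", "conc_M", "R0",
            "a_on", "a_off", "k_off", "C", "V_P", "L", "T",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not isinstance(self.N, (int,)) or isinstance(self.N, bool):
            if float(self.N).is_integer():
                object.__setattr__(self, "N", int(self.N))
            else:
                raise ValueError(f"N must be an integer >= 0, got {self.N}")
        if self.N < 0:
            raise ValueError(f"N must be an integer >= 0, got {self.N}")

    # -- derived quantities -------------------------------------------------

    @property
    def phi(self) -> float:
        """Steady-state free fraction of anchors a_off/(a_on + a_off)."""
        return free_fraction(self.a_on, self.a_off)

    @property
    def alpha(self) -> float:
        """Intra-complex unbound probability a_off/(C a_on + a_off)."""
        denom = self.C * self.a_on + self.a_off
        if denom == 0:
            raise UndefinedParameterError("alpha undefined: C*a_on + a_off == 0")
        return self.a_off / denom

    @property
    def conc_AR0(self) -> float:
        """The product [A]·R0 (µm⁻¹ equivalent rate scale)."""
        return self.conc_A * self.R0

    def with_(self, **changes: Any) -> "TrappingParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class DimensionlessParameters:
    """The dimensionless knobs spanned by the parameter sweeps.

    ``conc_dimless`` is the anchor concentration scale
    ``[A](D_P + D_A)R0 / k_off``: the φ-independent version of the
    "[A]k_on/k_off" axis, so that the φ = 0 column remains meaningful.
    """

    d_ratio: float = 20.0
    N: int = 15
    tau_ratio: float = 20.0
    conc_dimless: float = 2.0
    phi: float = 0.3
    C: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must lie in [0, 1], got {self.phi}")
        for name in ("d_ratio", "tau_ratio", "conc_dimless", "C"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.N < 0 or int(self.N) != self.N:
            raise ValueError("N must be an integer >= 0")
        object.__setattr__(self, "N", int(self.N))

    def with_(self, **changes: Any) -> "DimensionlessParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class Timescales:
    """The three competing timescales of the trapping problem (seconds)."""

    tau_L: float
    tau_AM: float
    tau_AP: float


def free_fraction(a_on: float, a_off: float) -> float:
    """Steady-state fraction of anchors not bound to the matrix.

    φ = a_off / (a_on + a_off); φ = 1 means anchors never bind the matrix,
    φ = 0 means permanently matrix-bound anchors.
    """
    denom = a_on + a_off
    if denom == 0:
        raise UndefinedParameterError("free fraction undefined: a_on + a_off == 0")
    return a_off / denom


def smoluchowski_rates(p: TrappingParameters) -> tuple[float, float]:
    """Encounter-limited particle-binding rates (k_on, k_on_prime).

    k_on is the rate at which free anchors bind the particle,
    k_on' the rate at which matrix-bound anchors do; both are proportional
    to the relative diffusivity of the encounter pair:

        k_on  = (D_P + D_A) φ [A] R0
        k_on' = (D_P + D_M) (1-φ) [A] R0
    """
    phi = p.phi
    k_on = (p.D_P + p.D_A) * phi * p.conc_AR0
    k_on_prime = (p.D_P + p.D_M) * (1.0 - phi) * p.conc_AR0
    return k_on, k_on_prime


def timescales(p: TrappingParameters) -> Timescales:
    """Diffusive passage, anchor-matrix, and anchor-particle timescales.

    tau_L = L²/(2 D_P), tau_AM = 1/(a_on + a_off),
    tau_AP = 1/(D_A [A] R0 + k_off).
    """
    if p.D_P <= 0:
        raise UndefinedParameterError("tau_L undefined for D_P == 0")
    tau_L = p.L**2 / (2.0 * p.D_P)
    denom_am = p.a_on + p.a_off
    if denom_am == 0:
        raise UndefinedParameterError("tau_AM undefined: a_on + a_off == 0")
    denom_ap = p.D_A * p.conc_AR0 + p.k_off
    if denom_ap == 0:
        raise UndefinedParameterError("tau_AP undefined: D_A [A] R0 + k_off == 0")
    return Timescales(tau_L=tau_L, tau_AM=1.0 / denom_am, tau_AP=1.0 / denom_ap)


def from_dimensionless(
    dp: DimensionlessParameters,
    k_off_scale: float = 1.0,
    D_P_scale: float = 1.0,
    R0: float = 1.0,
    **geometry: Any,
) -> TrappingParameters:
    """Realize a dimensionless parameter point as physical parameters.

    The scales fix the units: k_off = ``k_off_scale`` sets the clock and
    D_P = ``D_P_scale`` the length²/time scale.  All reported dimensionless
    outputs (D_eff/D_P, penetration probability at stated L, T) are
    invariant to these choices.  Extra keyword arguments (conc_M, V_P, L,
    T, D_M) are passed through to :class:`TrappingParameters`.

    Round-trips exactly with :func:`to_dimensionless`.
    """
    if k_off_scale <= 0 or D_P_scale <= 0 or R0 <= 0:
        raise ValueError("k_off_scale, D_P_scale and R0 must be > 0")
    D_P = D_P_scale
    D_A = dp.d_ratio * D_P
    conc_A = dp.conc_dimless * k_off_scale / ((D_P + D_A) * R0)
    if dp.tau_ratio <= 0:
        raise ValueError("tau_ratio must be > 0 to place the anchor-matrix clock")
    tau_AP = 1.0 / (D_A * conc_A * R0 + k_off_scale)
    rate_sum = dp.tau_ratio / tau_AP  # a_on + a_off = tau_ratio / tau_AP
    a_off = dp.phi * rate_sum
    a_on = (1.0 - dp.phi) * rate_sum
    return TrappingParameters(
        D_P=D_P,
        D_A=D_A,
        conc_A=conc_A,
        R0=R0,
        a_on=a_on,
        a_off=a_off,
        k_off=k_off_scale,
        C=dp.C,
        N=dp.N,
        **geometry,
    )


def to_dimensionless(p: TrappingParameters) -> DimensionlessParameters:
    """Project physical parameters onto the dimensionless knobs."""
    if p.D_P <= 0 or p.k_off <= 0:
        raise UndefinedParameterError("nondimensionalization needs D_P > 0 and k_off > 0")
    ts = timescales(p)
    return DimensionlessParameters(
        d_ratio=p.D_A / p.D_P,
        N=p.N,
        tau_ratio=ts.tau_AP / ts.tau_AM,
        conc_dimless=p.conc_A * (p.D_P + p.D_A) * p.R0 / p.k_off,
        phi=p.phi,
        C=p.C,
    )


# -- anchor spacing arithmetic ---------------------------------------------


def mass_to_number_conc(mass_conc: float, molar_mass: float) -> float:
    """µg/mL of a ``molar_mass``-kDa species -> number concentration (µm⁻³)."""
    if mass_conc < 0 or molar_mass <= 0:
        raise ValueError("mass_conc must be >= 0 and molar_mass > 0")
    # µg/mL = 1e-6 g / 1e12 µm³; molar mass in g/mol = 1e3 * kDa
    return mass_conc * 1.0e-6 / (molar_mass * 1.0e3) * AVOGADRO / 1.0e12


def number_to_mass_conc(number_conc: float, molar_mass: float) -> float:
    """Number concentration (µm⁻³) -> µg/mL for a ``molar_mass``-kDa species."""
    if number_conc < 0 or molar_mass <= 0:
        raise ValueError("number_conc must be >= 0 and molar_mass > 0")
    return number_conc * 1.0e12 * molar_mass * 1.0e3 / AVOGADRO * 1.0e6


def anchor_spacing(mass_conc: float, molar_mass: float = 150.0) -> float:
    """Mean nearest-anchor spacing (nm) at a bulk mass concentration.

    The spacing is the cube root of the volume per molecule.  At IgG-like
    concentrations of 1-3 µg/mL (150 kDa) this is roughly 440-630 nm, far
    larger than a 100-200 nm particle: a particle cannot straddle two
    immobilized anchors at once.

    Returns ``inf`` for zero concentration.
    """
    nu = mass_to_number_conc(mass_conc, molar_mass)  # µm^-3
    if nu == 0:
        return math.inf
    return nu ** (-1.0 / 3.0) * 1.0e3


def conc_for_spacing(spacing: float, molar_mass: float = 150.0) -> float:
    """Mass concentration (µg/mL) giving a mean anchor spacing of ``spacing`` nm.

    Exact inverse of :func:`anchor_spacing`; e.g. a 100 nm spacing of a
    150 kDa anchor requires about 250 µg/mL.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    nu = (spacing / 1.0e3) ** -3.0  # µm^-3
    return number_to_mass_conc(nu, molar_mass)


# -- operating-regime report -----------------------------------------------


@dataclass(frozen=True)
class ConditionCheck:
    name: str
    satisfied: bool
    ratio: float
    description: str


@dataclass(frozen=True)
class RegimeReport:
    """Boolean report on the six conditions for robust crosslink trapping."""

    conditions: dict[str, ConditionCheck] = field(default_factory=dict)
    factor: float = 10.0

    @property
    def all_satisfied(self) -> bool:
        return all(c.satisfied for c in self.conditions.values())

    def __getitem__(self, name: str) -> ConditionCheck:
        return self.conditions[name]


def regime_report(p: TrappingParameters, factor: float = 10.0) -> RegimeReport:
    """Evaluate the six regime conditions for robust trapping.

    "Much greater/less than" is interpreted as a ratio of at least
    ``factor`` (default 10); the strict-inequality condition C4 uses the
    plain comparison.  Each check reports the numeric ratio it evaluated.
    """
    ts = timescales(p)
    checks = {}
    r1 = ts.tau_AP / ts.tau_AM
    checks["C1"] = ConditionCheck(
        "C1", r1 >= factor, r1,
        "anchor-matrix exchange much faster than anchor-particle exchange "
        "(tau_AM << tau_AP)")
    checks["C2"] = ConditionCheck(
        "C2", p.N >= factor, float(p.N),
        "many anchor-binding sites per particle (N >> 1)")
    r3 = p.D_A / p.D_P if p.D_P > 0 else math.inf
    checks["C3"] = ConditionCheck(
        "C3", r3 >= factor, r3, "anchors much more mobile than particle (D_A >> D_P)")
    r4 = ts.tau_L / ts.tau_AP
    checks["C4"] = ConditionCheck(
        "C4", ts.tau_AP < ts.tau_L, r4,
        "anchors accumulate before the particle crosses the layer (tau_AP < tau_L)")
    bound = p.conc_A * (1.0 - p.phi)
    r5 = p.conc_M / bound if bound > 0 else math.inf
    checks["C5"] = ConditionCheck(
        "C5", bound < p.conc_M, r5,
        "matrix-bound anchors do not saturate matrix sites ([A](1-phi) < [M])")
    occupancy = p.conc_A * p.V_P
    r6 = 1.0 / occupancy if occupancy > 0 else math.inf
    checks["C6"] = ConditionCheck(
        "C6", occupancy * factor <= 1.0, r6,
        "less than one anchor per particle volume on average ([A] << 1/V_P)")
    return RegimeReport(conditions=checks, factor=factor)


# -- config files ----------------------------------------------------------

_PHYSICAL_KEYS = {
    "D_P", "D_A", "D_M", "conc_A", "conc_M", "R0",
    "a_on", "a_off", "k_off", "C", "N", "V_P",
}
_DIMLESS_KEYS = {"d_ratio", "N", "tau_ratio", "conc_dimless", "phi", "C"}
_GEOMETRY_KEYS = {"L", "T", "V_P"}


def load_config(path: str | Path) -> dict:
    """Read a YAML config with sections physical | dimensionless | geometry | simulation."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping of sections")
    return cfg


def parameters_from_config(cfg: dict, **overrides: Any) -> TrappingParameters:
    """Build :class:`TrappingParameters` from a parsed config.

    A ``dimensionless`` section is realized through
    :func:`from_dimensionless` (scales ``k_off`` and ``D_P`` may be given in
    its ``scales`` subsection); a ``physical`` section feeds the fields
    directly.  ``geometry`` supplies L, T, V_P.  Keyword overrides win over
    the file.
    """
    geometry = {k: v for k, v in (cfg.get("geometry") or {}).items() if k in _GEOMETRY_KEYS}
    if "dimensionless" in cfg:
        section = dict(cfg["dimensionless"])
        scales = section.pop("scales", {})
        unknown = set(section) - _DIMLESS_KEYS
        if unknown:
            raise ValueError(f"unknown dimensionless keys: {sorted(unknown)}")
        dp = DimensionlessParameters(**section)
        p = from_dimensionless(
            dp,
            k_off_scale=scales.get("k_off", 1.0),
            D_P_scale=scales.get("D_P", 1.0),
            R0=scales.get("R0", 1.0),
            **geometry,
        )
    else:
        section = dict(cfg.get("physical") or {})
        unknown = set(section) - _PHYSICAL_KEYS
        if unknown:
            raise ValueError(f"unknown physical keys: {sorted(unknown)}")
        p = TrappingParameters(**section, **geometry)
    if overrides:
        p = p.with_(**overrides)
    return p
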