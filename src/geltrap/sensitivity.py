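"""Finite-difference sensitivity of log(D_eff/D_P) to the model knobs.

The sensitivity of the trapping potency to a parameter p is

    S(p) = d log(D_eff/D_P) / d p,

evaluated by central finite differences on the exact-chain stationary
solution (the default engine, which remains meaningful at slow
anchor-matrix exchange where the closed-form reduction does not apply).
The four knobs are the timescale separation tau_AP/tau_AM, the
dimensionless anchor concentration, the binding-site count N (differenced
on the integer lattice) and the anchor/particle diffusivity ratio.

The diffusivity ratio is perturbed at fixed *physical* anchor
concentration [A]R0 — more mobile anchors find the particle faster — so
its sensitivity reflects anchor mobility rather than the dilution that a
fixed dimensionless concentration would imply.  Both the absolute-step
derivative and the relative (per log-parameter) form are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chain import d_eff_exact
from .params import DimensionlessParameters, from_dimensionless
from .qss import d_eff_qss

PARAMETERS = ("tau_ratio", "conc_dimless", "N", "d_ratio")


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    point: DimensionlessParameters
    step: float
    value: float  # d log(D_eff/D_P) / d p
    value_relative: float  # d log(D_eff/D_P) / d log p
    converged: bool
    engine: str


def _log_deff(dp: DimensionlessParameters, engine: str) -> float:
    evaluate = {"qss": d_eff_qss, "exact": d_eff_exact}[engine]
    val = evaluate(from_dimensionless(dp))
    if val <= 0:
        raise ValueError("D_eff/D_P vanished; log-sensitivity undefined")
    return math.log(val)


def _perturbed(dp: DimensionlessParameters, name: str, value: float) -> DimensionlessParameters:
    if name == "d_ratio":
        # hold the physical concentration [A]R0 fixed while D_A changes
        scale = (1.0 + value) / (1.0 + dp.d_ratio)
        return dp.with_(d_ratio=value, conc_dimless=dp.conc_dimless * scale)
    return dp.with_(**{name: value})


def sensitivity(
    dp: DimensionlessParameters,
    parameter: str,
    rel_step: float = 1e-3,
    engine: str = "exact",
    max_halvings: int = 8,
    rtol: float = 0.01,
) -> SensitivityResult:
    """Central-difference sensitivity of log(D_eff/D_P) at the point ``dp``.

    The step starts at ``rel_step`` times the parameter value and is halved
    until two successive central estimates agree within ``rtol``.  The
    integer parameter N uses unit forward/backward differences instead.
    A parameter with no effect (e.g. anything but concentration on the
    zero-concentration axis) reports a sensitivity of exactly 0.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"parameter must be one of {PARAMETERS}")
    p0 = getattr(dp, parameter)

    if parameter == "N":
        f0 = _log_deff(dp, engine)
        if dp.N >= 1:
            up = _log_deff(dp.with_(N=dp.N + 1), engine)
            dn = _log_deff(dp.with_(N=dp.N - 1), engine)
            val = (up - dn) / 2.0
        else:
            val = _log_deff(dp.with_(N=1), engine) - f0
        return SensitivityResult(parameter, dp, 1.0, val, val * max(p0, 1),
                                 converged=True, engine=engine)

    if p0 <= 0:
        raise ValueError(f"cannot take a relative step at {parameter} = {p0}")
    h = rel_step * p0
    prev = None
    converged = False
    for _ in range(max_halvings):
        up = _log_deff(_perturbed(dp, parameter, p0 + h), engine)
        dn = _log_deff(_perturbed(dp, parameter, p0 - h), engine)
        est = (up - dn) / (2.0 * h)
        if prev is not None:
            scale = max(abs(est), abs(prev), 1e-300)
            if abs(est - prev) <= rtol * scale or abs(est - prev) < 1e-12:
                converged = True
                break
        prev = est
        h /= 2.0
    return SensitivityResult(parameter, dp, h, est, est * p0,
                             converged=converged, engine=engine)


def sensitivity_table(
    dp: DimensionlessParameters,
    parameters: tuple[str, ...] = PARAMETERS,
    engine: str = "exact",
    **kwargs,
) -> pd.DataFrame:
    """All requested sensitivities at one evaluation point as a tidy table."""
    rows = []
    for name in parameters:
        r = sensitivity(dp, name, engine=engine, **kwargs)
        rows.append({
            "parameter": name, "point_value": getattr(dp, name),
            "step": r.step, "sensitivity": r.value,
            "sensitivity_relative": r.value_relative, "converged": r.converged,
        })
    return pd.DataFrame(rows)


def sensitivity_profile(
    dp: DimensionlessParameters,
    parameter: str,
    grid: np.ndarray | list[float],
    engine: str = "exact",
    **kwargs,
) -> pd.DataFrame:
    """Sensitivity to ``parameter`` evaluated along a grid of its values."""
    rows = []
    for value in grid:
        point = _perturbed(dp, parameter, float(value)) if parameter == "d_ratio" \
            else dp.with_(**{parameter: float(value) if parameter != "N" else int(value)})
        r = sensitivity(point, parameter, engine=engine, **kwargs)
        rows.append({
            parameter: value, "sensitivity": r.value,
            "sensitivity_relative": r.value_relative,
        })
    return pd.DataFrame(rows)
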