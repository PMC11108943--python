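"""Farquhar–von Caemmerer–Berry (FvCB) photosynthesis model and the
coupled leaf solver.

The FvCB model expresses net CO2 assimilation as the minimum of three
potential limitations — Rubisco carboxylation, RuBP regeneration
(electron transport), and triose-phosphate utilisation — minus day
respiration.  The coupled solver closes the loop with the diffusion
equation: for a prescribed leaf conductance it finds the unique
(A, C_i) pair that satisfies both the biochemical demand function and
the ternary-corrected supply function simultaneously.

No temperature response is applied: all kinetic constants are taken at
their 25 degC values and the caller is responsible for supplying
parameters appropriate to the measurement temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional

from scipy.optimize import brentq

from .conductance import (
    DEFAULT_GBW,
    DEFAULT_K,
    ChamberState,
    GasExchangeDomainError,
    NonPhysicalConductanceError,
    build_conductance_set,
    intercellular_co2,
)

__all__ = [
    "FvCBParams",
    "CoupledSolution",
    "CoupledSolverError",
    "rubisco_limited_rate",
    "rubp_limited_rate",
    "tpu_limited_rate",
    "net_assimilation",
    "limiting_process",
    "transition_ci",
    "coupled_solve",
]

Mode = Literal["uncorrected", "corrected"]


class CoupledSolverError(RuntimeError):
    """The supply/demand system has no root in the admissible C_i bracket."""


@dataclass(frozen=True)
class FvCBParams:
    """FvCB model parameters at the operating light and temperature.

    Parameters
    ----------
    vcmax : float
        Maximum Rubisco carboxylation rate, umol m-2 s-1.
    j : float
        Electron-transport rate at the operating irradiance,
        umol m-2 s-1 (reported as J_1200 when light is 1200).
    tpu : float or None
        Triose-phosphate-utilisation rate, umol m-2 s-1.  ``None``
        means no TPU limitation is considered (the TPU-limited rate is
        treated as +inf, never binding).
    rd : float
        Day respiration, umol m-2 s-1.
    gamma_star : float
        CO2 photo-compensation point, umol mol-1.
    kc, ko : float
        Michaelis constants of Rubisco for CO2 (umol mol-1) and O2
        (mmol mol-1).
    o2 : float
        Oxygen mole fraction, mmol mol-1.

    Defaults are the Bernacchi-style 25 degC constants with
    vcmax = 50 and j = 100, the standard forward-modelling setting.
    """

    vcmax: float = 50.0
    j: float = 100.0
    tpu: Optional[float] = None
    rd: float = 1.5
    gamma_star: float = 42.75
    kc: float = 404.9
    ko: float = 278.4
    o2: float = 210.0

    def __post_init__(self) -> None:
        for name in ("vcmax", "j", "gamma_star", "kc", "ko", "o2"):
            if getattr(self, name) <= 0:
                raise GasExchangeDomainError(f"{name} must be positive")
        if self.rd < 0:
            raise GasExchangeDomainError("rd must be non-negative")
        if self.tpu is not None and self.tpu <= 0:
            raise GasExchangeDomainError("tpu must be positive or None")
        if self.km <= self.gamma_star:
            raise GasExchangeDomainError("effective K_m must exceed gamma_star")

    @property
    def km(self) -> float:
        """Effective Michaelis term K_c * (1 + O / K_o), umol mol-1."""
        return self.kc * (1.0 + self.o2 / self.ko)

    def with_(self, **kwargs) -> "FvCBParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CoupledSolution:
    """Simultaneous solution of the supply and demand functions."""

    a: float
    ci: float
    e: float
    limitation: str
    residual: float
    g_tc: float


def rubisco_limited_rate(ci: float, params: FvCBParams) -> float:
    """Gross Rubisco-limited carboxylation rate A_c, umol m-2 s-1.

    ``vcmax * (ci - gamma_star) / (ci + km)``; negative below the
    photo-compensation point, asymptoting to vcmax at high C_i.
    """
    if ci < 0:
        raise GasExchangeDomainError(f"ci must be non-negative, got {ci}")
    return params.vcmax * (ci - params.gamma_star) / (ci + params.km)


def rubp_limited_rate(ci: float, params: FvCBParams) -> float:
    """Gross RuBP-regeneration-limited rate A_j, umol m-2 s-1.

    ``j * (ci - gamma_star) / (4 ci + 8 gamma_star)``; saturates at
    j/4.
    """
    if ci < 0:
        raise GasExchangeDomainError(f"ci must be non-negative, got {ci}")
    return params.j * (ci - params.gamma_star) / (4.0 * ci + 8.0 * params.gamma_star)


def tpu_limited_rate(params: FvCBParams) -> float:
    """Gross TPU-limited rate, 3*TPU; +inf when TPU is absent."""
    if params.tpu is None:
        return math.inf
    return 3.0 * params.tpu


def limiting_process(ci: float, params: FvCBParams) -> str:
    """Which potential rate binds at this C_i: Rubisco, RuBP, or TPU."""
    rates = {
        "Rubisco": rubisco_limited_rate(ci, params),
        "RuBP": rubp_limited_rate(ci, params),
        "TPU": tpu_limited_rate(params),
    }
    return min(rates, key=rates.get)


def net_assimilation(ci: float, params: FvCBParams) -> float:
    """Net assimilation A = min(A_c, A_j, A_p) - R_d (hard minimum).

    The hard minimum keeps the limitation-transition points exact
    intersections; smoothing, where wanted, is a fitting-side option.
    """
    gross = min(
        rubisco_limited_rate(ci, params),
        rubp_limited_rate(ci, params),
        tpu_limited_rate(params),
    )
    return gross - params.rd


def transition_ci(params: FvCBParams, which: Literal["first", "second"] = "first") -> Optional[float]:
    """C_i at a limitation transition, or ``None`` when it does not exist.

    ``first``  — Rubisco -> RuBP intersection (C_itrans1), present when
    ``4 vcmax > j``.
    ``second`` — RuBP -> TPU intersection (C_itrans2), present when TPU
    is finite and ``j > 12 tpu``.  Absence is a normal outcome (the
    curve simply never reaches the next limitation).
    """
    if which == "first":
        denom = 4.0 * params.vcmax - params.j
        if denom <= 0:
            return None
        return (params.j * params.km - 8.0 * params.gamma_star * params.vcmax) / denom
    if which == "second":
        if params.tpu is None:
            return None
        denom = params.j - 12.0 * params.tpu
        if denom <= 0:
            return None
        return params.gamma_star * (params.j + 24.0 * params.tpu) / denom
    raise ValueError(f"which must be 'first' or 'second', got {which!r}")


def coupled_solve(
    g_lw: float,
    g_cw: float = 0.0,
    chamber: ChamberState | None = None,
    params: FvCBParams | None = None,
    mode: Mode = "uncorrected",
    g_bw: float = DEFAULT_GBW,
    k: float = DEFAULT_K,
    xtol: float = 1e-12,
) -> CoupledSolution:
    """Solve the coupled diffusion/biochemistry system for one leaf state.

    Given a leaf conductance to water ``g_lw`` (and in corrected mode a
    cuticular share ``g_cw``), computes the total conductance to CO2
    along the requested pathway, the transpiration
    ``E = g_lw * VPD / P_atm``, and then the unique C_i in
    (gamma_star * 1e-3, C_a] at which the C_i implied by the ternary
    diffusion equation equals the C_i assumed by the demand function.

    Raises
    ------
    NonPhysicalConductanceError
        Corrected mode with ``g_cw >= g_lw``.
    CoupledSolverError
        No sign change in the bracket (e.g. C_a below the operational
        compensation point).
    """
    if chamber is None:
        chamber = ChamberState()
    if params is None:
        params = FvCBParams()
    if g_lw <= 0:
        raise GasExchangeDomainError(f"g_lw must be positive, got {g_lw}")
    if mode not in ("uncorrected", "corrected"):
        raise ValueError(f"mode must be 'uncorrected' or 'corrected', got {mode!r}")

    cond = build_conductance_set(g_lw, g_cw, g_bw=g_bw, k=k, corrected=(mode == "corrected"))
    g_tc = cond.g_tc
    e = g_lw * chamber.vpd / chamber.patm

    def residual_fn(ci: float) -> float:
        return intercellular_co2(net_assimilation(ci, params), e, chamber.ca, g_tc) - ci

    lo = params.gamma_star * 1e-3
    hi = chamber.ca
    f_lo, f_hi = residual_fn(lo), residual_fn(hi)
    if f_lo > 0 and f_hi > 0:
        # net-respiring leaf (C_a at or below the operational
        # compensation point): C_i sits above C_a.  Extend the bracket
        # by the largest possible respiratory drawdown reversal.
        gross_floor = min(
            -params.vcmax * params.gamma_star / params.km, -params.j / 8.0
        )
        hi = chamber.ca + (params.rd - gross_floor) / g_tc + 1.0
        f_hi = residual_fn(hi)
    if f_lo == 0.0:
        ci = lo
    elif f_hi == 0.0:
        ci = hi
    elif f_lo * f_hi > 0:
        raise CoupledSolverError(
            f"no C_i root in ({lo:.4g}, {hi:.4g}]: residuals {f_lo:.4g}, {f_hi:.4g} "
            f"(g_lw={g_lw}, g_cw={g_cw}, mode={mode}, ca={chamber.ca})"
        )
    else:
        ci = brentq(residual_fn, lo, hi, xtol=xtol)
    a = net_assimilation(ci, params)
    return CoupledSolution(
        a=a,
        ci=ci,
        e=e,
        limitation=limiting_process(ci, params),
        residual=residual_fn(ci),
        g_tc=g_tc,
    )
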