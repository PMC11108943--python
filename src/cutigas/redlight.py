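"""Red-light estimation of cuticular conductance.

Under low red light, stomata stay nearly closed while photosynthesis
is electron-transport limited, so C_i can be inferred *biochemically*
— by inverting the RuBP-limited rate equation with the leaf's own
J_a and gamma_star measured from a companion curve — instead of from
the diffusion equation.  With C_i known, the diffusion equation can be
inverted the other way, yielding the leaf conductance to CO2.  The
water-side conductance (measured) and the CO2-side conductance
(inferred) then over-determine the stomatal/cuticular split, because
the two paths discriminate against CO2 so differently (1.6 vs 20):
solving the 2x2 linear system per record gives g_cw directly.

Each reported g_cw is the mean over a steady 5-minute window sampled
every 7 s (42 records), which is what buys the method its precision:
the window mean beats the single-record conductance noise by sqrt(42).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .conductance import (
    CUTICULAR_H2O_CO2_RATIO,
    GasExchangeDomainError,
    STOMATAL_H2O_CO2_RATIO,
)

__all__ = [
    "IdentifiabilityError",
    "RedLightRun",
    "GcwEstimate",
    "estimate_j_gammastar",
    "invert_ci_redlight",
    "leaf_co2_conductance_from_fluxes",
    "solve_gcw",
    "estimate_gcw",
]

#: records in the default steady window (complete 7-s intervals in 5 min)
STEADY_WINDOW_RECORDS = 42


class IdentifiabilityError(ValueError):
    """The companion curve cannot identify (J_a, gamma_star)."""


class EstimationError(RuntimeError):
    """Too few physically valid records to estimate g_cw."""


@dataclass
class RedLightRun:
    """A red-light induction run plus the quantities its analysis needs:
    the dark respiration measured before induction, and (J_a,
    gamma_star) from the companion curve."""

    records: pd.DataFrame
    r_dark: float
    j_a: float
    gamma_star: float

    def steady_window(self) -> pd.DataFrame:
        """The steady-state window: records flagged ``steady`` when a
        phase column is present, otherwise the final 42 records."""
        if "phase" in self.records.columns:
            return self.records[self.records["phase"] == "steady"]
        return self.records.iloc[-STEADY_WINDOW_RECORDS:]


@dataclass(frozen=True)
class GcwEstimate:
    """Window-mean cuticular conductance with its spread."""

    g_cw: float
    sd: float
    g_sw: float
    n_used: int
    n_excluded: int


def estimate_j_gammastar(
    ci: np.ndarray, a: np.ndarray, r_dark: float
) -> tuple[float, float]:
    """Fit (J_a, gamma_star) to a companion A/C_i curve.

    Least squares of the RuBP-limited form
    ``A = J (C_i - gamma_star) / (4 C_i + 8 gamma_star) - R_dark`` with
    R_dark fixed at its measured value.  The curve must extend to low
    C_i or gamma_star is unidentifiable.
    """
    ci = np.asarray(ci, dtype=float)
    a = np.asarray(a, dtype=float)
    if len(ci) < 4:
        raise IdentifiabilityError(f"need at least 4 points, got {len(ci)}")
    if ci.min() >= 300.0:
        raise IdentifiabilityError(
            f"companion curve spans C_i [{ci.min():.0f}, {ci.max():.0f}]; "
            "points below C_i = 300 are required to identify gamma_star"
        )

    def model(c, j, gs):
        return j * (c - gs) / (4.0 * c + 8.0 * gs) - r_dark

    popt, _ = curve_fit(model, ci, a, p0=(60.0, 40.0),
                        bounds=([1.0, 5.0], [2000.0, 200.0]), xtol=1e-12, ftol=1e-12)
    return float(popt[0]), float(popt[1])


def invert_ci_redlight(a: float, r_d: float, j_a: float, gamma_star: float) -> float:
    """C_i from assimilation under electron-transport limitation.

    Algebraic inversion of the RuBP-limited rate: with gross
    assimilation ``G = A + R_d``,
    ``C_i = gamma_star (J_a + 8 G) / (J_a - 4 G)``.
    Valid only for 0 <= G < J_a / 4 (the rate saturates at J_a/4).
    """
    g = a + r_d
    if g >= j_a / 4.0:
        raise GasExchangeDomainError(
            f"gross assimilation {g:.4g} >= J_a/4 = {j_a / 4.0:.4g}: "
            "outside the invertible range of the RuBP-limited rate"
        )
    if g < -1e-9:
        raise GasExchangeDomainError(
            f"gross assimilation {g:.4g} is negative: A below -R_dark"
        )
    return gamma_star * (j_a + 8.0 * g) / (j_a - 4.0 * g)


def leaf_co2_conductance_from_fluxes(a: float, e: float, ca: float, ci: float) -> float:
    """Leaf conductance to CO2 by inverting the ternary C_i equation.

    ``g_lc = (A + (E/2)(C_a + C_i)) / (C_a - C_i)`` — exact inversion
    with the boundary layer taken as non-limiting (g_bw >> g_lw, which
    holds comfortably at red-light conductances).
    """
    if ca <= ci:
        raise GasExchangeDomainError(
            f"C_a={ca} must exceed C_i={ci} for the inversion"
        )
    return (a + (e / 2.0) * (ca + ci)) / (ca - ci)


def solve_gcw(g_lw: float, g_lc: float) -> tuple[float, float]:
    """Split leaf conductance into cuticular and stomatal shares.

    The water side gives ``g_lw = g_sw + g_cw`` and the CO2 side
    ``g_lc = g_sw/1.6 + g_cw/20``; eliminating g_sw:

    ``g_cw = (g_lw/1.6 - g_lc) / (1/1.6 - 1/20)``.

    Returns (g_cw, g_sw).  Values outside [0, g_lw] are returned as
    computed — callers decide whether to flag or exclude the record.
    """
    if g_lw <= 0 or g_lc <= 0:
        raise GasExchangeDomainError(
            f"conductances must be positive, got g_lw={g_lw}, g_lc={g_lc}"
        )
    g_cw = (g_lw / STOMATAL_H2O_CO2_RATIO - g_lc) / (
        1.0 / STOMATAL_H2O_CO2_RATIO - 1.0 / CUTICULAR_H2O_CO2_RATIO
    )
    return g_cw, g_lw - g_cw


def estimate_gcw(run: RedLightRun, max_nonphysical_fraction: float = 0.5) -> GcwEstimate:
    """Window-mean cuticular conductance from a red-light run.

    For each steady-window record: infer C_i from A via the
    electron-transport kinetics, invert the diffusion equation for
    g_lc, and solve the water/CO2 system for (g_cw, g_sw).  Records
    whose split falls outside [0, g_lw] — noise can push individual
    records non-physical — are excluded, with the count reported.
    """
    window = run.steady_window()
    gcw_vals, gsw_vals = [], []
    n_excluded = 0
    for _, rec in window.iterrows():
        try:
            ci = invert_ci_redlight(rec["A"], run.r_dark, run.j_a, run.gamma_star)
            g_lc = leaf_co2_conductance_from_fluxes(rec["A"], rec["E"], rec["Ca"], ci)
            g_cw, g_sw = solve_gcw(rec["gsw"], g_lc)
        except GasExchangeDomainError:
            n_excluded += 1
            continue
        if not (0.0 <= g_cw <= rec["gsw"]):
            n_excluded += 1
            continue
        gcw_vals.append(g_cw)
        gsw_vals.append(g_sw)
    n_used = len(gcw_vals)
    if n_used == 0 or n_excluded > max_nonphysical_fraction * len(window):
        raise EstimationError(
            f"{n_excluded}/{len(window)} steady-window records non-physical; "
            "g_cw estimation failed"
        )
    gcw_arr = np.asarray(gcw_vals)
    return GcwEstimate(
        g_cw=float(gcw_arr.mean()),
        sd=float(gcw_arr.std(ddof=1)) if n_used > 1 else 0.0,
        g_sw=float(np.mean(gsw_vals)),
        n_used=n_used,
        n_excluded=n_excluded,
    )
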