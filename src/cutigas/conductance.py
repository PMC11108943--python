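"""Leaf conductance calculus for gas-exchange analysis.

Infrared gas analyzers report a *leaf* conductance to water vapour
(g_lw) and, by default, treat it as purely stomatal.  When the cuticle
carries a non-negligible share of the water flux, that assumption
inflates the conductance available to CO2 — water crosses the cuticle
roughly 20 times more easily than CO2 does, versus 1.6 times for the
stomatal pore — and with it the inferred intercellular CO2 (C_i).

This module implements the conductance bookkeeping for both pathways:

* **uncorrected** — the instrument convention g_sw := g_lw;
* **corrected**   — partition g_lw = g_sw + g_cw, rebuild the leaf
  conductance to CO2 as g_lc = g_sw/1.6 + g_cw/20, and re-enter the
  standard total-conductance formula through a *pseudo* water-side
  conductance (1.6 x the corrected CO2 conductance) so that any
  downstream component which internally assumes g_tc = g_lw/1.6
  receives the corrected value.

Units follow instrument conventions throughout: conductances and
transpiration E in mol m-2 s-1, assimilation A in umol m-2 s-1, CO2
mole fractions in umol mol-1, pressures in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GasExchangeDomainError",
    "NonPhysicalConductanceError",
    "ChamberState",
    "ConductanceSet",
    "DEFAULT_GBW",
    "DEFAULT_K",
    "STOMATAL_H2O_CO2_RATIO",
    "BOUNDARY_H2O_CO2_RATIO",
    "CUTICULAR_H2O_CO2_RATIO",
    "total_conductance_co2",
    "correct_stomatal_conductance",
    "leaf_conductance_co2",
    "pseudo_glw",
    "intercellular_co2",
    "ci_misestimation",
    "build_conductance_set",
]

#: diffusivity ratio of H2O to CO2 through stomata
STOMATAL_H2O_CO2_RATIO = 1.6
#: diffusivity ratio of H2O to CO2 through the boundary layer
BOUNDARY_H2O_CO2_RATIO = 1.37
#: effective permeability ratio of H2O to CO2 across the cuticle
CUTICULAR_H2O_CO2_RATIO = 20.0

#: default boundary-layer conductance to water, mol m-2 s-1 (3x3 cm chamber)
DEFAULT_GBW = 2.23
#: default adaxial:abaxial stomatal-resistance ratio (hypostomatous limit)
DEFAULT_K = 0.0


class GasExchangeDomainError(ValueError):
    """An input lies outside the physical domain of a gas-exchange formula."""


class NonPhysicalConductanceError(GasExchangeDomainError):
    """A conductance decomposition would yield a non-positive component."""


@dataclass(frozen=True)
class ChamberState:
    """Environmental state of the leaf chamber at one instant.

    Parameters
    ----------
    ca : float
        Ambient (sample-cell) CO2 mole fraction, umol mol-1.
    e : float
        Transpiration rate, mol m-2 s-1.
    vpd : float
        Leaf-to-air vapour-pressure deficit, kPa.
    patm : float
        Atmospheric pressure, kPa.
    t_leaf : float
        Leaf temperature, degrees C.
    """

    ca: float = 400.0
    e: float = 0.0
    vpd: float = 1.5
    patm: float = 101.325
    t_leaf: float = 25.0

    def __post_init__(self) -> None:
        if self.ca <= 0:
            raise GasExchangeDomainError(f"ca must be positive, got {self.ca}")
        if self.patm <= 0:
            raise GasExchangeDomainError(f"patm must be positive, got {self.patm}")
        if self.e < 0:
            raise GasExchangeDomainError(f"e must be non-negative, got {self.e}")


@dataclass(frozen=True)
class ConductanceSet:
    """Full conductance decomposition of a leaf, water side and CO2 side.

    ``corrected`` records which pathway produced the set: the corrected
    pathway satisfies ``g_lw == g_sw + g_cw`` exactly, the uncorrected
    pathway sets ``g_sw == g_lw`` and ``g_cw`` plays no role.
    """

    g_lw: float
    g_sw: float
    g_cw: float
    g_bw: float
    k: float
    g_tc: float
    g_lc: float
    g_sc: float
    g_cc: float
    corrected: bool


def total_conductance_co2(g_sw: float, g_bw: float = DEFAULT_GBW, k: float = DEFAULT_K) -> float:
    """Total (leaf plus boundary-layer) conductance to CO2.

    Combines the stomatal and boundary-layer resistances in series for
    each leaf surface and the two surfaces in parallel, weighted by the
    adaxial:abaxial stomatal-resistance ratio ``k``.  With ``k = 0``
    (all stomata on one surface) the second surface drops out; as
    ``g_bw`` grows without bound the result tends to ``g_sw / 1.6``.
    """
    if g_sw <= 0:
        raise GasExchangeDomainError(f"g_sw must be positive, got {g_sw}")
    if g_bw <= 0:
        raise GasExchangeDomainError(f"g_bw must be positive, got {g_bw}")
    if k < 0:
        raise GasExchangeDomainError(f"k must be non-negative, got {k}")
    first = 1.0 / ((k + 1.0) * STOMATAL_H2O_CO2_RATIO / g_sw + BOUNDARY_H2O_CO2_RATIO / g_bw)
    if k == 0:
        second = 0.0
    else:
        second = k / ((k + 1.0) * STOMATAL_H2O_CO2_RATIO / g_sw + k * BOUNDARY_H2O_CO2_RATIO / g_bw)
    return first + second


def correct_stomatal_conductance(g_lw: float, g_cw: float) -> float:
    """Stomatal conductance to water once the cuticular share is removed.

    Raises
    ------
    NonPhysicalConductanceError
        If ``g_cw >= g_lw`` — the leaf would have non-positive stomatal
        conductance.  Callers working row-wise may catch this and flag
        the record instead.
    """
    if g_lw <= 0:
        raise GasExchangeDomainError(f"g_lw must be positive, got {g_lw}")
    if g_cw < 0:
        raise GasExchangeDomainError(f"g_cw must be non-negative, got {g_cw}")
    if g_cw >= g_lw:
        raise NonPhysicalConductanceError(
            f"g_cw={g_cw} >= g_lw={g_lw}: stomatal conductance would be non-positive"
        )
    return g_lw - g_cw


def leaf_conductance_co2(g_sw: float, g_cw: float) -> float:
    """Leaf conductance to CO2 with separate stomatal and cuticular paths.

    ``g_lc = g_sw/1.6 + g_cw/20`` — the cuticle is far more selective
    against CO2 than the stomatal pore, which is the whole reason the
    correction matters.
    """
    if g_sw < 0 or g_cw < 0:
        raise GasExchangeDomainError(
            f"conductances must be non-negative, got g_sw={g_sw}, g_cw={g_cw}"
        )
    return g_sw / STOMATAL_H2O_CO2_RATIO + g_cw / CUTICULAR_H2O_CO2_RATIO


def pseudo_glw(g_tc_corrected: float) -> float:
    """Water-side conductance that encodes a corrected CO2 conductance.

    Downstream components (including the standard total-conductance
    formula) often assume ``g_tc = g_lw / 1.6``; feeding them
    ``1.6 * g_tc_corrected`` makes them reproduce the corrected value.
    """
    if g_tc_corrected < 0:
        raise GasExchangeDomainError(f"g_tc must be non-negative, got {g_tc_corrected}")
    return STOMATAL_H2O_CO2_RATIO * g_tc_corrected


def intercellular_co2(a: float, e: float, ca: float, g_tc: float) -> float:
    """Intercellular CO2 mole fraction from fluxes (ternary-corrected).

    C_i = ((g_tc - E/2) * C_a - A) / (g_tc + E/2)

    The E/2 terms account for the net outward mass flow of transpired
    water.  With ``e = 0`` this reduces to ``ca - a / g_tc``.  The
    result may legitimately be negative at very low conductance — that
    is the misestimation regime this package quantifies — so no
    clamping is applied; callers should flag negative values as
    unreliable rather than discard them silently.
    """
    denom = g_tc + e / 2.0
    if denom <= 0:
        raise GasExchangeDomainError(f"g_tc + E/2 must be positive, got {denom}")
    return ((g_tc - e / 2.0) * ca - a) / denom


def ci_misestimation(ci_uncorr: float, ci_cor: float) -> float:
    """Proportional misestimation of C_i from ignoring the cuticle.

    ``(C_i_uncorrected - C_i_corrected) / C_i_corrected``; positive when
    the uncorrected calculation overestimates C_i, as expected whenever
    g_cw > 0.
    """
    if ci_cor <= 0:
        raise GasExchangeDomainError(f"ci_cor must be positive, got {ci_cor}")
    return (ci_uncorr - ci_cor) / ci_cor


def build_conductance_set(
    g_lw: float,
    g_cw: float = 0.0,
    g_bw: float = DEFAULT_GBW,
    k: float = DEFAULT_K,
    corrected: bool = True,
) -> ConductanceSet:
    """Assemble the full water-side / CO2-side conductance decomposition.

    In corrected mode the stomatal share is ``g_lw - g_cw`` and the
    total conductance to CO2 is rebuilt through the pseudo water-side
    conductance so the boundary layer still enters the usual way.  In
    uncorrected mode the instrument convention ``g_sw = g_lw`` is used
    and ``g_cw`` is carried for reference only.
    """
    if corrected:
        g_sw = correct_stomatal_conductance(g_lw, g_cw)
        g_lc = leaf_conductance_co2(g_sw, g_cw)
        g_tc = total_conductance_co2(pseudo_glw(g_lc), g_bw, k)
    else:
        g_sw = g_lw
        g_lc = g_sw / STOMATAL_H2O_CO2_RATIO
        g_tc = total_conductance_co2(g_sw, g_bw, k)
    return ConductanceSet(
        g_lw=g_lw,
        g_sw=g_sw,
        g_cw=g_cw,
        g_bw=g_bw,
        k=k,
        g_tc=g_tc,
        g_lc=g_lc,
        g_sc=g_sw / STOMATAL_H2O_CO2_RATIO,
        g_cc=g_cw / CUTICULAR_H2O_CO2_RATIO,
        corrected=corrected,
    )
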