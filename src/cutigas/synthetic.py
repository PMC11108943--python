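"""Synthetic gas-exchange data: an emulator of a portable infrared gas
analyzer (LI-6800 style) running CO2-response protocols on a modelled
leaf.

The generator produces the record streams the analysis modules consume:

* steady-state (SS) A/C_i curves over a 16-setpoint CO2 progression;
* constant-ramp (RACiR) curves at 100 umol mol-1 min-1 logged every
  2 s, with 30 s of endpoint padding on each side of the nominal ramp
  (so an 8-min 100->900 ramp yields a 9-min, 270-record log and a
  19-min 100->2000 ramp a 20-min, 600-record log);
* empty-chamber runs whose apparent assimilation follows a low-order
  polynomial of reference CO2 (the calibration signal) and whose
  reported conductance is pure instrument noise around zero;
* red-light induction runs at 7-s cadence for cuticular-conductance
  estimation.

The leaf model couples first-order stomatal dynamics (target stomatal
opening declines with ambient CO2 above 400 umol mol-1) to the FvCB
demand function through the diffusion equation, partitioning the true
leaf conductance into stomatal and cuticular shares.  The *reported*
columns are then what an instrument would log: Gaussian noise added to
g_lw (sd 0.00415 mol m-2 s-1 by default matches the empty-chamber
noise of the real instrument), and C_i recomputed from the noisy
observables by the uncorrected pathway — exactly the misestimation the
analysis modules are built to quantify.  Ground-truth columns
(``A_true``, ``Ci_true``, ``glw_true``) ride along for closure tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P
from scipy.optimize import brentq

from .conductance import (
    ChamberState,
    GasExchangeDomainError,
    intercellular_co2,
    total_conductance_co2,
)
from .fvcb import CoupledSolverError, FvCBParams, coupled_solve, rubp_limited_rate
from .misestimation import NoiseSpec

__all__ = [
    "SchemaError",
    "GasExchangeRecord",
    "ProtocolSpec",
    "StomatalModel",
    "EmptyChamberSpec",
    "SPECIES_PRESETS",
    "LI6800_COLUMNS",
    "generate_curve",
    "generate_empty_chamber",
    "generate_redlight_run",
    "generate_redlight_companion",
    "read_li6800_csv",
    "write_li6800_csv",
]

#: default SS CO2 setpoint progression, umol mol-1 (16 points)
SS_SETPOINTS = (380, 285, 190, 145, 100, 50, 380, 475, 570, 665, 760, 960, 1160, 1460, 1760, 1960)

#: mandatory columns of the CSV dialect, in write order
LI6800_COLUMNS = ["elapsed", "A", "E", "gsw", "Ca", "Ci", "CO2_r", "Tleaf", "VPDleaf", "Patm", "Qin"]

_MANDATORY = ["elapsed", "A", "E", "gsw", "Ca", "Ci", "CO2_r", "Tleaf", "VPDleaf", "Patm"]


class SchemaError(ValueError):
    """A gas-exchange file is missing a mandatory column."""


@dataclass(frozen=True)
class GasExchangeRecord:
    """One logged instant of chamber state and fluxes (scalar view of a
    data-frame row; the frame is the working container)."""

    elapsed: float
    a: float
    e: float
    g_lw: float
    ca: float
    c_ref: float
    ci: float
    t_leaf: float
    vpd: float
    patm: float
    q_in: float


@dataclass(frozen=True)
class ProtocolSpec:
    """Measurement protocol: what CO2 the chamber sees and when data are
    logged.

    ``endpoint_pad`` is the logged dwell at each ramp endpoint (s); the
    default 30 s per side reproduces the instrument's habit of logging
    one minute beyond the nominal ramp duration.
    """

    kind: str  # "ss" | "racir" | "empty" | "redlight"
    ss_setpoints: Sequence[float] = SS_SETPOINTS
    ramp_start: float = 100.0
    ramp_end: float = 900.0
    ramp_rate: float = 100.0  # umol mol-1 min-1
    log_interval: float = 2.0  # s
    endpoint_pad: float = 30.0  # s per side
    min_wait: float = 60.0  # s, SS
    max_wait: float = 120.0  # s, SS
    cadence: float = 7.0  # s, red-light
    induction_duration: float = 420.0  # s, red-light
    steady_duration: float = 300.0  # s, red-light

    @classmethod
    def steady_state(cls, setpoints: Sequence[float] = SS_SETPOINTS, **kw) -> "ProtocolSpec":
        return cls(kind="ss", ss_setpoints=tuple(setpoints), **kw)

    @classmethod
    def racir(cls, start: float = 100.0, end: float = 900.0, rate: float = 100.0, **kw) -> "ProtocolSpec":
        return cls(kind="racir", ramp_start=start, ramp_end=end, ramp_rate=rate, **kw)

    @classmethod
    def empty(cls, start: float = 100.0, end: float = 900.0, rate: float = 100.0, **kw) -> "ProtocolSpec":
        return cls(kind="empty", ramp_start=start, ramp_end=end, ramp_rate=rate, **kw)

    @classmethod
    def redlight(cls, **kw) -> "ProtocolSpec":
        return cls(kind="redlight", **kw)

    def ramp_timeline(self) -> tuple[np.ndarray, np.ndarray]:
        """(elapsed, C_ref) for a constant ramp with endpoint padding."""
        ramp_duration = abs(self.ramp_end - self.ramp_start) / self.ramp_rate * 60.0
        window = ramp_duration + 2.0 * self.endpoint_pad
        n = int(round(window / self.log_interval))
        t = np.arange(n) * self.log_interval
        direction = 1.0 if self.ramp_end >= self.ramp_start else -1.0
        cref = self.ramp_start + direction * self.ramp_rate / 60.0 * (t - self.endpoint_pad)
        lo, hi = sorted((self.ramp_start, self.ramp_end))
        return t, np.clip(cref, lo, hi)

    def redlight_timeline(self) -> tuple[np.ndarray, np.ndarray]:
        """(elapsed, phase) for a red-light run; the steady window holds
        exactly the number of complete cadence intervals in
        ``steady_duration`` (42 at the 7 s / 300 s defaults)."""
        n_steady = int(self.steady_duration // self.cadence)
        n_induction = int(round(self.induction_duration / self.cadence))
        t = np.arange(n_induction + n_steady) * self.cadence
        phase = np.array(["induction"] * n_induction + ["steady"] * n_steady)
        return t, phase


@dataclass(frozen=True)
class StomatalModel:
    """First-order stomatal dynamics with a CO2-dependent target.

    The target opening declines linearly with ambient CO2 above
    400 umol mol-1 (clipped to [g_min, g_max]) and g_sw relaxes toward
    it with time constant ``tau`` — the simplest mechanism reproducing
    the observed closure of stomata as the ramp passes high CO2.
    ``g_cw_true`` is the cuticular share added on top of the stomatal
    conductance to form the leaf conductance.
    """

    g_max: float
    g_min: float
    co2_sensitivity: float = 0.0005  # fractional closure per umol mol-1 above 400
    tau: float = 180.0  # s
    g_cw_true: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (0.0 <= self.g_cw_true <= self.g_min + 1e-15):
            raise ValueError("require 0 <= g_cw_true <= g_min")
        if self.g_max < self.g_min:
            raise ValueError("g_max must be >= g_min")

    @classmethod
    def static(cls, g_sw: float, g_cw_true: float = 0.0) -> "StomatalModel":
        """Stomata frozen at ``g_sw`` (no CO2 response, instant tau)."""
        return cls(g_max=g_sw, g_min=g_sw, co2_sensitivity=0.0, tau=1e-6, g_cw_true=g_cw_true)

    @classmethod
    def redlight(cls, g_cw_true: float = 0.0056, g_steady: Optional[float] = None,
                 tau: float = 120.0) -> "StomatalModel":
        """Dark-adapted leaf opening slowly under low red light; the
        steady stomatal conductance stays of the same order as the
        cuticular conductance (stomata nearly closed)."""
        if g_steady is None:
            g_steady = max(0.006, 1.2 * g_cw_true)
        return cls(g_max=g_steady, g_min=max(g_cw_true, 1e-4),
                   co2_sensitivity=0.0, tau=tau, g_cw_true=g_cw_true)

    def target(self, ca: float) -> float:
        openness = min(1.0, max(0.0, 1.0 - self.co2_sensitivity * (ca - 400.0)))
        return self.g_min + (self.g_max - self.g_min) * openness

    def step(self, g_sw: float, ca: float, dt: float) -> float:
        """Exact exponential relaxation of g_sw toward the target over dt."""
        tgt = self.target(ca)
        return tgt + (g_sw - tgt) * np.exp(-dt / self.tau)


#: species-level presets from measured leaf means: g_max is the stomatal
#: share of the mean daylight g_lw, g_cw_true the mean cuticular
#: conductance (mol m-2 s-1)
SPECIES_PRESETS: dict[str, StomatalModel] = {
    "magnolia": StomatalModel(g_max=0.0847, g_min=0.02, co2_sensitivity=0.0006, tau=300.0, g_cw_true=0.0053),
    "citrus": StomatalModel(g_max=0.1155, g_min=0.02, co2_sensitivity=0.0008, tau=180.0, g_cw_true=0.0045),
    "pepper": StomatalModel(g_max=0.3224, g_min=0.05, co2_sensitivity=0.0005, tau=120.0, g_cw_true=0.0076),
    "papaya": StomatalModel(g_max=0.1644, g_min=0.03, co2_sensitivity=0.0004, tau=150.0, g_cw_true=0.0056),
}


@dataclass(frozen=True)
class EmptyChamberSpec:
    """Polynomial model of the empty chamber's apparent assimilation as
    a function of reference CO2 (the instrument-drift signal RACiR
    calibration removes).  ``coeffs`` are ascending-power coefficients,
    degree at most 5."""

    coeffs: Sequence[float]
    cref_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if len(self.coeffs) == 0 or len(self.coeffs) > 6:
            raise ValueError("polynomial degree must be between 0 and 5")

    def apparent_a(self, cref: np.ndarray | float) -> np.ndarray | float:
        return P.polyval(cref, np.asarray(self.coeffs, dtype=float))


def _require_seed(noise: NoiseSpec, seed: Optional[int]) -> np.random.Generator:
    if (noise.sd_glw > 0 or noise.sd_a > 0) and seed is None:
        raise ValueError("a seed is mandatory whenever noise is non-zero")
    return np.random.default_rng(seed)


def _instrument_ci(a: float, e: float, ca: float, glw_reported: float) -> float:
    """C_i as the instrument computes it: uncorrected pathway from the
    reported (possibly noisy) conductance."""
    if glw_reported <= 0:
        return np.nan
    g_tc = total_conductance_co2(glw_reported)
    return intercellular_co2(a, e, ca, g_tc)


def _leaf_truth(
    g_sw: float, g_cw: float, ca: float, chamber: ChamberState, params: FvCBParams
) -> tuple[float, float, float, float]:
    """(A, C_i, E, g_lw) of the modelled leaf with the true conductance
    partition."""
    g_lw = g_sw + g_cw
    state = ChamberState(ca=ca, e=0.0, vpd=chamber.vpd, patm=chamber.patm, t_leaf=chamber.t_leaf)
    mode = "corrected" if g_cw > 0 else "uncorrected"
    sol = coupled_solve(g_lw, g_cw, state, params, mode)
    return sol.a, sol.ci, sol.e, g_lw


def generate_curve(
    protocol: ProtocolSpec,
    params: FvCBParams | None = None,
    stomata: StomatalModel | None = None,
    noise: NoiseSpec | None = None,
    seed: Optional[int] = None,
    chamber: ChamberState | None = None,
    q_in: float = 1200.0,
    artifact: EmptyChamberSpec | None = None,
) -> pd.DataFrame:
    """Generate a logged gas-exchange run under the given protocol.

    The leaf truth is computed by the coupled solver with the true
    stomatal/cuticular partition; the reported columns add Gaussian
    conductance noise and recompute C_i the way the instrument does
    (uncorrected pathway from the reported g_lw).  An optional
    ``artifact`` adds an empty-chamber-style apparent-assimilation
    signal to the reported A, for calibration exercises.

    Identical (protocol, params, stomata, noise, seed) yield identical
    output.
    """
    params = params or FvCBParams()
    stomata = stomata or SPECIES_PRESETS["papaya"]
    noise = noise or NoiseSpec(sd_glw=0.0, sd_a=0.0)
    chamber = chamber or ChamberState()
    rng = _require_seed(noise, seed)

    if protocol.kind == "redlight":
        return generate_redlight_run(
            j_a=params.j, gamma_star=params.gamma_star, r_dark=params.rd,
            stomata=stomata, noise=noise, seed=seed, chamber=chamber, protocol=protocol,
        )
    if protocol.kind == "empty":
        raise ValueError("use generate_empty_chamber for empty-chamber protocols")
    if protocol.kind == "ss":
        waits = np.full(len(protocol.ss_setpoints), protocol.max_wait)
        elapsed = np.cumsum(waits)
        crefs = np.asarray(protocol.ss_setpoints, dtype=float)
        dts = waits
    elif protocol.kind == "racir":
        elapsed, crefs = protocol.ramp_timeline()
        dts = np.full(len(elapsed), protocol.log_interval)
    else:
        raise ValueError(f"unknown protocol kind {protocol.kind!r}")

    if max(crefs) <= params.gamma_star:
        warnings.warn(
            "entire protocol lies below the photo-compensation point; "
            "assimilation will be negative throughout",
            stacklevel=2,
        )

    g_sw = stomata.target(crefs[0])
    rows = []
    for t, ca, dt in zip(elapsed, crefs, dts):
        g_sw = stomata.step(g_sw, ca, dt)
        try:
            a_true, ci_true, e, g_lw_true = _leaf_truth(g_sw, stomata.g_cw_true, ca, chamber, params)
        except CoupledSolverError:
            rows.append((t, np.nan, np.nan, np.nan, ca, np.nan, ca,
                         chamber.t_leaf, chamber.vpd, chamber.patm, q_in,
                         np.nan, np.nan, np.nan))
            continue
        glw_rep = g_lw_true + (rng.normal(0.0, noise.sd_glw) if noise.sd_glw > 0 else 0.0)
        a_rep = a_true + (rng.normal(0.0, noise.sd_a) if noise.sd_a > 0 else 0.0)
        if artifact is not None:
            a_rep = a_rep + float(artifact.apparent_a(ca))
        ci_rep = _instrument_ci(a_rep, e, ca, glw_rep)
        rows.append((t, a_rep, e, glw_rep, ca, ci_rep, ca,
                     chamber.t_leaf, chamber.vpd, chamber.patm, q_in,
                     a_true, ci_true, g_lw_true))

    return pd.DataFrame(rows, columns=LI6800_COLUMNS + ["A_true", "Ci_true", "glw_true"])


def generate_empty_chamber(
    protocol: ProtocolSpec,
    spec: EmptyChamberSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: Optional[int] = None,
    chamber: ChamberState | None = None,
) -> pd.DataFrame:
    """Generate an empty-chamber run: no leaf, true conductance zero.

    Apparent A follows the drift polynomial plus optional noise; the
    reported conductance is pure Gaussian instrument noise around zero,
    which is precisely how the instrument's g_lw noise floor is
    estimated in practice.
    """
    if protocol.kind != "empty":
        raise ValueError(f"protocol kind must be 'empty', got {protocol.kind!r}")
    spec = spec or EmptyChamberSpec(coeffs=(0.0,))
    noise = noise or NoiseSpec(sd_glw=0.0, sd_a=0.0)
    chamber = chamber or ChamberState()
    rng = _require_seed(noise, seed)

    elapsed, crefs = protocol.ramp_timeline()
    n = len(elapsed)
    a = np.asarray(spec.apparent_a(crefs), dtype=float)
    if noise.sd_a > 0:
        a = a + rng.normal(0.0, noise.sd_a, size=n)
    gsw = rng.normal(0.0, noise.sd_glw, size=n) if noise.sd_glw > 0 else np.zeros(n)
    ci = np.array([_instrument_ci(ai, 0.0, c, g) for ai, c, g in zip(a, crefs, gsw)])
    return pd.DataFrame({
        "elapsed": elapsed, "A": a, "E": np.zeros(n), "gsw": gsw, "Ca": crefs,
        "Ci": ci, "CO2_r": crefs, "Tleaf": np.full(n, chamber.t_leaf),
        "VPDleaf": np.full(n, chamber.vpd), "Patm": np.full(n, chamber.patm),
        "Qin": np.full(n, 1200.0),
    })


def generate_redlight_run(
    j_a: float = 60.0,
    gamma_star: float = 42.75,
    r_dark: float = 1.0,
    stomata: StomatalModel | None = None,
    noise: NoiseSpec | None = None,
    seed: Optional[int] = None,
    chamber: ChamberState | None = None,
    protocol: ProtocolSpec | None = None,
) -> pd.DataFrame:
    """Generate a red-light induction run for g_cw estimation.

    Under ~100 umol m-2 s-1 red light the leaf is electron-transport
    limited, so assimilation follows the RuBP-limited rate alone with a
    low operating J (``j_a``); the boundary layer is treated as
    non-limiting at these tiny conductances (g_lw ~ 0.01 << g_bw).
    Records carry a ``phase`` column; the steady window is the final
    42 records at the default 7-s cadence / 300-s window.
    """
    stomata = stomata or StomatalModel.redlight()
    noise = noise or NoiseSpec(sd_glw=0.0, sd_a=0.0)
    chamber = chamber or ChamberState()
    protocol = protocol or ProtocolSpec.redlight()
    rng = _require_seed(noise, seed)
    elapsed, phase = protocol.redlight_timeline()

    def net_a(ci: float) -> float:
        return rubp_limited_rate(ci, FvCBParams(j=j_a, gamma_star=gamma_star, rd=0.0)) - r_dark

    g_sw = stomata.g_min
    rows = []
    for t, ph in zip(elapsed, phase):
        g_sw = stomata.step(g_sw, chamber.ca, protocol.cadence)
        g_cw = stomata.g_cw_true
        g_lw = g_sw + g_cw
        g_lc = g_sw / 1.6 + g_cw / 20.0  # boundary layer non-limiting
        e = g_lw * chamber.vpd / chamber.patm

        def f(ci: float) -> float:
            return intercellular_co2(net_a(ci), e, chamber.ca, g_lc) - ci

        ci_true = brentq(f, gamma_star * 1e-3, chamber.ca, xtol=1e-12)
        a_true = net_a(ci_true)
        glw_rep = g_lw + (rng.normal(0.0, noise.sd_glw) if noise.sd_glw > 0 else 0.0)
        a_rep = a_true + (rng.normal(0.0, noise.sd_a) if noise.sd_a > 0 else 0.0)
        ci_rep = _instrument_ci(a_rep, e, chamber.ca, glw_rep)
        rows.append((t, a_rep, e, glw_rep, chamber.ca, ci_rep, chamber.ca,
                     chamber.t_leaf, chamber.vpd, chamber.patm, 100.0,
                     a_true, ci_true, g_lw, ph))

    return pd.DataFrame(
        rows, columns=LI6800_COLUMNS + ["A_true", "Ci_true", "glw_true", "phase"]
    )


def generate_redlight_companion(
    j_a: float = 60.0,
    gamma_star: float = 42.75,
    r_dark: float = 1.0,
    ci_min: float = 50.0,
    ci_max: float = 1200.0,
    n: int = 200,
    noise_sd_a: float = 0.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Idealised companion A/C_i curve for fitting (J_a, gamma_star):
    the RuBP-limited response sampled over a C_i span bracketing the
    compensation point."""
    if noise_sd_a > 0 and seed is None:
        raise ValueError("a seed is mandatory whenever noise is non-zero")
    rng = np.random.default_rng(seed)
    ci = np.linspace(ci_min, ci_max, n)
    p = FvCBParams(j=j_a, gamma_star=gamma_star, rd=0.0)
    a = np.array([rubp_limited_rate(c, p) for c in ci]) - r_dark
    if noise_sd_a > 0:
        a = a + rng.normal(0.0, noise_sd_a, size=n)
    return pd.DataFrame({"Ci": ci, "A": a})


def read_li6800_csv(path) -> pd.DataFrame:
    """Read a gas-exchange CSV, validating the mandatory columns.

    ``glw`` is accepted as an alias for ``gsw`` (renamed on read).
    Unknown columns are preserved untouched.
    """
    df = pd.read_csv(path)
    if "gsw" not in df.columns and "glw" in df.columns:
        df = df.rename(columns={"glw": "gsw"})
    for col in _MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    return df


def write_li6800_csv(records: pd.DataFrame, path) -> None:
    """Write records to CSV (single header row, comma separated).

    Floats are written with shortest round-trip representation, so
    write-then-read is lossless.
    """
    for col in _MANDATORY:
        if col not in records.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    records.to_csv(path, index=False)
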