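"""C_i misestimation analyses: conductance sweeps, instrument-noise
bands, and the combined-error envelope.

The central question: over what range of leaf conductance does the
instrument's uncorrected C_i meaningfully overestimate the true value?
Framing the answer against the ratio g_cw : g_lw (rather than g_lw
alone) aligns species with very different absolute conductances onto a
common risk scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .conductance import ChamberState, ci_misestimation
from .fvcb import CoupledSolverError, FvCBParams, Mode, coupled_solve

__all__ = [
    "NoiseSpec",
    "NoiseBand",
    "MisestimationProfile",
    "default_glw_grid",
    "DEFAULT_CA_SCENARIOS",
    "sweep_glw",
    "threshold_ratio",
    "noise_band",
    "combined_max_error",
    "sweep_noise",
    "noise_threshold_ratio",
]

#: ambient-CO2 scenarios of the standard sweep, umol mol-1
DEFAULT_CA_SCENARIOS = (100.0, 400.0, 2000.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Instrument noise model.

    ``sd_glw`` is the standard deviation of the reported leaf
    conductance to water, mol m-2 s-1; the default is the empirically
    determined empty-chamber value of an LI-6800-class analyzer.
    ``sd_a`` optionally adds Gaussian noise to reported assimilation.
    """

    sd_glw: float = 0.00415
    sd_a: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_glw < 0 or self.sd_a < 0:
            raise ValueError("noise standard deviations must be non-negative")


@dataclass(frozen=True)
class NoiseBand:
    """C_i evaluated at g_lw - sd, g_lw, g_lw + sd, and the resulting
    worst-case proportional error; ``one_sided`` marks bands whose lower
    perturbation was non-physical and had to be dropped."""

    ci_low: float
    ci_mid: float
    ci_high: float
    proportional_error: float
    one_sided: bool = False


@dataclass
class MisestimationProfile:
    """Gridded corrected/uncorrected C_i against g_lw.

    ``data`` holds one row per (g_lw, C_a) pair with columns
    ``g_lw, ratio, ca, ci_uncorr, ci_cor, ci_mis, flag``; rows are
    ordered by C_a then g_lw.  Flags: "" (clean), "non_physical"
    (g_lw <= g_cw, corrected pathway undefined), "solver_failure",
    "negative_ci" (uncorrected C_i below zero, the unreliable
    low-conductance regime).
    """

    data: pd.DataFrame
    g_cw: float
    params: FvCBParams
    vpd: float
    meta: dict = field(default_factory=dict)

    def for_ca(self, ca: float) -> pd.DataFrame:
        return self.data[self.data["ca"] == ca]


def default_glw_grid() -> np.ndarray:
    """g_lw from 0.001 to 1 mol m-2 s-1 in 0.001 steps (1000 points)."""
    return np.round(np.arange(1, 1001) * 0.001, 9)


def sweep_glw(
    glw_grid: Optional[Sequence[float]] = None,
    g_cw: float = 0.0056,
    ca_values: Sequence[float] = DEFAULT_CA_SCENARIOS,
    params: FvCBParams | None = None,
    chamber: ChamberState | None = None,
) -> MisestimationProfile:
    """Sweep g_lw and compute corrected and uncorrected C_i at each point.

    Grid rows where the corrected pathway is undefined (g_lw <= g_cw)
    are kept and flagged rather than dropped, so the profile always
    spans the full requested grid.
    """
    if params is None:
        params = FvCBParams()
    template = chamber if chamber is not None else ChamberState()
    grid = default_glw_grid() if glw_grid is None else np.asarray(glw_grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("glw_grid must be strictly positive and strictly increasing")

    rows = []
    for ca in ca_values:
        chamber_ca = ChamberState(
            ca=ca, e=template.e, vpd=template.vpd, patm=template.patm, t_leaf=template.t_leaf
        )
        for g_lw in grid:
            flag = ""
            ci_u = ci_c = mis = np.nan
            try:
                ci_u = coupled_solve(g_lw, g_cw, chamber_ca, params, "uncorrected").ci
                if g_lw <= g_cw:
                    flag = "non_physical"
                else:
                    ci_c = coupled_solve(g_lw, g_cw, chamber_ca, params, "corrected").ci
                    mis = ci_misestimation(ci_u, ci_c)
            except CoupledSolverError:
                flag = "solver_failure"
            if flag == "" and ci_u < 0:
                flag = "negative_ci"
            rows.append((g_lw, g_cw / g_lw, ca, ci_u, ci_c, mis, flag))

    data = pd.DataFrame(
        rows, columns=["g_lw", "ratio", "ca", "ci_uncorr", "ci_cor", "ci_mis", "flag"]
    )
    return MisestimationProfile(data=data, g_cw=g_cw, params=params, vpd=template.vpd)


def _first_crossing_ratio(
    ratio: np.ndarray, values: np.ndarray, threshold: float
) -> Optional[float]:
    """Ratio at the first upward crossing of ``values`` above
    ``threshold``, scanning in order of increasing ratio, with linear
    interpolation between the bracketing rows."""
    order = np.argsort(ratio)
    r, v = ratio[order], values[order]
    keep = np.isfinite(v)
    r, v = r[keep], v[keep]
    if len(r) == 0:
        return None
    if v[0] > threshold:
        return float(r[0])
    above = np.nonzero(v > threshold)[0]
    if len(above) == 0:
        return None
    i = above[0]
    # warn if the profile dips back under the threshold later on
    if np.any(v[i:] <= threshold):
        warnings.warn(
            "misestimation profile is non-monotone near the crossing; "
            "reporting the first crossing",
            stacklevel=3,
        )
    r0, r1, v0, v1 = r[i - 1], r[i], v[i - 1], v[i]
    if v1 == v0:
        return float(r1)
    return float(r0 + (threshold - v0) * (r1 - r0) / (v1 - v0))


def threshold_ratio(
    profile: MisestimationProfile, threshold: float = 0.05, ca: Optional[float] = None
) -> Optional[float]:
    """g_cw : g_lw ratio at which C_i misestimation first exceeds
    ``threshold``; ``None`` if the profile never crosses.

    A threshold of 0 with g_cw > 0 returns the smallest grid ratio
    (crossing is immediate).  The ratio framing makes the answer
    invariant to jointly rescaling g_cw and the grid.
    """
    data = profile.data if ca is None else profile.for_ca(ca)
    clean = data[data["flag"] == ""]
    if len(clean) == 0:
        return None
    return _first_crossing_ratio(
        clean["ratio"].to_numpy(), clean["ci_mis"].to_numpy(), threshold
    )


def noise_band(
    g_lw: float,
    g_cw: float = 0.0,
    noise: NoiseSpec | None = None,
    chamber: ChamberState | None = None,
    params: FvCBParams | None = None,
    mode: Mode = "corrected",
) -> NoiseBand:
    """C_i uncertainty band from a deterministic +/- 1 sd perturbation
    of g_lw (the instrument's reported conductance).

    The proportional error is the larger of the two deviations from the
    unperturbed C_i, relative to the unperturbed C_i.  If the lower
    perturbation is non-physical (g_lw - sd <= g_cw in corrected mode,
    or <= 0), a one-sided band is returned with a flag.
    """
    noise = noise or NoiseSpec()
    sd = noise.sd_glw
    mid = coupled_solve(g_lw, g_cw, chamber, params, mode).ci
    hi = coupled_solve(g_lw + sd, g_cw, chamber, params, mode).ci if sd > 0 else mid
    lower_glw = g_lw - sd
    lower_ok = lower_glw > (g_cw if mode == "corrected" else 0.0)
    lo = coupled_solve(lower_glw, g_cw, chamber, params, mode).ci if (sd > 0 and lower_ok) else mid
    deviations = [abs(hi - mid)]
    if sd > 0 and lower_ok:
        deviations.append(abs(lo - mid))
    err = max(deviations) / mid
    return NoiseBand(
        ci_low=lo if lower_ok else np.nan,
        ci_mid=mid,
        ci_high=hi,
        proportional_error=err,
        one_sided=sd > 0 and not lower_ok,
    )


def combined_max_error(
    g_lw: float,
    g_cw: float,
    noise: NoiseSpec | None = None,
    chamber: ChamberState | None = None,
    params: FvCBParams | None = None,
) -> float:
    """Worst-case proportional C_i error from instrument noise *and*
    ignoring the cuticle together.

    The uncorrected C_i is evaluated at g_lw - sd, g_lw, g_lw + sd and
    the maximum deviation from the unperturbed *corrected* C_i is
    reported as a proportion of the corrected value.  Dominates both
    the pure-correction and pure-noise errors.
    """
    noise = noise or NoiseSpec()
    sd = noise.sd_glw
    ci_cor = coupled_solve(g_lw, g_cw, chamber, params, "corrected").ci
    worst = 0.0
    for delta in (-sd, 0.0, sd):
        glw_p = g_lw + delta
        if glw_p <= 0:
            continue
        ci_u = coupled_solve(glw_p, g_cw, chamber, params, "uncorrected").ci
        worst = max(worst, abs(ci_u - ci_cor))
    return worst / ci_cor


def sweep_noise(
    glw_grid: Optional[Sequence[float]] = None,
    g_cw: float = 0.0056,
    noise: NoiseSpec | None = None,
    ca: float = 400.0,
    params: FvCBParams | None = None,
    chamber: ChamberState | None = None,
    mode: Mode = "corrected",
) -> pd.DataFrame:
    """Noise-band proportional error across the g_lw grid at one C_a.

    Rows where even the unperturbed point is non-physical are flagged
    and carry NaN; one-sided bands are flagged but still carry their
    (upper-only) error.
    """
    noise = noise or NoiseSpec()
    template = chamber if chamber is not None else ChamberState()
    chamber_ca = ChamberState(
        ca=ca, e=template.e, vpd=template.vpd, patm=template.patm, t_leaf=template.t_leaf
    )
    grid = default_glw_grid() if glw_grid is None else np.asarray(glw_grid, dtype=float)
    rows = []
    for g_lw in grid:
        flag = ""
        err = np.nan
        if mode == "corrected" and g_lw <= g_cw:
            flag = "non_physical"
        else:
            try:
                band = noise_band(g_lw, g_cw, noise, chamber_ca, params, mode)
                err = band.proportional_error
                if band.one_sided:
                    flag = "one_sided"
            except CoupledSolverError:
                flag = "solver_failure"
        rows.append((g_lw, g_cw / g_lw, ca, err, flag))
    return pd.DataFrame(rows, columns=["g_lw", "ratio", "ca", "prop_error", "flag"])


def noise_threshold_ratio(
    sweep: pd.DataFrame, threshold: float = 0.05, two_sided_only: bool = True
) -> Optional[float]:
    """g_cw : g_lw ratio at which the noise-band proportional error
    first exceeds ``threshold`` (linear interpolation, as for the
    misestimation threshold)."""
    ok_flags = ("",) if two_sided_only else ("", "one_sided")
    clean = sweep[sweep["flag"].isin(ok_flags)]
    if len(clean) == 0:
        return None
    return _first_crossing_ratio(
        clean["ratio"].to_numpy(), clean["prop_error"].to_numpy(), threshold
    )
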