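"""Empty-chamber calibration of constant-ramp (RACiR) curves.

During a CO2 ramp the two analyzer cells are never perfectly matched,
so even an empty chamber reports a non-zero "assimilation" that varies
smoothly with reference CO2.  The calibration fits a low-order
polynomial to an empty-chamber ramp and subtracts it from the leaf
ramp taken under the same conditions, then recomputes C_i from the
corrected assimilation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P

from .conductance import intercellular_co2, total_conductance_co2

__all__ = [
    "CalibrationError",
    "EmptyChamberModel",
    "select_calibration_range",
    "fit_empty_model",
    "apply_correction",
]


class CalibrationError(ValueError):
    """Range selection or polynomial fitting failed."""


@dataclass(frozen=True)
class EmptyChamberModel:
    """Fitted polynomial of apparent A on reference CO2.

    ``coeffs`` are ascending-power coefficients; ``cref_range`` is the
    span of reference CO2 the model was fitted on — predictions outside
    it are extrapolations and are flagged by :func:`apply_correction`.
    """

    coeffs: tuple[float, ...]
    degree: int
    cref_range: tuple[float, float]
    rmse: float
    n: int

    def predict(self, cref):
        return P.polyval(np.asarray(cref, dtype=float), np.asarray(self.coeffs))


def select_calibration_range(
    empty: pd.DataFrame, lower: float, upper: float
) -> pd.DataFrame:
    """Trim an empty-chamber run to reference CO2 within [lower, upper].

    Ramp endpoints dwell at constant CO2 and the analyzer needs settling
    time, so the extremes of the ramp are routinely discarded before
    fitting.  The number of removed rows is reported in
    ``result.attrs["n_removed"]``.
    """
    if lower >= upper:
        raise CalibrationError(f"lower={lower} must be below upper={upper}")
    cref = empty["CO2_r"]
    keep = (cref >= lower) & (cref <= upper)
    trimmed = empty[keep].copy()
    if len(trimmed) == 0:
        raise CalibrationError(
            f"no rows with CO2_r in [{lower}, {upper}] "
            f"(data span [{cref.min()}, {cref.max()}])"
        )
    trimmed.attrs["n_removed"] = int((~keep).sum())
    return trimmed


def fit_empty_model(trimmed: pd.DataFrame, max_degree: int = 5) -> EmptyChamberModel:
    """Least-squares polynomial of apparent A on reference CO2, degree
    chosen among 1..max_degree by BIC.

    The information criterion makes the degree choice deterministic
    where visual inspection is the traditional practice.
    """
    x = trimmed["CO2_r"].to_numpy(dtype=float)
    y = trimmed["A"].to_numpy(dtype=float)
    n = len(x)
    if n < max_degree and n < 3:
        raise CalibrationError(f"need at least 3 rows to fit, got {n}")
    best = None
    for degree in range(1, max_degree + 1):
        if n < degree + 2:
            break
        try:
            coeffs = P.polyfit(x, y, degree)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rank issues
            raise CalibrationError(f"rank-deficient fit at degree {degree}: {exc}")
        resid = y - P.polyval(x, coeffs)
        rss = float(np.sum(resid**2))
        # guard the log for exact fits
        bic = n * np.log(max(rss / n, 1e-300)) + (degree + 1) * np.log(n)
        if best is None or bic < best[0]:
            best = (bic, degree, coeffs, rss)
    if best is None:
        raise CalibrationError(f"too few rows ({n}) for any degree up to {max_degree}")
    _, degree, coeffs, rss = best
    return EmptyChamberModel(
        coeffs=tuple(float(c) for c in coeffs),
        degree=degree,
        cref_range=(float(x.min()), float(x.max())),
        rmse=float(np.sqrt(rss / n)),
        n=n,
    )


def apply_correction(leaf: pd.DataFrame, model: EmptyChamberModel) -> pd.DataFrame:
    """Subtract the empty-chamber signal from a leaf run and recompute C_i.

    ``A`` becomes the calibrated assimilation (the raw value is kept in
    ``A_raw``); C_i is recomputed from the calibrated A through the
    uncorrected conductance pathway, matching what the instrument would
    have reported had it not drifted — the cuticular correction is a
    separate, later step and stays orthogonal to this one.  Rows whose
    reference CO2 falls outside the model's fitted range are flagged
    ``out_of_calibration_range`` (and should be excluded from fitting)
    but are not dropped.
    """
    out = leaf.copy()
    cref = out["CO2_r"].to_numpy(dtype=float)
    lo, hi = model.cref_range
    in_range = (cref >= lo) & (cref <= hi)
    out["A_raw"] = out["A"]
    out["Ci_raw"] = out["Ci"]
    out["A"] = out["A_raw"] - model.predict(cref)
    ci = np.full(len(out), np.nan)
    for i, (a, e, ca, glw) in enumerate(
        zip(out["A"], out["E"], out["Ca"], out["gsw"])
    ):
        if glw > 0:
            ci[i] = intercellular_co2(a, e, ca, total_conductance_co2(glw))
    out["Ci"] = ci
    flag = out["flag"].astype(str) if "flag" in out.columns else pd.Series([""] * len(out), index=out.index)
    flag = flag.where(in_range, "out_of_calibration_range")
    out["flag"] = flag
    return out
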