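"""Cytotoxicity normalisation and four-parameter logistic EC50 fitting.

Raw well fluorescence is normalised to percent of the untreated (vehicle)
controls, then a four-parameter logistic

    y = bottom + (top - bottom) / (1 + 10^((logEC50 - log10 dose) * hill))

is least-squares fitted to the normalised data over log10 dose. Vehicle
wells (dose 0) define the 100% anchor but are excluded from the regression,
since log of zero is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["FourPLFit", "normalize_viability", "fit_4pl", "fit_plate", "ec50_table"]


@dataclass(frozen=True)
class FourPLFit:
    """Fitted 4PL parameters. `ec50` is NaN when the fit is flagged.

    `se_log_ec50` is the standard error of log10 EC50 from the fit
    covariance; `se_ec50_multiplicative` is its back-transform
    10**se_log_ec50, the factor form in which plate-fitting software usually
    prints "EC50 ± se".
    """

    log_ec50: float
    ec50: float
    hill: float
    top: float
    bottom: float
    se_log_ec50: float
    converged: bool
    residual_sd: float

    @property
    def se_ec50_multiplicative(self) -> float:
        return float(10.0**self.se_log_ec50)


def _flagged(reason_top: float = np.nan) -> FourPLFit:
    return FourPLFit(
        log_ec50=np.nan, ec50=np.nan, hill=np.nan, top=reason_top, bottom=np.nan,
        se_log_ec50=np.nan, converged=False, residual_sd=np.nan,
    )


def normalize_viability(table: pd.DataFrame) -> pd.DataFrame:
    """Express signals as percent of the mean vehicle signal, per compound.

    Expects columns (compound, dose, replicate, signal, is_vehicle); adds a
    `viability` column in percent.
    """
    required = {"compound", "dose", "signal", "is_vehicle"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns {sorted(missing)}")
    out = []
    for compound, sub in table.groupby("compound", sort=False):
        vehicle = sub.loc[sub["is_vehicle"], "signal"]
        if vehicle.empty or vehicle.mean() <= 0:
            raise ValueError(f"compound {compound!r} has no usable vehicle wells")
        sub = sub.copy()
        sub["viability"] = 100.0 * sub["signal"] / vehicle.mean()
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def _model(log_dose, log_ec50, hill, top, bottom):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - log_dose) * hill))


def fit_4pl(
    doses: np.ndarray,
    viability: np.ndarray,
    noise_floor: float = 1e-6,
    bounded: bool = False,
) -> FourPLFit:
    """Least-squares 4PL fit of percent viability against log10 dose.

    Initialisation: top = max y, bottom = min y, log EC50 at the dose whose
    response is nearest the midpoint, |hill| = 1 with sign from the response
    trend. A response range below `noise_floor` (flat curve) or a failed
    optimisation yields a flagged, non-converged fit with EC50 = NaN. With
    `bounded=True` the bottom is constrained to be nonnegative.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    keep = doses > 0
    doses, viability = doses[keep], viability[keep]
    if len(np.unique(doses)) < 4:
        raise ValueError("need >= 4 distinct positive doses")
    if not np.all(np.isfinite(viability)):
        raise ValueError("responses must be finite")
    if np.ptp(viability) < noise_floor:
        return _flagged()

    log_dose = np.log10(doses)
    top0, bottom0 = float(viability.max()), float(viability.min())
    midpoint = (top0 + bottom0) / 2.0
    log_ec50_0 = float(log_dose[np.argmin(np.abs(viability - midpoint))])
    trend = np.polyfit(log_dose, viability, 1)[0]
    hill0 = 1.0 if trend > 0 else -1.0
    p0 = (log_ec50_0, hill0, top0, bottom0)
    if bounded:
        bounds = ([-np.inf, -np.inf, -np.inf, 0.0], [np.inf] * 4)
    else:
        bounds = (-np.inf, np.inf)
    try:
        popt, pcov = curve_fit(
            _model, log_dose, viability, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError):
        return _flagged()
    log_ec50, hill, top, bottom = (float(v) for v in popt)
    resid = viability - _model(log_dose, *popt)
    dof = max(len(viability) - 4, 1)
    residual_sd = float(np.sqrt((resid**2).sum() / dof))
    se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.nan
    if top <= bottom:
        # mirror-symmetric parameterisation: normalise so top > bottom
        top, bottom, hill = bottom, top, -hill
    return FourPLFit(
        log_ec50=log_ec50, ec50=float(10.0**log_ec50), hill=hill, top=top,
        bottom=bottom, se_log_ec50=se, converged=True, residual_sd=residual_sd,
    )


def fit_plate(table: pd.DataFrame, **kwargs) -> dict[str, FourPLFit]:
    """Normalise a raw plate table and fit one 4PL per compound."""
    norm = normalize_viability(table)
    fits = {}
    for compound, sub in norm.groupby("compound", sort=False):
        treated = sub.loc[~sub["is_vehicle"]]
        fits[str(compound)] = fit_4pl(
            treated["dose"].to_numpy(), treated["viability"].to_numpy(), **kwargs
        )
    return fits


def ec50_table(fits: dict[str, dict[str, FourPLFit]]) -> pd.DataFrame:
    """Wide compound x cell-line summary of EC50s.

    `fits` maps line -> (compound -> FourPLFit). Cells report
    "ec50 ± multiplicative se" semantics via two stacked columns per line;
    flagged fits render as missing (NaN), never as zero.
    """
    compounds = sorted({c for per_line in fits.values() for c in per_line})
    records = []
    for compound in compounds:
        row_val = {"compound": compound, "quantity": "ec50"}
        row_se = {"compound": compound, "quantity": "se_multiplicative"}
        for line, per_line in fits.items():
            fit = per_line.get(compound)
            ok = fit is not None and fit.converged
            row_val[line] = fit.ec50 if ok else np.nan
            row_se[line] = fit.se_ec50_multiplicative if ok else np.nan
        records.extend([row_val, row_se])
    return pd.DataFrame(records)
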