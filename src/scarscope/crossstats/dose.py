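"""Four-parameter log-logistic dose-response fitting and IC50 fold changes.

The model is ``response(d) = bottom + (top - bottom) / (1 + (d/ic50)^hill)``,
a decreasing curve for hill > 0 whose midpoint concentration is the IC50.
The fit is performed on log-dose residuals centered at the mean log dose, so
rescaling all doses by a constant rescales the fitted IC50 exactly (the
optimizer sees an identical numerical problem).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["DoseResponseFit", "four_pl", "fit_dose_response"]


@dataclass(frozen=True)
class DoseResponseFit:
    top: float
    bottom: float
    hill: float
    ic50: float
    fold_change_vs_reference: float | None = None

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be > 0")
        if self.bottom > self.top:
            raise ValueError("bottom must be <= top")

    def response(self, dose: float | np.ndarray) -> np.ndarray:
        return four_pl(dose, self.top, self.bottom, self.hill, self.ic50)


def four_pl(dose, top: float, bottom: float, hill: float, ic50: float):
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def _model(theta: np.ndarray, logd_centered: np.ndarray, is_zero: np.ndarray) -> np.ndarray:
    top, bottom, hill, u = theta  # u = log(ic50) - mean(log positive doses)
    ratio = np.where(is_zero, 0.0, np.exp(hill * (logd_centered - u)))
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_dose_response(
    doses,
    responses,
    reference_fit: DoseResponseFit | None = None,
    *,
    normalize_to_vehicle: bool = True,
) -> DoseResponseFit:
    """Least-squares 4PL fit of colony counts against dose.

    Responses are first normalized to the mean vehicle (dose == 0) response
    when present. Requires >= 4 distinct doses. With ``reference_fit`` given,
    ``fold_change_vs_reference = ic50 / reference.ic50``.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have equal length")
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    if np.any(responses < 0):
        raise ValueError("responses must be >= 0")
    if np.unique(doses).size < 4:
        raise ValueError("need at least 4 distinct doses")

    if normalize_to_vehicle and np.any(doses == 0):
        vehicle = responses[doses == 0].mean()
        if vehicle <= 0:
            raise ValueError("vehicle responses are all zero: cannot normalize")
        responses = responses / vehicle

    pos = doses > 0
    if pos.sum() < 3:
        raise ValueError("need at least 3 positive doses")

    # identifiability check: per-dose means must span a real response range
    dose_means = {d: responses[doses == d].mean() for d in np.unique(doses)}
    means = np.array(list(dose_means.values()))
    span = means.max() - means.min()
    if span < 1e-3 * max(means.max(), 1e-12):
        raise ValueError("responses are flat across doses: ic50 unidentifiable")

    c0 = np.mean(np.log(doses[pos]))
    logd_centered = np.where(pos, np.log(np.where(pos, doses, 1.0)) - c0, 0.0)
    is_zero = ~pos

    rmax = float(responses.max())
    # initialize from data quartiles; u0 from the dose nearest the half response
    top0 = float(np.quantile(means, 0.9))
    bottom0 = float(np.quantile(means, 0.1))
    half = (top0 + bottom0) / 2.0
    pos_doses = np.array(sorted(d for d in dose_means if d > 0))
    pos_means = np.array([dose_means[d] for d in pos_doses])
    nearest = pos_doses[int(np.argmin(np.abs(pos_means - half)))]
    u0 = float(np.log(nearest) - c0)
    theta0 = np.array([top0, bottom0, 1.0, u0])

    lo = np.array([0.0, 0.0, 1e-3, np.log(pos_doses.min()) - c0 - np.log(1e3)])
    hi = np.array([1.2 * rmax, 1.2 * rmax, 50.0, np.log(pos_doses.max()) - c0 + np.log(1e3)])
    theta0 = np.clip(theta0, lo, hi)

    result = least_squares(
        lambda th: _model(th, logd_centered, is_zero) - responses,
        theta0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not result.success:
        raise RuntimeError(f"4PL fit did not converge: {result.message}")

    top, bottom, hill, u = result.x
    if bottom > top:
        # decreasing-curve convention: swap orientation by flipping hill sign
        top, bottom, hill = bottom, top, -hill
    ic50 = float(np.exp(u + c0))
    fold = None if reference_fit is None else ic50 / reference_fit.ic50
    return DoseResponseFit(
        top=float(top), bottom=float(bottom), hill=float(hill), ic50=ic50,
        fold_change_vs_reference=fold,
    )
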