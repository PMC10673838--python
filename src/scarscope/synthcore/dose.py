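"""Dose-colony tables from a 4PL truth curve with lognormal noise."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._rng import substream
from ..crossstats.dose import DoseResponseFit

__all__ = ["gen_dose_response"]


def gen_dose_response(
    fit: DoseResponseFit,
    doses,
    cv_noise: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Responses follow the truth curve with multiplicative lognormal noise of
    coefficient of variation ``cv_noise``. Returns a long table with columns
    dose, replicate, response.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0 (0 = vehicle)")
    if cv_noise < 0:
        raise ValueError("cv_noise must be >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    rng = substream(seed, "dose_response")
    rows = []
    # lognormal with unit mean and sd = cv: sigma^2 = ln(1 + cv^2)
    sigma = np.sqrt(np.log1p(cv_noise**2)) if cv_noise > 0 else 0.0
    mu = -(sigma**2) / 2.0
    for rep in range(1, n_reps + 1):
        mean_resp = fit.response(doses)
        noise = rng.lognormal(mu, sigma, size=doses.size) if sigma > 0 else 1.0
        resp = mean_resp * noise
        for d, r in zip(doses, np.atleast_1d(resp)):
            rows.append({"dose": float(d), "replicate": rep, "response": float(r)})
    return pd.DataFrame(rows, columns=["dose", "replicate", "response"])
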