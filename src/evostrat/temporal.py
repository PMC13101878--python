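"""Ancient-DNA score trajectories and archaic-vs-modern comparisons.

The *selection trajectory* of a partitioned polygenic score is operationalized
as the least-squares slope of the z-standardized score on time measured in
units of 10,000 years toward the present (so a positive coefficient means the
score has been increasing over time), with heteroskedasticity-robust standard
errors.  The unit (per 10 ka, standardized-score scale) is explicit in the
result; no claim is made that this matches any particular ancient-DNA
selection estimator.

Archaic samples are placed on the modern reference scale as
``z_i = (score_i - mean_modern) / sd_modern``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["TrajectoryResult", "selection_trajectory", "archaic_zscores"]


@dataclass
class TrajectoryResult:
    """Standardized-score slope per 10 ka toward the present."""

    s: float
    se: float
    p: float
    n: int
    unit: str = "sd_per_10ka_toward_present"


def selection_trajectory(
    scores: Sequence[float],
    ages_years_bp: Sequence[float],
    covariates: pd.DataFrame | None = None,
) -> TrajectoryResult:
    """Slope of a standardized score over sample age.

    ``ages_years_bp`` are years before present (larger = older).  Internally
    the time axis is ``-age / 10000`` so the reported coefficient is per
    10,000 years *toward the present*.  Covariates (e.g. genotype coverage)
    are optional.  Standard errors are HC1 robust.
    """
    import statsmodels.api as sm

    y = np.asarray(scores, dtype=float)
    ages = np.asarray(ages_years_bp, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 samples")
    if len(ages) != n:
        raise ValueError("scores and ages have different lengths")
    if np.ptp(ages) == 0:
        raise ValueError("all sample ages are equal; trajectory undefined")
    if y.std() == 0:
        # a constant score has exactly zero trend
        return TrajectoryResult(s=0.0, se=0.0, p=1.0, n=n)
    y = (y - y.mean()) / y.std()
    X = pd.DataFrame({"time_10ka": -ages / 10_000.0})
    if covariates is not None:
        for c in covariates.columns:
            X[c] = np.asarray(covariates[c], dtype=float)
    X.insert(0, "const", 1.0)
    fit = sm.OLS(y, X).fit(cov_type="HC1")
    return TrajectoryResult(
        s=float(fit.params["time_10ka"]),
        se=float(fit.bse["time_10ka"]),
        p=float(fit.pvalues["time_10ka"]),
        n=n,
    )


def archaic_zscores(
    archaic_scores: Sequence[float], modern_reference_scores: Sequence[float]
) -> tuple[np.ndarray, float, float]:
    """Archaic sample scores on the modern reference z-scale.

    Returns ``(z_per_sample, mean_z, median_z)``.  Requires a modern
    reference of at least 30 individuals with nonzero score variance.
    """
    arch = np.asarray(archaic_scores, dtype=float)
    modern = np.asarray(modern_reference_scores, dtype=float)
    if len(modern) < 30:
        raise ValueError("modern reference must have n >= 30")
    sd = modern.std(ddof=1)
    if sd == 0:
        raise ValueError("modern reference scores have zero variance")
    z = (arch - modern.mean()) / sd
    return z, float(z.mean()), float(np.median(z))
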