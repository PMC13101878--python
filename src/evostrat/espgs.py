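"""The evolutionary stratified polygenic score (ES-PGS) association model.

The model jointly regresses a phenotype on three standardized polygenic-score
terms — the genome-wide *background* score, a *matched-control* score built
from regions that replicate the annotation's genomic covariates, and the
*annotation* score itself — plus caller-supplied covariates.  The annotation
coefficient is the headline estimate: a positive beta means variants inside
the evolutionary annotation predict the phenotype beyond both the rest of
the genome and control regions of the same genomic character.

The nested model-improvement test compares the full model against the
reduced model without the annotation term (partial F-test for the linear
family, likelihood-ratio chi-squared for the logistic family).  Delta R^2 is
the corresponding gain in explained variance (Nagelkerke pseudo-R^2 for
binary phenotypes, stated in the result metadata).

The per-SNP predictive-power ratio compares the annotation's variance
explained per contributing SNP against a reference partition:
``rho = (delta_r2_annot / n_annot) / (r2_ref / n_ref)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ESPGSResult",
    "CollinearityError",
    "fit_espgs",
    "model_improvement_test",
    "per_snp_power_ratio",
    "bh_fdr",
]

SCORE_TERMS = ("background", "matched", "annotation")


class CollinearityError(ValueError):
    """Raised when score terms are perfectly collinear (names the terms)."""


@dataclass
class ESPGSResult:
    """Fitted ES-PGS model summary."""

    terms: pd.DataFrame  # term, beta, se, ci_lo, ci_hi, p
    r2_reduced: float
    r2_full: float
    delta_r2: float
    model_improvement_p: float
    n: int
    family: str
    r2_kind: str  # "ols" or "nagelkerke"
    per_snp_ratio: float | None = None
    _full_fit: object = field(default=None, repr=False)
    _reduced_fit: object = field(default=None, repr=False)

    @property
    def annotation(self) -> pd.Series:
        return self.terms.set_index("term").loc["annotation"]

    def to_frame(self) -> pd.DataFrame:
        out = self.terms.copy()
        out["delta_r2"] = self.delta_r2
        out["improvement_p"] = self.model_improvement_p
        out["n"] = self.n
        out["family"] = self.family
        return out


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a zero-variance column")
    return (x - x.mean()) / sd


def _design(scores: pd.DataFrame, covariates: pd.DataFrame | None) -> pd.DataFrame:
    cols = {}
    for t in SCORE_TERMS:
        if t not in scores.columns:
            raise ValueError(f"scores must include a {t!r} column")
        col = scores[t].to_numpy(dtype=float)
        # zero-variance partitions (e.g. no annotation SNPs) stay identically 0
        cols[t] = _standardize(col) if col.std() > 0 else col - col.mean()
    X = pd.DataFrame(cols, index=scores.index)
    # perfect collinearity among score terms gets a named error
    live = [t for t in SCORE_TERMS if X[t].std() > 0]
    if len(live) >= 2:
        corr = X[live].corr().to_numpy()
        iu = np.triu_indices(len(live), k=1)
        for a, b, r in zip(iu[0], iu[1], corr[iu]):
            if abs(r) > 1 - 1e-10:
                raise CollinearityError(
                    f"score terms {live[a]!r} and {live[b]!r} are perfectly collinear"
                )
    if covariates is not None:
        cov = covariates.loc[scores.index] if hasattr(covariates, "loc") else pd.DataFrame(covariates)
        for c in cov.columns:
            X[c] = cov[c].to_numpy(dtype=float)
    X.insert(0, "const", 1.0)
    return X


def fit_espgs(
    phenotype,
    scores,
    covariates: pd.DataFrame | None = None,
    family: str = "linear",
) -> ESPGSResult:
    """Fit the joint ES-PGS regression and the nested model-improvement test.

    Parameters
    ----------
    phenotype : array-like
        Quantitative trait (linear family; standardized internally) or 0/1
        outcome (logistic family).  No missing values allowed.
    scores : PartitionedScores or DataFrame
        Must expose columns ``background``, ``matched``, ``annotation``.
        Score columns are z-standardized internally, so reported betas are on
        the per-SD scale.
    covariates : DataFrame, optional
        Additional regressors (ancestry PCs, sex, age, ...), used as given.
    family : {"linear", "logistic"}
    """
    import statsmodels.api as sm

    score_df = scores.scores if hasattr(scores, "scores") else pd.DataFrame(scores)
    y = np.asarray(phenotype, dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype contains missing values")
    if len(y) != len(score_df):
        raise ValueError("phenotype and scores have different lengths")
    X = _design(score_df, covariates)
    X_red = X.drop(columns=["annotation"])
    n = len(y)

    if family == "linear":
        y = _standardize(y)
        full = sm.OLS(y, X).fit()
        reduced = sm.OLS(y, X_red).fit()
        r2_full, r2_red = float(full.rsquared), float(reduced.rsquared)
        improvement_p = _partial_f_pvalue(full, reduced)
        r2_kind = "ols"
    elif family == "logistic":
        uniq = set(np.unique(y))
        if not uniq <= {0.0, 1.0}:
            raise ValueError("logistic family requires a 0/1 phenotype")
        if len(uniq) < 2:
            raise ValueError("logistic phenotype is constant")
        try:
            full = sm.Logit(y, X).fit(disp=0, maxiter=200)
            reduced = sm.Logit(y, X_red).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
            raise ValueError(f"logistic fit failed (separation or non-convergence): {exc}")
        r2_full = _nagelkerke(full)
        r2_red = _nagelkerke(reduced)
        lr = 2.0 * (full.llf - reduced.llf)
        improvement_p = float(stats.chi2.sf(max(lr, 0.0), df=1))
        r2_kind = "nagelkerke"
    else:
        raise ValueError(f"unknown family {family!r}")

    rows = []
    for name in X.columns:
        if name == "const":
            continue
        b = float(full.params[name])
        se = float(full.bse[name])
        rows.append(
            {
                "term": name,
                "beta": b,
                "se": se,
                "ci_lo": b - 1.96 * se,
                "ci_hi": b + 1.96 * se,
                "p": float(full.pvalues[name]),
            }
        )
    return ESPGSResult(
        terms=pd.DataFrame(rows),
        r2_reduced=r2_red,
        r2_full=r2_full,
        delta_r2=r2_full - r2_red,
        model_improvement_p=improvement_p,
        n=n,
        family=family,
        r2_kind=r2_kind,
        _full_fit=full,
        _reduced_fit=reduced,
    )


def _nagelkerke(fit) -> float:
    n = fit.nobs
    cox_snell = 1.0 - np.exp((fit.llnull - fit.llf) * 2.0 / n)
    denom = 1.0 - np.exp(fit.llnull * 2.0 / n)
    return float(cox_snell / denom) if denom > 0 else 0.0


def _partial_f_pvalue(full, reduced) -> float:
    df_num = reduced.df_resid - full.df_resid
    if df_num == 0:
        return 1.0
    f = (reduced.ssr - full.ssr) / df_num / (full.ssr / full.df_resid)
    return float(stats.f.sf(max(f, 0.0), df_num, full.df_resid))


def model_improvement_test(full_fit, reduced_fit) -> float:
    """Nested model comparison p-value.

    Accepts either two :class:`ESPGSResult` objects or two fitted statsmodels
    results.  Linear models use the partial F-test on residual sums of
    squares; logistic models use the likelihood-ratio chi-squared with
    degrees of freedom equal to the parameter-count difference.
    """
    full = getattr(full_fit, "_full_fit", full_fit)
    reduced = getattr(reduced_fit, "_full_fit", reduced_fit)
    if full.nobs != reduced.nobs:
        raise ValueError("models fit on different numbers of observations")
    k_full = len(full.params)
    k_red = len(reduced.params)
    if k_red > k_full:
        raise ValueError("reduced model has more parameters than the full model")
    full_names = set(getattr(full.params, "index", range(k_full)))
    red_names = set(getattr(reduced.params, "index", range(k_red)))
    if not red_names <= full_names:
        raise ValueError("models are not nested: reduced terms are not a subset of full terms")
    if hasattr(full, "ssr"):  # linear
        return _partial_f_pvalue(full, reduced)
    lr = 2.0 * (full.llf - reduced.llf)
    df = k_full - k_red
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(max(lr, 0.0), df=df))


def per_snp_power_ratio(
    delta_r2_annot: float, n_annot: int, r2_ref: float, n_ref: int
) -> float:
    """Per-SNP predictive power of the annotation relative to a reference.

    ``rho = (delta_r2_annot / n_annot) / (r2_ref / n_ref)``: how many times
    more variance an average annotation SNP explains than an average
    reference SNP.
    """
    for name, val in (("delta_r2_annot", delta_r2_annot), ("r2_ref", r2_ref)):
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    for name, val in (("n_annot", n_annot), ("n_ref", n_ref)):
        if val <= 0:
            raise ValueError(f"{name} must be a positive count, got {val}")
    return (delta_r2_annot / n_annot) / (r2_ref / n_ref)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank downward
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
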