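"""PWM variant-effect scoring, per-motif selection/language statistics,
York errors-in-variables regression, and TF-family enrichment.

The variant effect of a motif is the best-window log2-odds difference

    delta = best_window_score(alt context) - best_window_score(ref context)

taken over all motif placements covering the variant on both strands.  A
negative delta means the alternate allele weakens predicted binding.

Per motif, the *selection statistic* contrasts reversions (rare alleles
restoring the human-chimpanzee ancestral base) with other rare variants:

    x = mean(-delta | reversions) - mean(-delta | other rare)

so a positive x means ancestral alleles disproportionately destroy binding,
i.e. the derived (hominin) allele gained binding at that motif.  The
*language statistic* y is the regression coefficient of a standardized
phenotype on the standardized per-individual motif-integrity burden.  York
regression of y on x — weighting each motif point by both uncertainties —
asks whether motifs under stronger selection for binding gain are also the
motifs whose integrity predicts the phenotype.

This per-motif x/y construction is a declared reconstruction of the
published figure axes, whose exact formulas are not printed; both statistics
and the burden definition are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PWM",
    "MotifScanError",
    "YorkFit",
    "read_jaspar",
    "scan_delta",
    "motif_selection_stat",
    "motif_language_stat",
    "york_regression",
    "family_enrichment",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MotifScanError(ValueError):
    pass


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities over A,C,G,T."""

    motif_id: str
    name: str
    probs: np.ndarray  # length x 4, rows sum to 1
    background: np.ndarray = None  # length-4, sums to 1
    family: str | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be a length x 4 matrix (A,C,G,T)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM position must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background frequencies must sum to 1")
        if (self.probs <= 0).any():
            raise ValueError("PWM probabilities must be positive (apply a pseudocount)")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        name: str,
        counts: np.ndarray,
        pseudocount: float = 1e-3,
        background: np.ndarray | None = None,
        family: str | None = None,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        return cls(motif_id, name, probs, background, family)

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p / q) per position and base."""
        return np.log2(self.probs / self.background)


def read_jaspar(
    path: str | Path,
    pseudocount: float = 1e-3,
    background: np.ndarray | None = None,
    families: Mapping[str, str] | None = None,
) -> list[PWM]:
    """Parse a JASPAR-style PFM text file (">ID NAME" header + A/C/G/T rows).

    Count matrices are converted to probabilities with a pseudocount.  Rows
    may be bracketed (``A [ 3 0 17 ]``) or bare.  ``families`` optionally
    maps motif ids to TF family labels.
    """
    pwms: list[PWM] = []
    header: tuple[str, str] | None = None
    rows: dict[str, list[float]] = {}

    def flush():
        nonlocal header, rows
        if header is None:
            return
        missing = [b for b in "ACGT" if b not in rows]
        if missing:
            raise ValueError(f"motif {header[0]}: missing base rows {missing}")
        counts = np.array([rows[b] for b in "ACGT"], dtype=float).T
        mid, name = header
        pwms.append(
            PWM.from_counts(
                mid, name, counts, pseudocount, background,
                family=families.get(mid) if families else None,
            )
        )
        header, rows = None, {}

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                header = (parts[0], parts[1] if len(parts) > 1 else parts[0])
            else:
                bits = line.replace("[", " ").replace("]", " ").split()
                base = bits[0].upper()
                if base not in "ACGT" or len(base) != 1:
                    raise ValueError(f"unexpected PFM row: {line!r}")
                rows[base] = [float(v) for v in bits[1:]]
    flush()
    return pwms


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        if ch == "N":
            out[i] = -1
        else:
            try:
                out[i] = _BASE_INDEX[ch]
            except KeyError:
                raise MotifScanError(f"non-ACGTN character {ch!r} in sequence") from None
    return out


def _best_window_score(seq: str, pwm: PWM, center: int) -> float:
    """Max log2-odds over windows covering ``center``, both strands.

    Windows containing N are skipped.  Returns -inf if every window is
    skipped (callers decide how to handle it).
    """
    lo_fwd = pwm.log_odds
    lo_rev = lo_fwd[::-1, ::-1]  # reverse-complement scan of the forward strand
    m = len(pwm)
    codes = _encode(seq)
    best = -np.inf
    for off in range(max(0, center - m + 1), min(center, len(seq) - m) + 1):
        window = codes[off : off + m]
        if (window < 0).any():
            continue  # N in window
        idx = np.arange(m)
        s_fwd = float(lo_fwd[idx, window].sum())
        s_rev = float(lo_rev[idx, window].sum())
        best = max(best, s_fwd, s_rev)
    return best


def scan_delta(ref_context: str, alt_context: str, pwm: PWM) -> float:
    """Best-window log2-odds change caused by a variant.

    Both contexts must be equal-length sequences centered on the variant
    (variant at index ``len // 2``) and at least ``2 * len(pwm) - 1`` long so
    every motif placement covering the variant fits.  Both strands are
    scanned; windows containing N are skipped.
    """
    if len(ref_context) != len(alt_context):
        raise MotifScanError("ref and alt contexts must have equal length")
    if len(ref_context) < len(pwm):
        raise MotifScanError(
            f"context length {len(ref_context)} shorter than motif length {len(pwm)}"
        )
    center = len(ref_context) // 2
    best_ref = _best_window_score(ref_context, pwm, center)
    best_alt = _best_window_score(alt_context, pwm, center)
    if not np.isfinite(best_ref) or not np.isfinite(best_alt):
        raise MotifScanError("no N-free motif window covers the variant")
    return best_alt - best_ref


def motif_selection_stat(
    deltas_reversions: Sequence[float], deltas_other_rare: Sequence[float]
) -> tuple[float, float, float]:
    """Selection statistic for one motif: reversions vs other rare variants.

    Returns ``(x, se, p)`` where ``x = mean(-delta | reversions) -
    mean(-delta | other)``; positive x means reversions disproportionately
    destroy predicted binding (the derived allele gained binding).  The
    standard error and p-value come from Welch's unequal-variance t-test.
    """
    a = -np.asarray(deltas_reversions, dtype=float)
    b = -np.asarray(deltas_other_rare, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 delta values per group")
    x = float(a.mean() - b.mean())
    se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
    if se == 0:
        raise ValueError("both groups have zero variance; Welch SE undefined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return x, se, float(p)


def motif_language_stat(
    burden: Sequence[float],
    phenotype: Sequence[float],
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float, float]:
    """Language statistic for one motif.

    Regression coefficient of the standardized phenotype on the standardized
    per-individual motif-integrity burden (plus optional covariates).
    Returns ``(y, se, p)``.
    """
    import statsmodels.api as sm

    x = np.asarray(burden, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if len(x) != len(y):
        raise ValueError("burden and phenotype lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 individuals")
    if x.std() == 0:
        raise ValueError("zero-variance burden")
    if y.std() == 0:
        raise ValueError("zero-variance phenotype")
    X = pd.DataFrame({"burden": (x - x.mean()) / x.std()})
    if covariates is not None:
        for c in covariates.columns:
            X[c] = np.asarray(covariates[c], dtype=float)
    X.insert(0, "const", 1.0)
    fit = sm.OLS((y - y.mean()) / y.std(), X).fit()
    se = float(fit.bse["burden"])
    p = float(fit.pvalues["burden"]) if se > 0 else 0.0
    return float(fit.params["burden"]), se, p


@dataclass
class YorkFit:
    """Straight-line fit with errors in both variables (zero error correlation)."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    chi2: float
    p: float
    n_iter: int
    converged: bool
    n: int


def york_regression(
    x: Sequence[float],
    y: Sequence[float],
    sigma_x: Sequence[float],
    sigma_y: Sequence[float],
    max_iter: int = 200,
    tol: float = 1e-10,
) -> YorkFit:
    """Iterative York (2004) errors-in-both-variables line fit.

    Weights per point: ``W_i = w_x w_y / (w_x + b^2 w_y)`` with
    ``w = 1 / sigma^2`` and zero x-y error correlation.  The slope iterates
    via ``b = sum(W beta V) / sum(W beta U)`` where ``U, V`` are weighted-mean
    deviations and ``beta_i = W_i (U_i / w_y + b V_i / w_x)``, until
    ``|delta b| < tol``.  The goodness statistic is
    ``chi2 = sum W_i (y_i - b x_i - a)^2`` and the p-value is a two-sided
    Wald test on the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = np.asarray(sigma_x, dtype=float)
    sy = np.asarray(sigma_y, dtype=float)
    n = len(x)
    if not (len(y) == len(sx) == len(sy) == n):
        raise ValueError("x, y, sigma_x, sigma_y must have equal length")
    if n < 3:
        raise ValueError("York regression needs at least 3 points")
    if (sx <= 0).any() or (sy <= 0).any():
        raise ValueError("all sigma values must be positive")

    w_x = 1.0 / sx**2
    w_y = 1.0 / sy**2
    # OLS starting slope
    b = float(np.polyfit(x, y, 1)[0])
    trace = [b]
    converged = False
    for it in range(1, max_iter + 1):
        W = w_x * w_y / (w_x + b * b * w_y)
        xbar = float((W * x).sum() / W.sum())
        ybar = float((W * y).sum() / W.sum())
        U = x - xbar
        V = y - ybar
        beta_i = W * (U / w_y + b * V / w_x)
        b_new = float((W * beta_i * V).sum() / (W * beta_i * U).sum())
        trace.append(b_new)
        if abs(b_new - b) < tol:
            b = b_new
            converged = True
            break
        b = b_new
    if not converged:
        raise RuntimeError(
            f"York regression did not converge in {max_iter} iterations; "
            f"slope trace tail: {trace[-6:]}"
        )
    W = w_x * w_y / (w_x + b * b * w_y)
    xbar = float((W * x).sum() / W.sum())
    ybar = float((W * y).sum() / W.sum())
    a = ybar - b * xbar
    beta_i = W * ((x - xbar) / w_y + b * (y - ybar) / w_x)
    x_adj = xbar + beta_i
    xbar_adj = float((W * x_adj).sum() / W.sum())
    u = x_adj - xbar_adj
    var_b = 1.0 / float((W * u * u).sum())
    var_a = 1.0 / float(W.sum()) + xbar_adj**2 * var_b
    chi2 = float((W * (y - b * x - a) ** 2).sum())
    z = b / np.sqrt(var_b)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return YorkFit(
        slope=b,
        intercept=a,
        slope_se=float(np.sqrt(var_b)),
        intercept_se=float(np.sqrt(var_a)),
        chi2=chi2,
        p=p,
        n_iter=it,
        converged=converged,
        n=n,
    )


def family_enrichment(points: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """TF-family enrichment for concordant selection and language effects.

    ``points`` needs columns ``motif_id``, ``family``, ``x``, ``p_x``, ``y``,
    ``p_y``.  A motif is *concordant* when both statistics are positive and
    individually significant at ``alpha``.  For each family, a 2x2 table
    (in-family vs not x concordant vs not) gives the odds ratio (Haldane 0.5
    correction when any cell is zero), Fisher exact p, and a Wald CI on the
    log2 odds ratio.
    """
    req = {"motif_id", "family", "x", "p_x", "y", "p_y"}
    if not req <= set(points.columns):
        raise ValueError(f"points missing columns: {sorted(req - set(points.columns))}")
    families = points["family"].dropna().unique()
    if len(families) < 2:
        raise ValueError("need at least 2 TF families")
    concordant = (
        (points["x"] > 0) & (points["p_x"] < alpha) & (points["y"] > 0) & (points["p_y"] < alpha)
    ).to_numpy()
    fam = points["family"].to_numpy()
    rows = []
    for f in families:
        in_f = fam == f
        n11 = int((in_f & concordant).sum())
        n10 = int((in_f & ~concordant).sum())
        n01 = int((~in_f & concordant).sum())
        n00 = int((~in_f & ~concordant).sum())
        if n11 + n10 == 0:
            import warnings

            warnings.warn(f"family {f!r} has no members; skipped")
            continue
        _, fisher_p = stats.fisher_exact([[n11, n10], [n01, n00]])
        cells = np.array([n11, n10, n01, n00], dtype=float)
        if (cells == 0).any():
            cells = cells + 0.5
        or_val = (cells[0] * cells[3]) / (cells[1] * cells[2])
        log2_or = float(np.log2(or_val))
        se_ln = float(np.sqrt((1.0 / cells).sum()))
        half = 1.96 * se_ln / np.log(2)
        rows.append(
            {
                "family": f,
                "n_motifs": n11 + n10,
                "n_concordant": n11,
                "odds_ratio": float(or_val),
                "log2_or": log2_or,
                "ci_lo": log2_or - half,
                "ci_hi": log2_or + half,
                "p": float(fisher_p),
            }
        )
    return pd.DataFrame(rows)
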