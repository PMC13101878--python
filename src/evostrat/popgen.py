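"""Balancing-selection diagnostics: SFS ratios, heterozygosity, inbreeding F.

An excess of intermediate-frequency variants and of heterozygotes relative
to Hardy-Weinberg expectation are the two classic desk-level signatures of
balancing selection.  The site-frequency-spectrum comparison reports, per
minor-allele-frequency bin, ``L_k = log2(prop_A,k / prop_B,k)`` with
variant-level bootstrap percentile confidence intervals; the inbreeding
coefficient is ``F = 1 - sum(H_obs) / sum(H_exp)`` so that negative values
indicate heterozygote excess.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SFSResult",
    "HetFStats",
    "DEFAULT_MAF_BINS",
    "sfs_log2ratio",
    "heterozygosity_by_class",
    "inbreeding_F",
]

# the top bin isolates intermediate-frequency (30-50%) variation
DEFAULT_MAF_BINS = (0.0, 0.1, 0.2, 0.3, 0.5)


@dataclass
class SFSResult:
    """Per-bin log2 ratio of variant proportions with bootstrap CIs."""

    table: pd.DataFrame  # bin_lo, bin_hi, prop_a, prop_b, log2_ratio, ci_lo, ci_hi, defined
    n_boot: int
    n_a: int
    n_b: int


def _bin_counts(maf: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Counts per right-closed bin (lo, hi]; values at or below edges[0] or
    above edges[-1] are excluded."""
    idx = np.digitize(maf, edges, right=True)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for k in range(1, len(edges)):
        counts[k - 1] = int(np.sum(idx == k))
    return counts


def sfs_log2ratio(
    maf_a: Sequence[float],
    maf_b: Sequence[float],
    bin_edges: Sequence[float] = DEFAULT_MAF_BINS,
    n_boot: int = 1000,
    seed: int = 0,
) -> SFSResult:
    """Compare two site frequency spectra as per-bin log2 proportion ratios.

    Proportions are computed within each set over the variants that fall in
    a bin (monomorphic sites, MAF = 0, are excluded).  The bootstrap
    resamples variants within each set independently (the variant, not the
    individual, is the sampling unit) and reports 95% percentile intervals.
    Bins empty in either set yield an undefined (NaN) ratio, flagged rather
    than raised.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 3:
        raise ValueError("need at least 2 bins")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    a = np.asarray(maf_a, dtype=float)
    b = np.asarray(maf_b, dtype=float)
    for name, arr in (("maf_a", a), ("maf_b", b)):
        if ((arr < 0) | (arr > 0.5)).any():
            raise ValueError(f"{name} must contain minor allele frequencies in [0, 0.5]")
    rng = np.random.default_rng(seed)

    counts_a = _bin_counts(a, edges)
    counts_b = _bin_counts(b, edges)
    n_a, n_b = int(counts_a.sum()), int(counts_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("no variants fall inside the bins in one of the sets")
    prop_a = counts_a / n_a
    prop_b = counts_b / n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        l2 = np.log2(prop_a / prop_b)
    defined = (counts_a > 0) & (counts_b > 0)

    # multinomial bootstrap over bin memberships == resampling variants
    boot_a = rng.multinomial(n_a, prop_a, size=n_boot) / n_a
    boot_b = rng.multinomial(n_b, prop_b, size=n_boot) / n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        boot_l2 = np.log2(boot_a / boot_b)
    boot_l2[~np.isfinite(boot_l2)] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ci_lo = np.nanpercentile(boot_l2, 2.5, axis=0)
        ci_hi = np.nanpercentile(boot_l2, 97.5, axis=0)

    table = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "prop_a": prop_a,
            "prop_b": prop_b,
            "log2_ratio": np.where(defined, l2, np.nan),
            "ci_lo": np.where(defined, ci_lo, np.nan),
            "ci_hi": np.where(defined, ci_hi, np.nan),
            "defined": defined,
        }
    )
    return SFSResult(table=table, n_boot=n_boot, n_a=n_a, n_b=n_b)


@dataclass
class HetFStats:
    """Per-class heterozygosity summaries and pairwise Welch tests."""

    per_class: pd.DataFrame  # class, n_variants, mean_h_obs, mean_h_exp, F
    pairwise: pd.DataFrame  # class_a, class_b, t, p


def _per_variant_het(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Observed and expected heterozygosity per variant (columns)."""
    obs_mask = np.isfinite(dosages)
    n_obs = obs_mask.sum(axis=0)
    if (n_obs == 0).any():
        raise ValueError("a variant has all-missing genotypes")
    h_obs = np.nansum(dosages == 1, axis=0) / n_obs
    p_alt = np.nansum(dosages, axis=0) / (2.0 * n_obs)
    h_exp = 2.0 * p_alt * (1.0 - p_alt)
    return h_obs, h_exp


def heterozygosity_by_class(
    dosages: np.ndarray, variant_class_labels: Sequence[str]
) -> HetFStats:
    """Observed/expected heterozygosity and inbreeding F per region class.

    ``dosages`` is samples x variants; ``variant_class_labels`` assigns each
    variant (column) to a class.  Per-variant observed heterozygosity is the
    fraction of heterozygous calls among non-missing genotypes; expected is
    ``2 p (1 - p)`` from the alt-allele frequency.  Classes are compared by
    Welch's t-test on per-variant observed heterozygosity.
    """
    labels = np.asarray(variant_class_labels)
    if dosages.shape[1] != len(labels):
        raise ValueError("one class label required per variant column")
    classes = pd.unique(labels)
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 variants")
    h_obs, h_exp = _per_variant_het(dosages)

    rows = []
    for c in classes:
        m = labels == c
        sum_exp = h_exp[m].sum()
        f = 1.0 - h_obs[m].sum() / sum_exp if sum_exp > 0 else np.nan
        rows.append(
            {
                "class": c,
                "n_variants": int(m.sum()),
                "mean_h_obs": float(h_obs[m].mean()),
                "mean_h_exp": float(h_exp[m].mean()),
                "F": float(f),
            }
        )
    pair_rows = []
    for ca, cb in combinations(classes, 2):
        t, p = stats.ttest_ind(h_obs[labels == ca], h_obs[labels == cb], equal_var=False)
        pair_rows.append({"class_a": ca, "class_b": cb, "t": float(t), "p": float(p)})
    return HetFStats(per_class=pd.DataFrame(rows), pairwise=pd.DataFrame(pair_rows))


def inbreeding_F(dosages: np.ndarray, variant_subset: Sequence[int] | None = None) -> float:
    """Inbreeding coefficient ``F = 1 - sum(H_obs) / sum(H_exp)``.

    Sums run over the variant subset (columns).  Returns NaN (with a
    warning) when every variant is monomorphic, where F is undefined.
    Negative F indicates heterozygote excess.
    """
    d = dosages if variant_subset is None else dosages[:, list(variant_subset)]
    if d.shape[1] == 0:
        raise ValueError("variant subset is empty")
    if d.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    h_obs, h_exp = _per_variant_het(d)
    denom = h_exp.sum()
    if denom == 0:
        warnings.warn("all variants monomorphic: inbreeding F undefined")
        return float("nan")
    return float(1.0 - h_obs.sum() / denom)
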