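"""Rare ancestral-allele reversions and burden-phenotype association.

A *reversion* is a rare variant whose alternate allele restores the inferred
human-chimpanzee ancestral state, undoing a human-specific substitution:
``alt == ancestral`` and ``ref != ancestral``.  Variants with unknown
ancestral state are excluded from classification entirely (not treated as
non-reversions), which avoids polarization bias.

Burden counting follows the 10-kb flank convention: a variant contributes to
a region class if its (1-based) position lies within ``[start - window,
end + window)`` of any region in the class, counted once per class even when
near several regions.  The per-individual burden is the carried allele count
(heterozygote 1, homozygote 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import RegionSet

__all__ = [
    "BurdenCounts",
    "classify_reversions",
    "count_reversions_near",
    "burden_association",
    "DEFAULT_RARE_THRESHOLD",
    "DEFAULT_WINDOW_BP",
]

DEFAULT_RARE_THRESHOLD = 0.01
DEFAULT_WINDOW_BP = 10_000
_BASES = {"A", "C", "G", "T"}
_UNKNOWN = {".", "N", "", "-", None}


@dataclass
class BurdenCounts:
    """Per-individual reversion allele counts by region class."""

    counts: pd.DataFrame  # index = individual id; one column per region class
    window_bp: int

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "individual_id"
        out.to_csv(path, sep="\t")


def classify_reversions(
    variants: pd.DataFrame,
    rare_threshold: float = DEFAULT_RARE_THRESHOLD,
) -> pd.DataFrame:
    """Flag reversions among a variant table.

    ``variants`` needs columns ``ref``, ``alt``, ``alt_freq`` and
    ``ancestral``.  Returns a copy with boolean columns ``is_polarized``
    (ancestral allele known), ``is_rare`` and ``is_reversion``.  A variant is
    a reversion iff it is rare, polarized, ``alt == ancestral`` and
    ``ref != ancestral``.
    """
    anc = variants["ancestral"]
    normalized = anc.where(anc.notna(), ".").astype(str).str.upper()
    bad = ~normalized.isin(_BASES | {".", "N", "-", ""})
    if bad.any():
        raise ValueError(
            f"invalid ancestral allele values: {sorted(normalized[bad].unique())}"
        )
    out = variants.copy()
    out["is_polarized"] = normalized.isin(_BASES).to_numpy()
    out["is_rare"] = (variants["alt_freq"] < rare_threshold).to_numpy()
    out["is_reversion"] = (
        out["is_polarized"]
        & out["is_rare"]
        & (variants["alt"].str.upper() == normalized)
        & (variants["ref"].str.upper() != normalized)
    ).to_numpy()
    return out


def read_ancestral_table(path) -> pd.DataFrame:
    """Read an ancestral-allele TSV (chrom, pos, ancestral)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("chrom", "pos", "ancestral") if c not in df.columns]
    if missing:
        raise ValueError(f"ancestral table missing columns: {missing}")
    return df


def read_ancestral_vcf(path, info_key: str = "AA") -> pd.DataFrame:
    """Extract ancestral alleles from a VCF INFO key (default ``AA``).

    Sites without the key get ancestral ``.`` (unknown).
    """
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        anc = rec.INFO.get(info_key)
        rows.append(
            {"chrom": rec.CHROM, "pos": rec.POS, "ancestral": str(anc).upper() if anc else "."}
        )
    return pd.DataFrame(rows)


def _flank_tree(regions: RegionSet, window_bp: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        start = max(0, r.start - window_bp)
        trees.setdefault(r.chrom, IntervalTree()).addi(start, r.end + window_bp)
    return trees


def count_reversions_near(
    regions_by_class: Mapping[str, RegionSet],
    variants: pd.DataFrame,
    dosages: np.ndarray,
    samples: list[str],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> BurdenCounts:
    """Per-individual reversion allele counts within ``window_bp`` of each class.

    ``variants`` must carry ``chrom``, ``pos`` (1-based) and ``is_reversion``
    (see :func:`classify_reversions`); ``dosages`` is samples x variants with
    NaN for missing calls (treated as 0 carried alleles).  A variant counts
    toward a class at most once even if it flanks several of its regions.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if dosages.shape != (len(samples), len(variants)):
        raise ValueError("dosage shape inconsistent with samples x variants")
    rev_idx = np.flatnonzero(variants["is_reversion"].to_numpy())
    cols = {}
    for cls, regions in regions_by_class.items():
        trees = _flank_tree(regions, window_bp)
        members = []
        for j in rev_idx:
            chrom = variants["chrom"].iloc[j]
            pos = int(variants["pos"].iloc[j])
            tree = trees.get(chrom)
            # 1-based pos p is inside [s, e) iff s < p <= e, i.e. point p-1
            if tree is not None and tree[pos - 1]:
                members.append(j)
        if members:
            cols[cls] = np.nansum(dosages[:, members], axis=1)
        else:
            cols[cls] = np.zeros(len(samples))
    counts = pd.DataFrame(cols, index=samples)
    return BurdenCounts(counts=counts, window_bp=window_bp)


def burden_association(
    counts: pd.Series,
    phenotype,
    covariates: pd.DataFrame | None = None,
    family: str = "linear",
) -> tuple[float, float, float]:
    """Regression of phenotype on the standardized reversion burden.

    Returns ``(beta, se, p)`` for the burden term.  The logistic family is
    appropriate for diagnosis outcomes; the linear family for quantitative
    language scores.  Delegates to the same fitting machinery as the ES-PGS
    model by treating the burden as a single standardized predictor.
    """
    import statsmodels.api as sm

    x = np.asarray(counts, dtype=float)
    if x.std() == 0:
        raise ValueError("reversion counts have zero variance")
    y = np.asarray(phenotype, dtype=float)
    if len(y) != len(x):
        raise ValueError("counts and phenotype have different lengths")
    X = pd.DataFrame({"burden": (x - x.mean()) / x.std()}, index=getattr(counts, "index", None))
    if covariates is not None:
        for c in covariates.columns:
            X[c] = np.asarray(covariates[c], dtype=float)
    X.insert(0, "const", 1.0)
    if family == "linear":
        sd = y.std()
        if sd == 0:
            raise ValueError("phenotype is constant")
        fit = sm.OLS((y - y.mean()) / sd, X).fit()
    elif family == "logistic":
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    else:
        raise ValueError(f"unknown family {family!r}")
    return float(fit.params["burden"]), float(fit.bse["burden"]), float(fit.pvalues["burden"])
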