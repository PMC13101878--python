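"""GWAS summary statistics, LD clumping, and partitioned polygenic scores.

A polygenic score here is the weighted allele count ``PGS_i = sum_j g_ij * beta_j``
over a set of approximately independent ("clumped") variants.  No ``/2M``
averaging is applied: scores are z-standardized before association testing,
so the absolute scale is immaterial.

Partitioned scores split the clumped variant set by evolutionary annotation
(annotation / matched-control / background) and score each subset separately;
by construction the three partition scores sum exactly to the genome-wide
score.

Degraded (ancient-DNA) genotypes are scored over observed sites only and
rescaled by the ratio of total |beta| mass over the full panel to |beta| mass
over the observed sites, with the coverage fraction reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PartitionedScores",
    "HarmonizationError",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "ld_clump",
    "compute_pgs",
    "partition_scores",
    "score_degraded",
]

SUMSTAT_COLUMNS = ("variant_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "p")
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


class HarmonizationError(ValueError):
    """Raised when no summary-statistic variant can be aligned to the genotypes."""


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with per-variant metadata.

    ``dosages`` is samples x variants, entries in {0, 1, 2} or NaN (missing).
    ``variants`` carries columns: variant_id, chrom, pos (1-based), ref, alt.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValueError("dosages must lie in [0, 2] or be NaN")
        self._index = {v: j for j, v in enumerate(self.variants["variant_id"])}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def columns(self, variant_ids: Sequence[str]) -> np.ndarray:
        """Dosage submatrix for the given variant ids (in that order)."""
        try:
            idx = [self._index[v] for v in variant_ids]
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} not in genotype matrix") from None
        return self.dosages[:, idx]

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        """Read GT fields of a VCF 4.x file into a dosage matrix.

        Multi-allelic records are skipped with a warning; missing genotypes
        become NaN.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, dosage_rows = [], []
        for rec in vcf:
            if len(rec.ALT) != 1:
                logger.warning("skipping multi-allelic record %s:%d", rec.CHROM, rec.POS)
                continue
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = rec.gt_types.astype(float)
            dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
            vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
            rows.append((vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
            dosage_rows.append(dosage)
        variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])
        dosages = np.array(dosage_rows).T if dosage_rows else np.empty((len(samples), 0))
        return cls(samples=samples, variants=variants, dosages=dosages)

    def write_vcf(self, path: str | Path) -> None:
        """Write the matrix as an uncompressed VCF 4.2 file (GT only)."""
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        order = self.variants.sort_values(["chrom", "pos"], kind="stable").index
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in pd.unique(self.variants["chrom"]):
                max_pos = int(self.variants.loc[self.variants["chrom"] == chrom, "pos"].max())
                fh.write(f"##contig=<ID={chrom},length={max_pos + 1000}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(self.samples) + "\n")
            for j in order:
                v = self.variants.loc[j]
                gts = "\t".join(
                    gt_codes.get(d, "./.") if np.isfinite(d) else "./." for d in self.dosages[:, j]
                )
                fh.write(
                    f"{v.chrom}\t{int(v.pos)}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
                )


@dataclass
class PartitionedScores:
    """Per-individual polygenic scores split by evolutionary partition."""

    scores: pd.DataFrame  # index = individual id; columns = background, matched, annotation
    n_snps: dict[str, int]

    @property
    def total(self) -> pd.Series:
        return self.scores.sum(axis=1)

    def write_tsv(self, path: str | Path) -> None:
        out = self.scores.copy()
        out.index.name = "individual_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Summary statistics I/O


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV with required header names."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing required columns: {missing}")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (df["effect_allele"] == df["other_allele"]).any():
        raise ValueError("effect and other allele must differ")
    return df


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization


def _is_ambiguous(a1: str, a2: str) -> bool:
    return {a1, a2} in _AMBIGUOUS_PAIRS


def harmonize(sumstats: pd.DataFrame, genotype_variants: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Align summary-statistic effect alleles to the genotype alt allele.

    Variants are keyed by (chrom, pos).  When the effect allele equals the
    genotype ref allele the sign of beta is flipped so that beta is always
    per copy of the alt allele.  Strand-ambiguous sites (A/T, C/G) are
    dropped and counted, as are sites whose allele pair does not match.

    Returns the aligned table (columns of the genotype variant plus
    ``beta`` and ``p``) and a dict of drop counters.
    """
    gv = genotype_variants[["variant_id", "chrom", "pos", "ref", "alt"]]
    merged = gv.merge(
        sumstats, on=["chrom", "pos"], how="inner", suffixes=("", "_ss")
    )
    counters = {"ambiguous_dropped": 0, "allele_mismatch_dropped": 0}
    keep_rows = []
    for row in merged.itertuples(index=False):
        if _is_ambiguous(row.effect_allele, row.other_allele):
            counters["ambiguous_dropped"] += 1
            continue
        if row.effect_allele == row.alt and row.other_allele == row.ref:
            beta = row.beta
        elif row.effect_allele == row.ref and row.other_allele == row.alt:
            beta = -row.beta
        else:
            counters["allele_mismatch_dropped"] += 1
            continue
        keep_rows.append(
            {
                "variant_id": row.variant_id,
                "chrom": row.chrom,
                "pos": row.pos,
                "ref": row.ref,
                "alt": row.alt,
                "beta": beta,
                "p": row.p,
            }
        )
    if not keep_rows:
        raise HarmonizationError("no summary-statistic variants could be aligned to the genotypes")
    return pd.DataFrame(keep_rows), counters


# ---------------------------------------------------------------------------
# LD clumping


def ld_clump(
    sumstats: pd.DataFrame,
    reference_genotypes: GenotypeMatrix,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
) -> list[str]:
    """Greedy LD clumping to an approximately independent variant set.

    Variants are visited in ascending p-value order (ties broken by variant
    id, so the result is invariant to input row order).  A variant is kept
    unless its squared dosage correlation with an already-kept variant within
    ``window_kb`` on the same chromosome exceeds ``r2_threshold``.
    Monomorphic variants are treated as uncorrelated (warning logged).
    """
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must lie in (0, 1]")
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    window_bp = window_kb * 1000.0

    df = sumstats.sort_values(["p", "variant_id"], kind="stable")
    dos = reference_genotypes.columns(list(df["variant_id"]))
    # mean-impute missing dosages so correlations are defined
    col_mean = np.nanmean(np.where(np.isnan(dos), np.nan, dos), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    dos = np.where(np.isnan(dos), col_mean, dos)
    centered = dos - dos.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    mono = norms == 0
    if mono.any():
        logger.warning("%d monomorphic variants treated as uncorrelated in clumping", int(mono.sum()))

    chroms = df["chrom"].to_numpy()
    positions = df["pos"].to_numpy(dtype=float)
    vids = df["variant_id"].to_numpy()

    kept: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    for i in range(len(df)):
        ok = True
        for k in kept_by_chrom.get(chroms[i], []):
            if abs(positions[i] - positions[k]) > window_bp:
                continue
            if mono[i] or mono[k]:
                continue
            r = float(centered[:, i] @ centered[:, k]) / (norms[i] * norms[k])
            if r * r > r2_threshold:
                ok = False
                break
        if ok:
            kept.append(i)
            kept_by_chrom.setdefault(chroms[i], []).append(i)
    return [vids[i] for i in kept]


# ---------------------------------------------------------------------------
# Scoring


def compute_pgs(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    variant_subset: Sequence[str] | None = None,
) -> pd.Series:
    """Weighted allele count per individual over ``variant_subset``.

    ``weights`` must carry ``variant_id`` and ``beta`` (alt-allele aligned,
    as produced by :func:`harmonize`).  Missing dosages are imputed with the
    variant's sample-mean dosage.
    """
    w = weights.set_index("variant_id")["beta"]
    ids = list(variant_subset) if variant_subset is not None else list(w.index)
    if not ids:
        raise ValueError("variant subset is empty")
    beta = w.loc[ids].to_numpy(dtype=float)
    dos = genotypes.columns(ids).astype(float)
    col_mean = np.nanmean(np.where(np.isnan(dos), np.nan, dos), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    dos = np.where(np.isnan(dos), col_mean, dos)
    return pd.Series(dos @ beta, index=genotypes.samples, name="pgs")


def partition_scores(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    clumped_ids: Sequence[str],
    partition_labels: Mapping[str, str],
) -> PartitionedScores:
    """Score each evolutionary partition of the clumped variant set.

    ``partition_labels`` maps every clumped variant id to one of
    {"annotation", "matched", "background"}.  Partition SNP counts sum to
    ``len(clumped_ids)`` and partition scores sum to the genome-wide score.
    """
    parts = ("background", "matched", "annotation")
    by_part: dict[str, list[str]] = {p: [] for p in parts}
    for vid in clumped_ids:
        if vid not in partition_labels:
            raise KeyError(f"no partition label for clumped variant {vid!r}")
        lab = partition_labels[vid]
        if lab not in by_part:
            raise ValueError(f"unknown partition label {lab!r} for variant {vid!r}")
        by_part[lab].append(vid)
    cols = {}
    for p in parts:
        if by_part[p]:
            cols[p] = compute_pgs(genotypes, weights, by_part[p])
        else:
            cols[p] = pd.Series(0.0, index=genotypes.samples)
    scores = pd.DataFrame(cols)
    return PartitionedScores(scores=scores, n_snps={p: len(by_part[p]) for p in parts})


def score_degraded(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    variant_subset: Sequence[str],
) -> pd.DataFrame:
    """Coverage-aware scores for degraded (e.g. ancient) genotypes.

    The score over observed sites is rescaled by
    ``sum(|beta|) over the subset / sum(|beta|) over observed sites`` so that
    samples with different missingness are comparable in expectation.
    Returns a frame with columns ``score`` (NaN when coverage is 0) and
    ``coverage``.
    """
    ids = list(variant_subset)
    if not ids:
        raise ValueError("variant subset is empty")
    w = weights.set_index("variant_id")["beta"].loc[ids].to_numpy(dtype=float)
    dos = genotypes.columns(ids).astype(float)
    observed = np.isfinite(dos)
    total_mass = float(np.abs(w).sum())
    obs_mass = (observed * np.abs(w)).sum(axis=1)
    raw = np.nansum(dos * w, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(obs_mass > 0, raw * total_mass / obs_mass, np.nan)
    coverage = observed.sum(axis=1) / len(ids)
    return pd.DataFrame(
        {"score": score, "coverage": coverage}, index=genotypes.samples
    )
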