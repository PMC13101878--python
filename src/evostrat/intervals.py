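"""Genomic intervals: BED I/O, region covariates, matched controls, enrichment.

Coordinate conventions
----------------------
Intervals are BED-style: 0-based, half-open ``[start, end)``.  Variant
positions follow the VCF convention (1-based).  The two meet at a single
documented junction: a 1-based position ``p`` overlaps ``[start, end)``
iff ``start < p <= end`` (equivalently, the 0-based coordinate ``p - 1``
lies inside the interval).

The matched-control sampler implements greedy nearest-neighbour matching
without replacement on z-scored covariates, stratified by chromosome, which
reproduces the covariate list used to build control panels for evolutionary
annotations (length, GC content, distance to genes, coding overlap, and
chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicRegion",
    "RegionSet",
    "MatchDiagnostics",
    "EnrichmentResult",
    "BedParseError",
    "MatchingError",
    "read_bed",
    "write_bed",
    "compute_region_covariates",
    "sample_matched_controls",
    "permutation_enrichment",
    "assign_variants_to_partitions",
]

VALID_LABELS = ("annotation", "matched", "background", "other")


class BedParseError(ValueError):
    """Raised when a BED file cannot be parsed; names the offending line."""


class MatchingError(ValueError):
    """Raised when a matching stratum has too few candidate regions."""


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    region_id: str | None = None
    label: str = "other"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {VALID_LABELS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> str:
        """Stable identifier: explicit region_id, else coordinates."""
        return self.region_id if self.region_id is not None else f"{self.chrom}:{self.start}-{self.end}"

    def contains_position(self, pos: int) -> bool:
        """True iff the 1-based position ``pos`` falls inside the interval."""
        return self.start < pos <= self.end


class RegionSet:
    """An ordered collection of :class:`GenomicRegion` with overlap queries."""

    def __init__(self, regions: Iterable[GenomicRegion], name: str | None = None):
        self.regions: list[GenomicRegion] = list(regions)
        self.name = name
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> GenomicRegion:
        return self.regions[i]

    @property
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.chrom, None)
        return list(seen)

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees (built lazily, cached)."""
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for r in self.regions:
                trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
            self._trees = trees
        return self._trees

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        tree = self.trees().get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def overlaps_position(self, chrom: str, pos: int) -> bool:
        """Overlap query for a 1-based (VCF) position."""
        tree = self.trees().get(chrom)
        return bool(tree is not None and tree[pos - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "region_id": [r.key for r in self.regions],
                "label": [r.label for r in self.regions],
            }
        )


def read_bed(path: str | Path, label: str = "other") -> RegionSet:
    """Read a BED3/BED4 file (tab-separated, no header) into a :class:`RegionSet`.

    The optional 4th column becomes ``region_id``.  Malformed lines raise
    :class:`BedParseError` naming the 1-based line number.
    """
    path = Path(path)
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate ({exc})") from None
            region_id = fields[3] if len(fields) >= 4 and fields[3] != "" else None
            try:
                regions.append(GenomicRegion(fields[0], start, end, region_id, label))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    return RegionSet(regions, name=path.stem)


def write_bed(regions: RegionSet | Iterable[GenomicRegion], path: str | Path) -> None:
    """Write regions as BED3 (or BED4 when any region carries an id)."""
    regions = list(regions)
    with_ids = any(r.region_id is not None for r in regions)
    with open(path, "w") as fh:
        for r in regions:
            if with_ids:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.key}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


@dataclass
class MatchDiagnostics:
    """Quality report for covariate matching.

    ``smd`` maps each covariate to the standardized mean difference
    ``|mean_target - mean_control| / pooled SD`` between the target set and
    the selected controls (0 is a perfect match on that covariate).
    """

    smd: dict[str, float]
    n_matched: int
    n_requested: int

    @property
    def max_smd(self) -> float:
        return max(self.smd.values()) if self.smd else 0.0


@dataclass
class EnrichmentResult:
    """Permutation enrichment of one region set within another."""

    observed_overlap: int
    null_mean: float
    null_sd: float
    empirical_p: float
    n_perm: int


# ---------------------------------------------------------------------------
# Region covariates


def _as_fasta(genome_fasta):
    import pyfaidx

    if isinstance(genome_fasta, (str, Path)):
        return pyfaidx.Fasta(str(genome_fasta))
    return genome_fasta


def _gc_fraction(seq: str) -> float:
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    denom = gc + at  # ambiguous bases excluded from the denominator
    return gc / denom if denom else float("nan")


def _sorted_intervals_by_chrom(regions: RegionSet) -> dict[str, np.ndarray]:
    out: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        out.setdefault(r.chrom, []).append((r.start, r.end))
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in out.items()}


def _merge_intervals(arr: np.ndarray) -> np.ndarray:
    merged: list[list[int]] = []
    for s, e in arr:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


def compute_region_covariates(
    regions: RegionSet,
    genome_fasta,
    gene_bed: RegionSet,
    coding_bed: RegionSet | None = None,
) -> pd.DataFrame:
    """Length, GC fraction, distance to nearest gene, and coding overlap per region.

    GC fraction counts G+C over unambiguous bases only.  Distance to the
    nearest gene is 0 for regions overlapping a gene, and is computed within
    the region's chromosome.  Coding overlap is the fraction of region bases
    covered by the (merged) coding intervals.
    """
    if len(gene_bed) == 0:
        raise ValueError("gene_bed is empty: distance to nearest gene is undefined")
    fasta = _as_fasta(genome_fasta)
    genes = {c: _merge_intervals(v) for c, v in _sorted_intervals_by_chrom(gene_bed).items()}
    coding = (
        {c: _merge_intervals(v) for c, v in _sorted_intervals_by_chrom(coding_bed).items()}
        if coding_bed is not None and len(coding_bed)
        else {}
    )

    rows = []
    for r in regions:
        if r.chrom not in fasta:
            raise LookupError(f"chromosome {r.chrom!r} absent from the reference FASTA")
        seq = str(fasta[r.chrom][r.start : r.end])
        gchrom = genes.get(r.chrom)
        if gchrom is None:
            raise ValueError(
                f"no gene intervals on chromosome {r.chrom!r}: distance undefined"
            )
        # nearest-gene gap: 0 when overlapping
        starts, ends = gchrom[:, 0], gchrom[:, 1]
        overlap = (starts < r.end) & (ends > r.start)
        if overlap.any():
            dist = 0
        else:
            gaps = np.where(starts >= r.end, starts - r.end, r.start - ends)
            dist = int(gaps[gaps >= 0].min()) if (gaps >= 0).any() else 0
        cchrom = coding.get(r.chrom)
        covered = 0
        if cchrom is not None:
            s = np.maximum(cchrom[:, 0], r.start)
            e = np.minimum(cchrom[:, 1], r.end)
            covered = int(np.clip(e - s, 0, None).sum())
        rows.append(
            {
                "region_id": r.key,
                "chrom": r.chrom,
                "length_bp": r.length,
                "gc_fraction": _gc_fraction(seq),
                "dist_to_gene_bp": dist,
                "coding_overlap_fraction": covered / r.length,
            }
        )
    return pd.DataFrame(rows).set_index("region_id")


# ---------------------------------------------------------------------------
# Matched-control sampling

NUMERIC_COVARIATES = ("length_bp", "gc_fraction", "dist_to_gene_bp", "coding_overlap_fraction")


def _smd(target_vals: np.ndarray, control_vals: np.ndarray) -> float:
    mt, mc = float(np.mean(target_vals)), float(np.mean(control_vals))
    vt = float(np.var(target_vals, ddof=1)) if len(target_vals) > 1 else 0.0
    vc = float(np.var(control_vals, ddof=1)) if len(control_vals) > 1 else 0.0
    pooled = np.sqrt((vt + vc) / 2.0)
    if pooled == 0.0:
        return 0.0 if mt == mc else float("inf")
    return abs(mt - mc) / pooled


def sample_matched_controls(
    targets: RegionSet,
    candidate_pool: RegionSet,
    covariates: pd.DataFrame,
    controls_per_target: int = 1,
    seed: int = 0,
    covariate_columns: Sequence[str] | None = None,
) -> tuple[RegionSet, MatchDiagnostics]:
    """Draw covariate-matched control regions for each target region.

    Matching is greedy nearest-neighbour without replacement on covariates
    z-scored over the candidate pool, within each chromosome stratum.  The
    order in which targets claim their nearest candidates is randomized by
    ``seed``; nearest-neighbour ties are broken by candidate pool order, so
    the procedure is deterministic given the seed.
    """
    if covariate_columns is None:
        covariate_columns = [c for c in NUMERIC_COVARIATES if c in covariates.columns]
    if not covariate_columns:
        raise ValueError("no numeric covariate columns available for matching")
    rng = np.random.default_rng(seed)

    pool_keys = [r.key for r in candidate_pool]
    target_keys = {r.key for r in targets}
    missing = [k for k in pool_keys if k not in covariates.index]
    missing += [r.key for r in targets if r.key not in covariates.index]
    if missing:
        raise KeyError(f"covariates missing for regions: {missing[:5]}")

    # z-scoring uses pool statistics so that distances are comparable across covariates
    pool_cov = covariates.loc[pool_keys, list(covariate_columns)].to_numpy(float)
    mu = pool_cov.mean(axis=0)
    sd = pool_cov.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0

    by_chrom_pool: dict[str, list[int]] = {}
    for i, r in enumerate(candidate_pool):
        if r.key in target_keys:
            continue  # a region cannot serve as its own control
        by_chrom_pool.setdefault(r.chrom, []).append(i)
    by_chrom_targets: dict[str, list[GenomicRegion]] = {}
    for r in targets:
        by_chrom_targets.setdefault(r.chrom, []).append(r)

    selected: list[GenomicRegion] = []
    for chrom, chrom_targets in by_chrom_targets.items():
        cand_idx = by_chrom_pool.get(chrom, [])
        need = controls_per_target * len(chrom_targets)
        if len(cand_idx) < need:
            raise MatchingError(
                f"chromosome {chrom}: need {need} candidates, pool has {len(cand_idx)}"
            )
        cand_z = (pool_cov[cand_idx] - mu) / sd
        available = np.ones(len(cand_idx), dtype=bool)
        order = rng.permutation(len(chrom_targets))
        picks_by_target: dict[int, list[GenomicRegion]] = {}
        for ti in order:
            t = chrom_targets[ti]
            tz = (covariates.loc[t.key, list(covariate_columns)].to_numpy(float) - mu) / sd
            d = np.linalg.norm(cand_z - tz, axis=1)
            d[~available] = np.inf
            # stable argsort => ties broken by candidate pool order
            chosen = np.argsort(d, kind="stable")[:controls_per_target]
            if not np.all(np.isfinite(d[chosen])):
                raise MatchingError(f"chromosome {chrom}: candidate pool exhausted")
            available[chosen] = False
            picks_by_target[ti] = [candidate_pool[cand_idx[j]] for j in chosen]
        for ti in range(len(chrom_targets)):  # emit in target order, not draw order
            selected.extend(picks_by_target[ti])

    matched = RegionSet(
        [GenomicRegion(r.chrom, r.start, r.end, r.region_id, "matched") for r in selected],
        name="matched",
    )
    t_cov = covariates.loc[[r.key for r in targets], list(covariate_columns)].to_numpy(float)
    c_cov = covariates.loc[[r.key for r in selected], list(covariate_columns)].to_numpy(float)
    smd = {
        col: _smd(t_cov[:, j], c_cov[:, j]) for j, col in enumerate(covariate_columns)
    }
    diag = MatchDiagnostics(smd=smd, n_matched=len(selected), n_requested=controls_per_target * len(targets))
    return matched, diag


# ---------------------------------------------------------------------------
# Permutation enrichment


def _count_overlapping(query: RegionSet, targets: Iterable[GenomicRegion]) -> int:
    trees: dict[str, IntervalTree] = {}
    for r in targets:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    n = 0
    for q in query:
        tree = trees.get(q.chrom)
        if tree is not None and tree.overlap(q.start, q.end):
            n += 1
    return n


def permutation_enrichment(
    query: RegionSet,
    targets: RegionSet,
    candidate_pool: RegionSet,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test for enrichment of ``query`` regions within ``targets``.

    The observed statistic is the number of query regions overlapping at
    least one target.  The null re-draws, for each permutation, a control
    set of the same per-chromosome composition as the targets from the
    candidate pool (stratified random sampling without replacement within
    chromosome), and recounts.  The empirical p-value uses the add-one form
    ``(r + 1) / (n_perm + 1)`` and is therefore never exactly 0.
    """
    if len(query) == 0 or len(targets) == 0:
        raise ValueError("query and targets must be nonempty")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    observed = _count_overlapping(query, targets)

    pool_by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in candidate_pool:
        pool_by_chrom.setdefault(r.chrom, []).append(r)
    need_by_chrom: dict[str, int] = {}
    for r in targets:
        need_by_chrom[r.chrom] = need_by_chrom.get(r.chrom, 0) + 1
    for chrom, need in need_by_chrom.items():
        if len(pool_by_chrom.get(chrom, [])) < need:
            raise MatchingError(
                f"chromosome {chrom}: need {need} pool regions per permutation, "
                f"have {len(pool_by_chrom.get(chrom, []))}"
            )

    null = np.empty(n_perm, dtype=np.int64)
    for b in range(n_perm):
        drawn: list[GenomicRegion] = []
        for chrom, need in need_by_chrom.items():
            cands = pool_by_chrom[chrom]
            idx = rng.choice(len(cands), size=need, replace=False)
            drawn.extend(cands[i] for i in idx)
        null[b] = _count_overlapping(query, drawn)
    r = int(np.sum(null >= observed))
    return EnrichmentResult(
        observed_overlap=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        empirical_p=(r + 1) / (n_perm + 1),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Variant partition assignment


def assign_variants_to_partitions(
    variant_chroms: Sequence[str],
    variant_positions: Sequence[int],
    annotation_set: RegionSet,
    matched_set: RegionSet,
) -> np.ndarray:
    """Label each variant as annotation / matched / background.

    Positions are 1-based (VCF); intervals are 0-based half-open (BED).  A
    position ``p`` overlaps ``[s, e)`` iff ``s < p <= e``.  Labels are
    mutually exclusive with precedence annotation > matched > background,
    and exhaustive (background is the catch-all).
    """
    chroms = np.asarray(variant_chroms)
    positions = np.asarray(variant_positions, dtype=np.int64)
    if chroms.shape != positions.shape:
        raise ValueError("variant_chroms and variant_positions must have the same length")
    labels = np.full(len(positions), "background", dtype=object)
    for i in range(len(positions)):
        c, p = chroms[i], int(positions[i])
        if annotation_set.overlaps_position(c, p):
            labels[i] = "annotation"
        elif matched_set.overlaps_position(c, p):
            labels[i] = "matched"
    return labels
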