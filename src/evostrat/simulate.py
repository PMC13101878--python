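"""Synthetic-data generation for every analysis in the package.

The cohort generator emulates the statistical structure of a deeply
phenotyped language cohort analysed with partitioned polygenic scores:

* diploid genotypes at Hardy-Weinberg equilibrium inside equicorrelated LD
  blocks (a latent-Gaussian threshold model);
* a quantitative trait whose heritability is concentrated in an annotation
  partition (default h2 = 0.04) and a background partition (default 0.037),
  mirroring the published variance scale for annotation vs genome-wide
  scores;
* GWAS summary statistics estimated in an independent simulated discovery
  sample (so harmonization and clumping are exercised on realistically noisy
  weights, including allele-orientation flips);
* rare variants with known ancestral alleles, enriched for
  ancestral-reversions near the annotation regions, plus a binary disorder
  phenotype driven by the annotation reversion burden (default log-odds 0.16
  per burden SD);
* a birth-death species tree with Brownian-motion traits: a species
  similarity score, a binary vocal-learning-style trait thresholded to an
  exact positive count (default 49 of 170), and continuous brain-mass-style
  traits.

A single integer seed drives a named hierarchy of substreams so components
can be varied independently; identical configs produce byte-identical
outputs.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicRegion, RegionSet, write_bed
from .pgs import GenotypeMatrix, write_sumstats

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "SimulatedPhylo",
    "simulate_cohort",
    "resample_phenotype",
    "simulate_ancient_panel",
    "simulate_tree_and_traits",
    "simulate_alignments",
    "simulate_region_panel",
]

_STREAMS = (
    "genotypes",
    "effects",
    "noise",
    "discovery",
    "alleles",
    "rare",
    "disorder",
    "tree",
    "traits",
    "alignments",
    "regions",
)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


@dataclass
class SimConfig:
    """Ground-truth parameters for the synthetic cohort and species panel."""

    seed: int
    # cohort
    n_individuals: int = 2000
    n_variants: int = 600
    annotation_fraction: float = 0.1  # fraction of LD blocks in the annotation partition
    matched_fraction: float = 0.1
    h2_annot: float = 0.04
    h2_background: float = 0.037
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 10
    ld_block_r: float = 0.2
    n_chromosomes: int = 2
    block_spacing_bp: int = 300_000
    within_block_spacing_bp: int = 1_000
    discovery_n: int = 20_000
    # rare variants / reversions
    n_rare_variants: int = 200
    rare_maf_range: tuple = (0.0005, 0.008)
    reversion_rate_annotation: float = 0.5
    reversion_rate_other: float = 0.2
    unpolarized_fraction: float = 0.05
    reversion_window_bp: int = 10_000
    disorder_burden_beta: float = 0.16  # log-odds per SD of annotation reversion burden
    disorder_prevalence: float = 0.15
    # ancient panel
    n_ancient: int = 3244
    n_archaic: int = 10
    n_modern: int = 503
    age_range_years_bp: tuple = (150.0, 18_775.0)
    temporal_s_true: float = 0.088  # standardized-score drift per 10 ka toward the present
    archaic_z_shift: float = 0.91  # archaic score elevation on the modern SD scale
    # species panel
    n_species: int = 170
    n_positive_species: int | None = None  # default: the 49/170 study proportion
    phylo_logistic_beta: float = 1.41
    pgls_beta: float = 0.42
    weight_ratio_beta: float = 0.44
    birth_rate: float = 1.0
    death_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.h2_annot < 0 or self.h2_background < 0:
            raise ValueError("heritabilities must be >= 0")
        if self.h2_annot + self.h2_background > 1:
            raise ValueError(
                f"infeasible heritability split: {self.h2_annot} + {self.h2_background} > 1"
            )
        if not (0 <= self.ld_block_r < 1):
            raise ValueError("ld_block_r must lie in [0, 1)")
        if self.n_species < 4:
            raise ValueError("tree size must be >= 4")


@dataclass
class SimulatedCohort:
    """In-memory synthetic cohort; ``write`` materializes standard files."""

    config: SimConfig
    samples: list[str]
    variants: pd.DataFrame  # variant_id chrom pos ref alt maf partition is_rare ancestral
    genotypes: GenotypeMatrix
    sumstats: pd.DataFrame
    phenotype: pd.DataFrame  # individual_id, trait, disorder
    ancestral: pd.DataFrame  # chrom, pos, ancestral
    annotation_regions: RegionSet
    matched_regions: RegionSet
    genetic_values: dict = field(repr=False, default_factory=dict)

    @property
    def common_ids(self) -> list[str]:
        return list(self.variants.loc[~self.variants["is_rare"], "variant_id"])

    @property
    def partition_labels(self) -> dict[str, str]:
        return dict(zip(self.variants["variant_id"], self.variants["partition"]))

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "genotypes.vcf",
            "annotation_bed": outdir / "annotation.bed",
            "matched_bed": outdir / "matched.bed",
            "sumstats": outdir / "sumstats.tsv",
            "phenotype": outdir / "phenotype.tsv",
            "ancestral": outdir / "ancestral.tsv",
        }
        self.genotypes.write_vcf(paths["vcf"])
        write_bed(self.annotation_regions, paths["annotation_bed"])
        write_bed(self.matched_regions, paths["matched_bed"])
        write_sumstats(self.sumstats, paths["sumstats"])
        self.phenotype.to_csv(paths["phenotype"], sep="\t", index=False)
        self.ancestral.to_csv(paths["ancestral"], sep="\t", index=False)
        return paths


def _draw_dosages(
    rng: np.random.Generator,
    mafs: np.ndarray,
    block_id: np.ndarray,
    block_r: float,
    n: int,
) -> np.ndarray:
    """HWE dosages with equicorrelated latent haplotypes within LD blocks."""
    m = len(mafs)
    thresh = stats.norm.ppf(mafs).astype(np.float32)  # allele carried when latent < threshold
    n_blocks = int(block_id.max()) + 1
    dosage = np.zeros((n, m), dtype=np.float32)
    sqrt_r = np.float32(np.sqrt(block_r))
    sqrt_1mr = np.float32(np.sqrt(1.0 - block_r))
    for _hap in range(2):
        shared = rng.standard_normal((n, n_blocks), dtype=np.float32)
        z = rng.standard_normal((n, m), dtype=np.float32)
        z *= sqrt_1mr
        z += sqrt_r * shared[:, block_id]
        dosage += z < thresh
    return dosage.astype(np.float64)


_ALLELE_PAIRS = [  # ref, alt — strand-unambiguous pairs only
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]


def _marginal_gwas(dosages: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Vectorized per-variant OLS: beta, se, p, eaf."""
    n = len(y)
    yc = y - y.mean()
    mean_g = dosages.mean(axis=0)
    var_g = (dosages * dosages).mean(axis=0) - mean_g**2
    cov_gy = (dosages.T @ yc) / n  # yc is centered, so no mean cross-term
    safe = var_g > 0
    beta = np.zeros(dosages.shape[1])
    beta[safe] = cov_gy[safe] / var_g[safe]
    resid_var = np.clip(yc.var() - beta**2 * var_g, 1e-12, None)
    se = np.full_like(beta, np.inf)
    se[safe] = np.sqrt(resid_var[safe] / (n * var_g[safe]))
    t = np.where(se > 0, beta / se, 0.0)
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df=n - 2), 1e-300, 1.0)
    return pd.DataFrame({"beta": beta, "se": se, "p": p, "eaf": dosages.mean(axis=0) / 2.0})


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort (see module docstring)."""
    rngs = _rngs(config.seed)
    cfg = config

    # --- variant layout: whole LD blocks are assigned to partitions so the
    # partition structure is not diluted by within-block LD leakage
    n_blocks = int(np.ceil(cfg.n_variants / cfg.ld_block_size))
    block_labels = np.array(["background"] * n_blocks, dtype=object)
    n_annot_blocks = max(1, round(cfg.annotation_fraction * n_blocks))
    n_matched_blocks = max(1, round(cfg.matched_fraction * n_blocks))
    perm = rngs["regions"].permutation(n_blocks)
    block_labels[perm[:n_annot_blocks]] = "annotation"
    block_labels[perm[n_annot_blocks : n_annot_blocks + n_matched_blocks]] = "matched"

    block_id = np.arange(cfg.n_variants) // cfg.ld_block_size
    partition = block_labels[block_id]
    chrom_of_block = np.array(
        [f"chr{(b % cfg.n_chromosomes) + 1}" for b in range(n_blocks)], dtype=object
    )
    block_rank_on_chrom = np.zeros(n_blocks, dtype=int)
    seen: dict[str, int] = {}
    for b in range(n_blocks):
        c = chrom_of_block[b]
        block_rank_on_chrom[b] = seen.get(c, 0)
        seen[c] = block_rank_on_chrom[b] + 1
    chroms = chrom_of_block[block_id]
    within = np.arange(cfg.n_variants) % cfg.ld_block_size
    positions = (
        1_000_000
        + block_rank_on_chrom[block_id] * cfg.block_spacing_bp
        + within * cfg.within_block_spacing_bp
        + 1
    )

    mafs = rngs["genotypes"].uniform(*cfg.maf_range, size=cfg.n_variants)
    pair_idx = rngs["alleles"].integers(0, len(_ALLELE_PAIRS), size=cfg.n_variants)
    refs = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    alts = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    vids = np.array([f"var{i:05d}" for i in range(cfg.n_variants)], dtype=object)

    dosages = _draw_dosages(
        rngs["genotypes"], mafs, block_id, cfg.ld_block_r, cfg.n_individuals
    )

    # --- true effects, variance-scaled per partition
    beta_true = np.zeros(cfg.n_variants)
    genetic = {}
    for part, h2 in (("annotation", cfg.h2_annot), ("background", cfg.h2_background)):
        idx = np.flatnonzero(partition == part)
        g_part = np.zeros(cfg.n_individuals)
        if h2 > 0 and len(idx):
            raw = rngs["effects"].standard_normal(len(idx))
            centered = dosages[:, idx] - dosages[:, idx].mean(axis=0)
            g_raw = centered @ raw
            scale = np.sqrt(h2) / g_raw.std()
            beta_true[idx] = raw * scale
            g_part = g_raw * scale
        genetic[part] = g_part
    genetic_total = genetic["annotation"] + genetic["background"]
    noise_sd = np.sqrt(max(1.0 - cfg.h2_annot - cfg.h2_background, 0.0))
    trait = genetic_total + rngs["noise"].standard_normal(cfg.n_individuals) * noise_sd

    # --- discovery-sample GWAS on an independent draw from the same LD structure
    disc_dos = _draw_dosages(
        rngs["discovery"], mafs, block_id, cfg.ld_block_r, cfg.discovery_n
    )
    disc_genetic = (disc_dos - disc_dos.mean(axis=0)) @ beta_true
    disc_y = disc_genetic + rngs["discovery"].standard_normal(cfg.discovery_n) * noise_sd
    gwas = _marginal_gwas(disc_dos, disc_y)
    flip = rngs["alleles"].random(cfg.n_variants) < 0.5  # half reported on the other allele
    sumstats = pd.DataFrame(
        {
            "variant_id": vids,
            "chrom": chroms,
            "pos": positions,
            "effect_allele": np.where(flip, refs, alts),
            "other_allele": np.where(flip, alts, refs),
            "beta": np.where(flip, -gwas["beta"], gwas["beta"]),
            "p": gwas["p"],
            "eaf": np.where(flip, 1.0 - gwas["eaf"], gwas["eaf"]),
        }
    )

    # --- annotation / matched regions covering their blocks
    def _block_regions(label: str) -> RegionSet:
        regions = []
        for b in np.flatnonzero(block_labels == label):
            cols = np.flatnonzero(block_id == b)
            start = int(positions[cols].min()) - 1 - 200
            end = int(positions[cols].max()) + 200
            regions.append(
                GenomicRegion(chrom_of_block[b], max(0, start), end, f"{label}_{b}", label)
            )
        return RegionSet(regions, name=label)

    annotation_regions = _block_regions("annotation")
    matched_regions = _block_regions("matched")

    # --- rare variants with ancestral-allele structure
    rare_rng = rngs["rare"]
    n_rare = cfg.n_rare_variants
    rare_class = rare_rng.choice(
        ["annotation", "matched", "background"], size=n_rare, p=[1 / 3, 1 / 3, 1 / 3]
    )
    rare_chrom = np.empty(n_rare, dtype=object)
    rare_pos = np.empty(n_rare, dtype=np.int64)
    max_pos_by_chrom: dict[str, int] = {}
    for c, p in zip(chroms, positions):
        max_pos_by_chrom[c] = max(max_pos_by_chrom.get(c, 0), int(p))
    for i in range(n_rare):
        cls = rare_class[i]
        if cls in ("annotation", "matched"):
            pool = annotation_regions if cls == "annotation" else matched_regions
            r = pool[int(rare_rng.integers(0, len(pool)))]
            offset = int(rare_rng.integers(-cfg.reversion_window_bp // 2, cfg.reversion_window_bp // 2))
            rare_chrom[i] = r.chrom
            pos = max(2, r.start + r.length // 2 + offset)
            # common variants sit at odd positions; keep rare ones even so the
            # two never collide at a (chrom, pos) key
            rare_pos[i] = pos + (pos % 2)
        else:
            c = f"chr{int(rare_rng.integers(0, cfg.n_chromosomes)) + 1}"
            rare_chrom[i] = c
            pos = max_pos_by_chrom[c] + 200_000 + int(rare_rng.integers(0, 100_000))
            rare_pos[i] = pos + (pos % 2)
    rare_maf = rare_rng.uniform(*cfg.rare_maf_range, size=n_rare)
    rare_dos = rare_rng.binomial(2, rare_maf, size=(cfg.n_individuals, n_rare)).astype(float)
    rare_pair = rare_rng.integers(0, len(_ALLELE_PAIRS), size=n_rare)
    rare_ref = np.array([_ALLELE_PAIRS[i][0] for i in rare_pair], dtype=object)
    rare_alt = np.array([_ALLELE_PAIRS[i][1] for i in rare_pair], dtype=object)
    rev_prob = np.where(
        rare_class == "annotation", cfg.reversion_rate_annotation, cfg.reversion_rate_other
    )
    is_rev = rare_rng.random(n_rare) < rev_prob
    unpolarized = rare_rng.random(n_rare) < cfg.unpolarized_fraction
    rare_anc = np.where(is_rev, rare_alt, rare_ref)
    rare_anc = np.where(unpolarized, ".", rare_anc)
    rare_ids = np.array([f"rare{i:05d}" for i in range(n_rare)], dtype=object)

    # --- binary disorder driven by the annotation reversion burden
    rev_near_annot = np.zeros(n_rare, dtype=bool)
    trees = annotation_regions.trees()
    for i in range(n_rare):
        if not (is_rev[i] and not unpolarized[i]):
            continue
        tree = trees.get(rare_chrom[i])
        if tree is None:
            continue
        lo = int(rare_pos[i]) - 1
        # 10-kb flank rule on the 1-based position
        for iv in tree:
            if iv.begin - cfg.reversion_window_bp <= lo < iv.end + cfg.reversion_window_bp:
                rev_near_annot[i] = True
                break
    burden = rare_dos[:, rev_near_annot].sum(axis=1)
    z_burden = (burden - burden.mean()) / burden.std() if burden.std() > 0 else burden * 0.0
    logit0 = np.log(cfg.disorder_prevalence / (1 - cfg.disorder_prevalence))
    p_dis = 1.0 / (1.0 + np.exp(-(logit0 + cfg.disorder_burden_beta * z_burden)))
    disorder = (rngs["disorder"].random(cfg.n_individuals) < p_dis).astype(int)

    # --- assemble
    samples = [f"ind{i:05d}" for i in range(cfg.n_individuals)]
    variants = pd.DataFrame(
        {
            "variant_id": np.concatenate([vids, rare_ids]),
            "chrom": np.concatenate([chroms, rare_chrom]),
            "pos": np.concatenate([positions, rare_pos]).astype(np.int64),
            "ref": np.concatenate([refs, rare_ref]),
            "alt": np.concatenate([alts, rare_alt]),
            "maf": np.concatenate([mafs, rare_maf]),
            "partition": np.concatenate([partition, rare_class]),
            "is_rare": np.concatenate(
                [np.zeros(cfg.n_variants, dtype=bool), np.ones(n_rare, dtype=bool)]
            ),
            "ancestral": np.concatenate([refs, rare_anc]),  # common variants: derived alt
        }
    )
    genotypes = GenotypeMatrix(
        samples=samples,
        variants=variants[["variant_id", "chrom", "pos", "ref", "alt"]],
        dosages=np.concatenate([dosages, rare_dos], axis=1),
    )
    phenotype = pd.DataFrame(
        {"individual_id": samples, "trait": trait, "disorder": disorder}
    )
    ancestral = variants[["chrom", "pos", "ancestral"]].copy()
    return SimulatedCohort(
        config=cfg,
        samples=samples,
        variants=variants,
        genotypes=genotypes,
        sumstats=sumstats,
        phenotype=phenotype,
        ancestral=ancestral,
        annotation_regions=annotation_regions,
        matched_regions=matched_regions,
        genetic_values={**genetic, "total": genetic_total, "noise_sd": noise_sd},
    )


def resample_phenotype(cohort: SimulatedCohort, seed: int) -> pd.Series:
    """Redraw the quantitative trait keeping genotypes and genetic values fixed.

    Useful for repeated null/power refits of the same simulated cohort.
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(cohort.samples)) * cohort.genetic_values["noise_sd"]
    return pd.Series(
        cohort.genetic_values["total"] + noise, index=cohort.samples, name="trait"
    )


def simulate_ancient_panel(config: SimConfig) -> pd.DataFrame:
    """Time-stamped score panel: ancient, archaic, and modern samples.

    Ancient scores drift toward the present at ``temporal_s_true`` SD per
    10 ka on top of unit noise; archaic samples sit ``archaic_z_shift``
    modern SDs above the modern mean.  Genotype coverage decays with age,
    giving a realistic covariate for trajectory fits.  Columns: sample_id,
    group (ancient | archaic | modern), age_years_bp, score, coverage.
    """
    rngs = _rngs(config.seed)
    rng = rngs["traits"]
    lo, hi = config.age_range_years_bp
    ages = rng.uniform(lo, hi, size=config.n_ancient)
    scores = config.temporal_s_true * (-ages / 10_000.0) + rng.standard_normal(config.n_ancient)
    coverage = np.clip(1.0 - 0.3 * (ages - lo) / (hi - lo) + rng.normal(0, 0.05, config.n_ancient), 0.05, 1.0)
    modern = rng.standard_normal(config.n_modern)
    archaic = modern.mean() + modern.std(ddof=1) * (
        config.archaic_z_shift + 0.3 * rng.standard_normal(config.n_archaic)
    )
    frames = [
        pd.DataFrame(
            {
                "sample_id": [f"anc{i:05d}" for i in range(config.n_ancient)],
                "group": "ancient",
                "age_years_bp": ages,
                "score": scores,
                "coverage": coverage,
            }
        ),
        pd.DataFrame(
            {
                "sample_id": [f"arch{i:02d}" for i in range(config.n_archaic)],
                "group": "archaic",
                "age_years_bp": rng.uniform(40_000, 120_000, config.n_archaic),
                "score": archaic,
                "coverage": rng.uniform(0.3, 0.9, config.n_archaic),
            }
        ),
        pd.DataFrame(
            {
                "sample_id": [f"mod{i:04d}" for i in range(config.n_modern)],
                "group": "modern",
                "age_years_bp": 0.0,
                "score": modern,
                "coverage": 1.0,
            }
        ),
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Species tree, traits, and alignments


@dataclass
class SimulatedPhylo:
    """Species tree with similarity scores and tree-structured traits."""

    config: SimConfig
    tree: object  # dendropy.Tree
    newick: str
    traits: pd.DataFrame  # species, similarity, vocal_learner, brain_mass, weight_ratio

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"tree": outdir / "species.nwk", "traits": outdir / "traits.tsv"}
        paths["tree"].write_text(self.newick + "\n")
        self.traits.to_csv(paths["traits"], sep="\t", index=False)
        return paths


def _brownian_leaf_values(tree, rng: np.random.Generator) -> dict[str, float]:
    """Simulate Brownian motion down the tree; returns leaf-name -> value."""
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        parent_val = values.get(id(node.parent_node), 0.0)
        bl = node.edge.length or 0.0
        values[id(node)] = parent_val + rng.standard_normal() * np.sqrt(max(bl, 0.0))
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


def simulate_tree_and_traits(config: SimConfig) -> SimulatedPhylo:
    """Birth-death tree with BM traits and an exact positive-class count.

    The binary trait thresholds a Brownian latent variable plus
    ``phylo_logistic_beta * similarity`` at the value giving exactly
    ``n_positive_species`` positives; continuous traits add
    ``pgls_beta`` / ``weight_ratio_beta`` times the similarity score to
    independent Brownian components.
    """
    import dendropy
    from dendropy.simulate import treesim

    rngs = _rngs(config.seed)
    pyrng = _pyrandom.Random(int(rngs["tree"].integers(0, 2**31 - 1)))
    tree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=config.death_rate,
        num_extant_tips=config.n_species,
        rng=pyrng,
        repeat_until_success=True,
    )
    # relabel deterministically and scale tree height to 1
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i:03d}"
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    height = max(depths)
    if height <= 0:
        raise ValueError("degenerate tree: zero total branch length")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / height

    rng = rngs["traits"]
    sim_raw = _brownian_leaf_values(tree, rng)
    species = sorted(sim_raw)
    sim = np.array([sim_raw[s] for s in species])
    sim = (sim - sim.mean()) / sim.std()

    n_pos = config.n_positive_species
    if n_pos is None:
        n_pos = max(1, round(config.n_species * 49 / 170))
    if not (0 < n_pos < config.n_species):
        raise ValueError("n_positive_species must lie strictly between 0 and n_species")
    latent_map = _brownian_leaf_values(tree, rng)
    latent = np.array([latent_map[s] for s in species])
    latent = latent + config.phylo_logistic_beta * sim
    cutoff = np.sort(latent)[-n_pos]
    vocal = (latent >= cutoff).astype(int)

    bm_brain = _brownian_leaf_values(tree, rng)
    bm_weight = _brownian_leaf_values(tree, rng)
    brain = np.array([bm_brain[s] for s in species]) + config.pgls_beta * sim
    weight = np.array([bm_weight[s] for s in species]) + config.weight_ratio_beta * sim

    traits = pd.DataFrame(
        {
            "species": species,
            "similarity": sim,
            "vocal_learner": vocal,
            "brain_mass": brain,
            "weight_ratio": weight,
        }
    )
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return SimulatedPhylo(config=config, tree=tree, newick=newick, traits=traits)


def simulate_alignments(
    seed: int,
    species_scores: Mapping[str, float],
    n_annotation: int = 8,
    n_background: int = 15,
    length: int = 120,
    background_identity: float = 0.85,
    identity_per_score: float = 0.02,
) -> tuple[dict, list[str], list[str]]:
    """Pairwise human<->species alignments whose annotation identity tracks a score.

    Background regions diverge at ``1 - background_identity`` per base for
    every species; annotation regions for a species with similarity score s
    use identity ``background_identity + identity_per_score * s`` (clipped).
    Returns (alignments, annotation_ids, background_ids) in the layout
    consumed by :func:`evostrat.phylo.similarity_scores`.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    ann_ids = [f"ann{i:03d}" for i in range(n_annotation)]
    bg_ids = [f"bg{i:03d}" for i in range(n_background)]
    human = {
        rid: "".join(rng.choice(bases, size=length)) for rid in ann_ids + bg_ids
    }
    alignments: dict[str, dict[str, tuple[str, str]]] = {}
    for sp, score in species_scores.items():
        ann_ident = float(np.clip(background_identity + identity_per_score * score, 0.5, 1.0))
        regions = {}
        for rid in ann_ids + bg_ids:
            ident = ann_ident if rid in ann_ids else background_identity
            h = human[rid]
            mutate = rng.random(length) >= ident
            sp_seq = np.array(list(h))
            n_mut = int(mutate.sum())
            if n_mut:
                sp_seq[mutate] = rng.choice(bases, size=n_mut)
            regions[rid] = (h, "".join(sp_seq))
        alignments[sp] = regions
    return alignments, ann_ids, bg_ids


# ---------------------------------------------------------------------------
# Small genome + region panel (for covariate matching and enrichment)


def simulate_region_panel(
    seed: int,
    n_targets: int = 20,
    pool_per_target: int = 30,
    n_chromosomes: int = 3,
    chrom_length: int = 400_000,
    region_length: tuple = (500, 2000),
    outdir: str | Path | None = None,
):
    """A small synthetic genome with target regions, a candidate pool, and
    gene/coding annotation, for exercising covariate matching end to end.

    Returns ``(targets, pool, genes, coding, fasta_path_or_seqs)``; when
    ``outdir`` is given, a FASTA and BED files are written there and the
    FASTA path is returned in the last slot.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
    seqs = {c: "".join(rng.choice(bases, size=chrom_length, p=[0.3, 0.2, 0.2, 0.3])) for c in chroms}

    def _draw_regions(n: int, label: str, tag: str) -> RegionSet:
        regions = []
        for i in range(n):
            c = chroms[i % n_chromosomes]
            ln = int(rng.integers(*region_length))
            start = int(rng.integers(0, chrom_length - ln))
            regions.append(GenomicRegion(c, start, start + ln, f"{tag}{i:04d}", label))
        return RegionSet(regions, name=tag)

    targets = _draw_regions(n_targets, "annotation", "tgt")
    pool = _draw_regions(n_targets * pool_per_target, "other", "pool")
    genes = _draw_regions(max(10, n_targets), "other", "gene")
    coding = RegionSet(
        [
            GenomicRegion(g.chrom, g.start, g.start + max(100, g.length // 3), f"cds_{g.region_id}")
            for g in genes
        ],
        name="coding",
    )
    if outdir is None:
        return targets, pool, genes, coding, seqs
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for c in chroms:
            fh.write(f">{c}\n")
            s = seqs[c]
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")
    write_bed(targets, outdir / "targets.bed")
    write_bed(pool, outdir / "pool.bed")
    write_bed(genes, outdir / "genes.bed")
    write_bed(coding, outdir / "coding.bed")
    return targets, pool, genes, coding, fasta
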