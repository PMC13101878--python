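import numpy as np
import pytest

from evostrat.espgs import fit_espgs
from evostrat.intervals import assign_variants_to_partitions
from evostrat.pgs import harmonize, ld_clump, partition_scores
from evostrat.simulate import SimConfig, simulate_cohort, simulate_region_panel


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared across read-only tests."""
    cfg = SimConfig(
        seed=11,
        n_individuals=400,
        n_variants=200,
        discovery_n=4000,
        n_rare_variants=100,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_files(small_cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    return small_cohort.write(outdir)


@pytest.fixture(scope="session")
def region_panel(tmp_path_factory):
    """Targets, candidate pool, gene/coding BEDs and a small FASTA on disk."""
    outdir = tmp_path_factory.mktemp("panel")
    targets, pool, genes, coding, fasta = simulate_region_panel(seed=7, outdir=outdir)
    return {
        "targets": targets,
        "pool": pool,
        "genes": genes,
        "coding": coding,
        "fasta": fasta,
        "dir": outdir,
    }


def run_espgs_pipeline(cohort, phenotype=None, family="linear"):
    """Harmonize -> clump -> partition -> fit, the canonical analysis chain."""
    aligned, _ = harmonize(cohort.sumstats, cohort.genotypes.variants)
    kept = ld_clump(aligned, cohort.genotypes)
    sub = aligned.set_index("variant_id").loc[kept]
    labels = dict(
        zip(
            kept,
            assign_variants_to_partitions(
                sub["chrom"], sub["pos"], cohort.annotation_regions, cohort.matched_regions
            ),
        )
    )
    scores = partition_scores(cohort.genotypes, aligned, kept, labels)
    if phenotype is None:
        phenotype = cohort.phenotype["trait"].to_numpy()
    return fit_espgs(np.asarray(phenotype, dtype=float), scores, family=family), scores
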