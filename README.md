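# evostrat

Evolutionary stratified polygenic scores (ES-PGS) and companion
evolutionary-genomics analyses, as a tested Python library with a thin
command-line interface.

## The problem

Complex traits such as language ability are highly polygenic. A natural
evolutionary question is *when* the relevant regulatory variation arose:
do variants inside regions that changed on a particular lineage (say,
fast-evolving hominin elements) predict the trait better than the rest of
the genome — and better than control regions with the same mundane genomic
properties? `evostrat` is for statistical geneticists who want to answer
that question with individual-level data, and to run the surrounding
analyses that triangulate it: ancestral-allele reversion burdens,
transcription-factor motif statistics, balancing-selection diagnostics,
ancient-sample score trajectories, and phylogenetically controlled
cross-species regression.

## The core model

For individual *i* with dosages *g<sub>ij</sub>* and alt-aligned GWAS weights
*β<sub>j</sub>* over a clumped SNP set, the genome-wide score
PGS<sub>i</sub> = Σ<sub>j</sub> g<sub>ij</sub>β<sub>j</sub> is partitioned
by location into **annotation**, covariate-**matched** control, and
**background** components (the three sum exactly to the genome-wide score),
and the phenotype is regressed jointly on the standardized partition scores:

&nbsp;&nbsp;&nbsp;&nbsp;*y* ~ β<sub>bg</sub>·PGS<sub>bg</sub> + β<sub>m</sub>·PGS<sub>m</sub> + β<sub>a</sub>·PGS<sub>a</sub> + covariates

β<sub>a</sub> is the headline coefficient; the matched term guarantees it is
not explained by region length, GC, gene proximity, or coding overlap. A
nested model comparison (partial F or likelihood-ratio χ²) gives the
model-improvement p-value, ΔR² the added explained variance, and
ρ = (ΔR²<sub>a</sub>/n<sub>a</sub>) / (R²<sub>ref</sub>/n<sub>ref</sub>) the
per-SNP predictive-power ratio. Full model documentation is in
[docs/methods.md](docs/methods.md).

## Worked example

Everything below runs on synthetic data produced by the package's own
generator — no external files needed.

```bash
evostrat simulate --seed 7 --out demo/sim --n-individuals 400 --n-variants 200
evostrat score  --seed 7 --out demo/score \
    --vcf demo/sim/genotypes.vcf --sumstats demo/sim/sumstats.tsv \
    --annotation-bed demo/sim/annotation.bed --matched-bed demo/sim/matched.bed
evostrat espgs  --seed 7 --out demo/espgs \
    --scores demo/score/scores.tsv --phenotype demo/sim/phenotype.tsv
```

which prints:

```
simulated cohort (n=400) and tree (n=170) -> demo/sim
scored 400 individuals; SNPs per partition: {'background': 160, 'matched': 20, 'annotation': 20}
annotation beta = 0.1516 (p = 0.00207); delta R2 = 0.0228; improvement p = 0.00207
```

Reading the output: the cohort was simulated with 4% of trait variance in
the annotation partition and 3.7% elsewhere. The annotation score predicts
the trait at 0.15 SD per SD of score (p ≈ 0.002) *on top of* the background
and matched-control scores, adding ΔR² ≈ 0.023 of explained variance at this
small n — the signature the method is built to detect. Every run also writes
a `manifest.json` recording parameters, package version, and input hashes.

The same library surface is importable directly:

```python
from evostrat.simulate import SimConfig, simulate_cohort
from evostrat.pgs import harmonize, ld_clump, partition_scores
from evostrat.espgs import fit_espgs

cohort = simulate_cohort(SimConfig(seed=1))
weights, _ = harmonize(cohort.sumstats, cohort.genotypes.variants)
kept = ld_clump(weights, cohort.genotypes)
scores = partition_scores(cohort.genotypes, weights, kept, cohort.partition_labels)
result = fit_espgs(cohort.phenotype["trait"], scores)
print(result.annotation)
```

Other subcommands: `match-controls` (covariate-matched control regions with
SMD diagnostics), `clump`, `reversions` (ancestral-reversion burdens and
association), `motifs` (York regression and TF-family enrichment over
per-motif statistics), `popgen` (SFS log2 ratios, heterozygosity,
inbreeding F), `trajectory` (score drift over ancient sample ages), and
`phylo` (PGLS / phylogenetic logistic regression).

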