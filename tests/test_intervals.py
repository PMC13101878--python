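"""Interval model, BED I/O, covariates, matching, and enrichment."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from evostrat.intervals import (
    BedParseError,
    GenomicRegion,
    MatchingError,
    RegionSet,
    assign_variants_to_partitions,
    compute_region_covariates,
    permutation_enrichment,
    read_bed,
    sample_matched_controls,
    write_bed,
)


class TestRegionModel:
    def test_validation(self):
        r = GenomicRegion("chr1", 10, 20)
        assert r.length == 10
        with pytest.raises(ValueError):
            GenomicRegion("chr1", 20, 10)
        with pytest.raises(ValueError):
            GenomicRegion("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicRegion("", 0, 10)

    def test_position_overlap_convention(self):
        # 1-based position p overlaps [s, e) iff s < p <= e
        r = GenomicRegion("chr1", 10, 20)
        assert not r.contains_position(10)
        assert r.contains_position(11)
        assert r.contains_position(20)
        assert not r.contains_position(21)


class TestBedIO:
    def test_minimal_and_errors(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\n")
        rs = read_bed(p)
        assert len(rs) == 1 and rs[0] == GenomicRegion("chr1", 10, 20)

        p.write_text("chr1\t20\t10\n")
        with pytest.raises(BedParseError, match=":1:"):
            read_bed(p)
        p.write_text("chr1\t10\t20\nchr1 5 6\n")
        with pytest.raises(BedParseError, match=":2:"):
            read_bed(p)

    def test_roundtrip_identity(self, tmp_path):
        regions = RegionSet(
            [
                GenomicRegion("chr1", 10, 20, "r1"),
                GenomicRegion("chr2", 0, 5, "r2"),
                GenomicRegion("chr1", 100, 250, "r3"),
            ]
        )
        p1, p2 = tmp_path / "r1.bed", tmp_path / "r2.bed"
        write_bed(regions, p1)
        again = read_bed(p1)
        assert [(r.chrom, r.start, r.end, r.key) for r in again] == [
            (r.chrom, r.start, r.end, r.key) for r in regions
        ]
        write_bed(again, p2)
        assert p1.read_text() == p2.read_text()


class TestCovariates:
    def test_gc_fraction(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\nGGCCACGTNNAA\n")
        regions = RegionSet(
            [GenomicRegion("chr1", 0, 4, "gc1"), GenomicRegion("chr1", 4, 8, "gc2"),
             GenomicRegion("chr1", 6, 12, "gcn")]
        )
        genes = RegionSet([GenomicRegion("chr1", 0, 2, "g")])
        cov = compute_region_covariates(regions, fa, genes)
        assert cov.loc["gc1", "gc_fraction"] == 1.0
        assert cov.loc["gc2", "gc_fraction"] == 0.5
        # N bases drop out of the denominator: GT--AA -> 1 GC of 4 unambiguous
        assert cov.loc["gcn", "gc_fraction"] == pytest.approx(0.25)

    def test_gene_distance_and_coding_overlap(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chrT\n" + "A" * 300 + "\n")
        region = RegionSet([GenomicRegion("chrT", 100, 200, "r")])
        gene = RegionSet([GenomicRegion("chrT", 150, 160, "gene")])
        cov = compute_region_covariates(region, fa, gene, coding_bed=gene)
        assert cov.loc["r", "dist_to_gene_bp"] == 0
        assert cov.loc["r", "coding_overlap_fraction"] == pytest.approx(0.10)
        # non-overlapping gene: distance is the gap
        far_gene = RegionSet([GenomicRegion("chrT", 250, 260, "gene")])
        cov2 = compute_region_covariates(region, fa, far_gene)
        assert cov2.loc["r", "dist_to_gene_bp"] == 50

    def test_errors(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\nACGT\n")
        region = RegionSet([GenomicRegion("chr9", 0, 2, "r")])
        genes = RegionSet([GenomicRegion("chr1", 0, 2)])
        with pytest.raises(LookupError):
            compute_region_covariates(region, fa, genes)
        with pytest.raises(ValueError, match="empty"):
            compute_region_covariates(region, fa, RegionSet([]))


def _fake_covariates(regions, values):
    rows = [{"region_id": r.key, "length_bp": v, "gc_fraction": 0.5,
             "dist_to_gene_bp": 0, "coding_overlap_fraction": 0.0}
            for r, v in zip(regions, values)]
    return pd.DataFrame(rows).set_index("region_id")


class TestMatching:
    def test_exact_duplicate_pool_gives_zero_smd(self):
        targets = RegionSet([GenomicRegion("chr1", i * 100, i * 100 + 50, f"t{i}") for i in range(5)])
        dupes = [GenomicRegion("chr1", 10_000 + i * 100, 10_000 + i * 100 + 50, f"d{i}") for i in range(5)]
        decoys = [GenomicRegion("chr1", 50_000 + i * 100, 50_000 + i * 100 + 50, f"x{i}") for i in range(5)]
        pool = RegionSet(dupes + decoys)
        cov = pd.concat(
            [
                _fake_covariates(targets, [1, 2, 3, 4, 5]),
                _fake_covariates(dupes, [1, 2, 3, 4, 5]),
                _fake_covariates(decoys, [50, 60, 70, 80, 90]),
            ]
        )
        matched, diag = sample_matched_controls(targets, pool, cov, seed=0)
        assert {r.key for r in matched} == {f"d{i}" for i in range(5)}
        assert all(v == 0.0 for v in diag.smd.values())

    def test_nearest_candidate_chosen(self):
        target = RegionSet([GenomicRegion("chr1", 0, 50, "t")])
        near = GenomicRegion("chr1", 1000, 1050, "near")
        far = GenomicRegion("chr1", 2000, 2050, "far")
        pool = RegionSet([far, near])  # file order: far first
        cov = pd.concat(
            [_fake_covariates(target, [10.0]), _fake_covariates([far, near], [15.0, 10.1])]
        )
        matched, _ = sample_matched_controls(target, pool, cov, seed=0)
        assert matched[0].key == "near"

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        targets = RegionSet([GenomicRegion("chr1", i * 100, i * 100 + 50, f"t{i}") for i in range(8)])
        pool = RegionSet(
            [GenomicRegion("chr1", 100_000 + i * 100, 100_000 + i * 100 + 60, f"p{i}") for i in range(60)]
        )
        cov = pd.concat(
            [_fake_covariates(targets, rng.normal(size=8)), _fake_covariates(pool, rng.normal(size=60))]
        )
        m1, d1 = sample_matched_controls(targets, pool, cov, seed=42)
        m2, d2 = sample_matched_controls(targets, pool, cov, seed=42)
        assert [r.key for r in m1] == [r.key for r in m2]
        assert d1.smd == d2.smd

    def test_insufficient_stratum_named(self):
        targets = RegionSet([GenomicRegion("chr7", 0, 50, "t")])
        pool = RegionSet([GenomicRegion("chr1", 0, 50, "p")])
        cov = pd.concat([_fake_covariates(targets, [1.0]), _fake_covariates(pool, [1.0])])
        with pytest.raises(MatchingError, match="chr7"):
            sample_matched_controls(targets, pool, cov, seed=0)


class TestEnrichment:
    def _disjoint_pool(self, chrom="chr1", n=10, start=100_000):
        return [GenomicRegion(chrom, start + i * 1000, start + i * 1000 + 100, f"p{i}") for i in range(n)]

    def test_query_equals_targets(self):
        regions = RegionSet(self._disjoint_pool(n=3, start=0))
        pool = RegionSet(self._disjoint_pool(n=10, start=0))
        res = permutation_enrichment(regions, regions, pool, n_perm=200, seed=0)
        assert res.observed_overlap == 3
        assert 0 < res.empirical_p <= 1

    def test_disjoint_chromosomes(self):
        query = RegionSet([GenomicRegion("chr2", 0, 100, "q")])
        targets = RegionSet([GenomicRegion("chr1", 0, 100, "t")])
        pool = RegionSet(self._disjoint_pool("chr1"))
        res = permutation_enrichment(query, targets, pool, n_perm=100, seed=0)
        assert res.observed_overlap == 0

    def test_empirical_p_matches_exhaustive_enumeration(self):
        # pool of 10 on one chromosome, targets draw 2: the null is uniform
        # over C(10, 2) subsets and can be enumerated exactly
        pool_regions = self._disjoint_pool(n=10, start=0)
        pool = RegionSet(pool_regions)
        query = RegionSet(
            [GenomicRegion("chr1", i * 1000, i * 1000 + 100, f"q{i}") for i in range(3)]
        )  # query regions coincide with pool slots 0-2
        targets = RegionSet([pool_regions[0], pool_regions[5]])
        observed = 1  # only pool slot 0 hits the query
        tail = 0
        subsets = list(combinations(range(10), 2))
        for s in subsets:
            count = sum(1 for q in range(3) if q in s)
            tail += count >= observed
        exact_p = tail / len(subsets)
        res = permutation_enrichment(query, targets, pool, n_perm=2000, seed=1)
        assert res.observed_overlap == observed
        assert res.empirical_p == pytest.approx(exact_p, abs=0.03)

    def test_null_p_roughly_uniform_when_no_enrichment(self):
        # query placed independently of targets: p should not pile up near 0
        rng = np.random.default_rng(9)
        ps = []
        pool = RegionSet(self._disjoint_pool(n=40, start=0))
        for rep in range(50):
            q_idx = rng.choice(40, size=5, replace=False)
            t_idx = rng.choice(40, size=5, replace=False)
            query = RegionSet([pool[i] for i in q_idx])
            targets = RegionSet([pool[i] for i in t_idx])
            ps.append(
                permutation_enrichment(query, targets, pool, n_perm=500, seed=rep).empirical_p
            )
        ps = np.array(ps)
        assert (ps > 0).all() and (ps <= 1).all()
        # the overlap count is discrete, so p is super-uniform (conservative):
        # the calibration requirement is no anti-conservatism at small alpha
        assert ps.mean() > 0.4
        for alpha in (0.05, 0.1, 0.2):
            assert np.mean(ps <= alpha) <= alpha + 0.08

    def test_input_validation(self):
        pool = RegionSet(self._disjoint_pool())
        with pytest.raises(ValueError):
            permutation_enrichment(RegionSet([]), pool, pool, n_perm=100)
        with pytest.raises(ValueError):
            permutation_enrichment(pool, pool, pool, n_perm=10)


class TestPartitionAssignment:
    def test_overlap_convention_and_precedence(self):
        ann = RegionSet([GenomicRegion("chr1", 10, 20, "a", "annotation")])
        mat = RegionSet(
            [
                GenomicRegion("chr1", 10, 20, "m", "matched"),
                GenomicRegion("chr1", 100, 120, "m2", "matched"),
            ]
        )
        labels = assign_variants_to_partitions(
            ["chr1", "chr1", "chr1", "chr1"], [11, 10, 15, 110], ann, mat
        )
        assert labels.tolist() == ["annotation", "background", "annotation", "matched"]

    def test_labels_are_exhaustive(self, small_cohort):
        v = small_cohort.variants
        labels = assign_variants_to_partitions(
            v["chrom"], v["pos"], small_cohort.annotation_regions, small_cohort.matched_regions
        )
        counts = pd.Series(labels).value_counts()
        assert counts.sum() == len(v)
        assert set(counts.index) <= {"annotation", "matched", "background"}
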