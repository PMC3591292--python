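import numpy as np
import pandas as pd
import pytest

import snpherit as sh
from snpherit.partitioning import (
    PartitionResult,
    RegionSet,
    aggregate_across_traits,
    assign_snps_to_regions,
    equal_snp_subsample,
    fit_region_partition,
    length_variance_regression,
    partition_by_chromosome,
)


def make_variants(bps, chrom=1):
    return pd.DataFrame(
        {
            "chrom": chrom if not np.isscalar(chrom) else [chrom] * len(bps),
            "bp": bps,
            "id": [f"v{i}" for i in range(len(bps))],
            "a1": "A",
            "a2": "G",
        }
    )


def make_result(trait, names, v_c, lengths):
    v_c = np.asarray(v_c, dtype=float)
    return PartitionResult(
        trait=trait,
        component_names=tuple(names),
        v_c=v_c,
        se=np.full(v_c.size, 0.01),
        v_total=float(v_c.sum()),
        lengths=np.asarray(lengths, dtype=float),
    )


class TestAssignSnpsToRegions:
    def test_toy_split_with_padding(self):
        # genes [50k, 60k] and [200k, 210k], pad 20kb -> [30k, 80k], [180k, 230k]
        bps = [10_000, 30_000, 55_000, 80_000, 80_001, 150_000, 185_000, 229_999, 230_001, 400_000]
        variants = make_variants(bps)
        regions = RegionSet(
            name="genic",
            intervals=pd.DataFrame(
                {"chrom": [1, 1], "start": [50_000, 200_000], "end": [60_000, 210_000]}
            ),
            pad_kb=20,
        )
        in_ids, out_ids = assign_snps_to_regions(variants, regions)
        assert set(in_ids) == {"v1", "v2", "v3", "v6", "v7"}  # 5 inside
        assert set(out_ids) == {"v0", "v4", "v5", "v8", "v9"}
        assert set(in_ids) | set(out_ids) == set(variants["id"])
        assert set(in_ids) & set(out_ids) == set()

    def test_boundary_inclusive_at_padded_start(self):
        variants = make_variants([29_999, 30_000])
        regions = RegionSet(
            name="g",
            intervals=pd.DataFrame({"chrom": [1], "start": [50_000], "end": [60_000]}),
            pad_kb=20,
        )
        in_ids, out_ids = assign_snps_to_regions(variants, regions)
        assert list(in_ids) == ["v1"]
        assert list(out_ids) == ["v0"]

    def test_empty_region_set(self):
        variants = make_variants([100, 200])
        regions = RegionSet(
            name="none", intervals=pd.DataFrame(columns=["chrom", "start", "end"])
        )
        in_ids, out_ids = assign_snps_to_regions(variants, regions)
        assert len(in_ids) == 0
        assert len(out_ids) == 2

    def test_chromosome_mismatch_raises(self):
        variants = make_variants([100, 200])
        regions = RegionSet(
            name="g", intervals=pd.DataFrame({"chrom": [7], "start": [1], "end": [10]})
        )
        with pytest.raises(ValueError, match="absent"):
            assign_snps_to_regions(variants, regions)

    def test_padding_clips_at_one(self):
        rs = RegionSet(
            name="g",
            intervals=pd.DataFrame({"chrom": [1], "start": [5_000], "end": [6_000]}),
            pad_kb=10,
        )
        padded = rs.padded()
        assert padded["start"].iloc[0] == 1
        assert padded["end"].iloc[0] == 16_000

    def test_bed_conversion_is_one_based_inclusive(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t99\t200\n")
        rs = RegionSet.from_bed(bed, name="g")
        assert rs.intervals["start"].iloc[0] == 100
        assert rs.intervals["end"].iloc[0] == 200
        variants = make_variants([99, 100, 200, 201])
        in_ids, _ = assign_snps_to_regions(variants, rs)
        assert set(in_ids) == {"v1", "v2"}

    def test_union_length_merges_overlaps(self):
        rs = RegionSet(
            name="g",
            intervals=pd.DataFrame(
                {"chrom": [1, 1], "start": [100, 150], "end": [200, 300]}
            ),
        )
        assert rs.total_length() == 201  # union [100, 300]


class TestLengthVarianceRegression:
    def test_exact_line(self):
        reg = length_variance_regression([2, 4, 6, 8], [1, 2, 3, 4])
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.r2 == pytest.approx(1.0)

    def test_proportional_values(self):
        lengths = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        reg = length_variance_regression(0.003 * lengths, lengths)
        assert reg.slope == pytest.approx(0.003)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.p_intercept_eq_0 > 0.9

    def test_five_point_normal_equations_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        y = np.array([0.8, 2.1, 2.9, 5.4, 7.6])
        reg = length_variance_regression(y, x)
        # textbook normal equations
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        s2 = (resid**2).sum() / (len(x) - 2)
        slope_se = np.sqrt(s2 / sxx)
        int_se = np.sqrt(s2 * (1 / len(x) + x.mean() ** 2 / sxx))
        assert reg.slope == pytest.approx(slope, abs=1e-12)
        assert reg.intercept == pytest.approx(intercept, abs=1e-12)
        assert reg.slope_se == pytest.approx(slope_se, abs=1e-12)
        assert reg.intercept_se == pytest.approx(int_se, abs=1e-12)
        r = np.corrcoef(x, y)[0, 1]
        assert reg.r == pytest.approx(r, abs=1e-12)

    def test_slope_eq_one_pvalue(self):
        rng = np.random.default_rng(0)
        x = np.linspace(1, 10, 20)
        y = x + rng.normal(0, 0.5, 20)
        reg = length_variance_regression(y, x)
        assert reg.p_slope_eq_1 > 0.05

    def test_zero_length_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            length_variance_regression([1, 2, 3], [5, 5, 5])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            length_variance_regression([1, 2], [1, 2])


class TestAggregateAcrossTraits:
    def test_single_trait_identity(self):
        r = make_result("t1", ["a", "b"], [0.1, 0.3], [100, 300])
        agg = aggregate_across_traits([r])
        np.testing.assert_allclose(agg.values, [0.1, 0.3])
        assert agg.n_traits == 1

    def test_genetic_fraction_mean(self):
        r1 = make_result("t1", ["a", "b"], [0.06, 0.04], [1, 2])  # fractions .6/.4
        r2 = make_result("t2", ["a", "b"], [0.05, 0.20], [1, 2])  # fractions .2/.8
        agg = aggregate_across_traits([r1, r2], mode="genetic-fraction-mean")
        np.testing.assert_allclose(agg.values, [0.4, 0.6])

    def test_zero_total_traits_excluded(self):
        r1 = make_result("t1", ["a", "b"], [0.1, 0.1], [1, 2])
        r0 = make_result("null", ["a", "b"], [0.0, 0.0], [1, 2])
        agg = aggregate_across_traits([r1, r0], mode="mean")
        assert agg.n_traits == 1

    def test_inconsistent_components_rejected(self):
        r1 = make_result("t1", ["a", "b"], [0.1, 0.1], [1, 2])
        r2 = make_result("t2", ["a", "c"], [0.1, 0.1], [1, 2])
        with pytest.raises(ValueError, match="inconsistent"):
            aggregate_across_traits([r1, r2])

    def test_empirical_se_attached(self):
        rs = [
            make_result(f"t{i}", ["a", "b"], [0.1 + 0.01 * i, 0.2], [1, 2])
            for i in range(5)
        ]
        agg = aggregate_across_traits(rs)
        assert agg.se[0] > 0
        assert agg.se[1] == pytest.approx(0.0, abs=1e-15)


class TestEqualSnpSubsample:
    def test_cardinality_and_determinism(self, small_cohort):
        _, G, _, _ = small_cohort
        sub1 = equal_snp_subsample(G, k_per_chr=50, seed=1)
        sub2 = equal_snp_subsample(G, k_per_chr=50, seed=1)
        counts = sub1.variants["chrom"].value_counts()
        assert (counts == 50).all()
        np.testing.assert_array_equal(sub1.dosages, sub2.dosages)

    def test_different_seed_differs(self, small_cohort):
        _, G, _, _ = small_cohort
        a = equal_snp_subsample(G, k_per_chr=50, seed=1)
        b = equal_snp_subsample(G, k_per_chr=50, seed=2)
        assert not a.variants["id"].equals(b.variants["id"])

    def test_small_chromosome_kept_whole_with_warning(self, small_cohort):
        _, G, _, _ = small_cohort
        smallest = G.variants["chrom"].value_counts().min()
        with pytest.warns(UserWarning, match="keeping all"):
            sub = equal_snp_subsample(G, k_per_chr=smallest + 10, seed=0)
        counts = sub.variants["chrom"].value_counts()
        assert counts.min() == smallest


class TestGrmDecomposition:
    def test_snp_weighted_chromosome_grms_average_to_full(self, small_cohort, small_grm):
        _, G, _, _ = small_cohort
        chrom = G.variants["chrom"].to_numpy()
        m = G.n_variants
        acc = np.zeros_like(small_grm.values)
        for c in np.unique(chrom):
            mask = chrom == c
            acc += sh.compute_grm(G.subset_variants(mask)).values * (mask.sum() / m)
        np.testing.assert_allclose(acc, small_grm.values, atol=1e-10)


class TestPartitionByChromosome:
    def test_enrichment_on_first_chromosome(self):
        cfg = sh.SimConfig(
            n_individuals=500,
            n_snps=2000,
            n_chromosomes=4,
            chromosome_lengths=(25_000_000,) * 4,
            h2_target=0.5,
            per_component_fractions={"chr1": 1.0, "chr2": 0.0, "chr3": 0.0, "chr4": 0.0},
            seed=61,
        )
        G = sh.simulate_genotypes(cfg)
        table, _ = sh.simulate_phenotype(G, cfg)
        res = partition_by_chromosome(G, table.data["trait1"].to_numpy(), trait="t")
        frac = res.v_c[list(res.component_names).index("chr1")] / max(res.v_total, 1e-12)
        assert frac == max(res.genetic_fractions())
        assert frac > 0.5

    def test_permuted_phenotype_loses_signal(self, small_cohort):
        _, G, table, _ = small_cohort
        rng = np.random.default_rng(4)
        y = rng.permutation(table.data["trait1"].to_numpy())
        res = partition_by_chromosome(G, y)
        unpermuted = partition_by_chromosome(G, table.data["trait1"].to_numpy())
        assert res.v_total < unpermuted.v_total
        assert res.fit.lrt_p > 0.01
        assert res.fit.constrained.any()  # some components hit the boundary

    def test_single_chromosome_rejected(self):
        cfg = sh.SimConfig(n_individuals=60, n_snps=100, n_chromosomes=1, seed=0)
        G = sh.simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="at least 2"):
            partition_by_chromosome(G, np.random.default_rng(0).standard_normal(60))

    def test_lengths_taken_from_config_when_given(self, small_cohort):
        cfg, G, table, _ = small_cohort
        res = partition_by_chromosome(
            G,
            table.data["trait1"].to_numpy(),
            chrom_lengths={c + 1: L for c, L in enumerate(cfg.chromosome_lengths)},
        )
        np.testing.assert_allclose(res.lengths, cfg.chromosome_lengths)


@pytest.fixture(scope="module")
def enriched():
    # all causal SNPs on chromosome 1, "genic" region = chromosome 1
    cfg = sh.SimConfig(
        n_individuals=500,
        n_snps=2000,
        n_chromosomes=2,
        chromosome_lengths=(30_000_000, 30_000_000),
        h2_target=0.5,
        per_component_fractions={"chr1": 1.0, "chr2": 0.0},
        seed=62,
    )
    G = sh.simulate_genotypes(cfg)
    table, truth = sh.simulate_phenotype(G, cfg)
    return G, table.data["trait1"].to_numpy(), truth


class TestFitRegionPartition:
    def test_in_region_component_recovers_signal(self, enriched):
        G, y, _ = enriched
        regions = RegionSet(
            name="genic",
            intervals=pd.DataFrame(
                {"chrom": [1], "start": [1], "end": [30_000_000]}
            ),
        )
        res = fit_region_partition(G, y, regions, trait="t")
        fractions = dict(zip(res.component_names, res.genetic_fractions()))
        assert fractions["genic"] > 0.6

    def test_whole_genome_region_degenerates_to_single_fit(self, small_cohort, small_grm):
        cfg, G, table, _ = small_cohort
        y = table.data["trait1"].to_numpy()
        regions = RegionSet(
            name="all",
            intervals=pd.DataFrame(
                {
                    "chrom": np.arange(1, cfg.n_chromosomes + 1),
                    "start": 1,
                    "end": np.array(cfg.chromosome_lengths),
                }
            ),
        )
        from snpherit.reml import RemlModel, fit_reml

        res = fit_region_partition(G, y, regions, trait="t")
        assert res.component_names == ("all",)
        single = fit_reml(RemlModel(y=y, components={"g": small_grm.values}))
        assert res.v_c[0] == pytest.approx(single.h2[0], abs=1e-6)

    def test_small_side_warns(self, enriched):
        G, y, _ = enriched
        regions = RegionSet(
            name="tiny",
            intervals=pd.DataFrame({"chrom": [1], "start": [1], "end": [1_000_000]}),
        )
        with pytest.warns(UserWarning, match="only"):
            fit_region_partition(G, y, regions, trait="t")


class TestPartitionResultInvariants:
    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_result("t", ["a"], [-0.1], [1])

    def test_vtotal_consistency_enforced(self):
        with pytest.raises(ValueError, match="v_total"):
            PartitionResult(
                trait="t",
                component_names=("a",),
                v_c=np.array([0.1]),
                se=np.array([0.01]),
                v_total=0.5,
                lengths=np.array([1.0]),
            )


class TestAcrossSeedVariability:
    def test_longer_chromosomes_more_variable_estimates(self):
        # across-seed SD of per-chromosome estimates grows with length
        from scipy.stats import spearmanr

        n_seeds, n_chrom = 12, 5
        rows = []
        for s in range(n_seeds):
            cfg = sh.SimConfig(
                n_individuals=400, n_snps=1500, n_chromosomes=n_chrom,
                h2_target=0.5, seed=300 + s,
            )
            G = sh.simulate_genotypes(cfg)
            table, _ = sh.simulate_phenotype(G, cfg)
            res = partition_by_chromosome(
                G,
                table.data["trait1"].to_numpy(),
                chrom_lengths={c + 1: L for c, L in enumerate(cfg.chromosome_lengths)},
            )
            rows.append(res.v_c)
        sds = np.vstack(rows).std(axis=0, ddof=1)
        lengths = np.array(
            sh.SimConfig(n_individuals=2, n_snps=1, n_chromosomes=n_chrom).chromosome_lengths
        )
        rho, _ = spearmanr(sds, lengths)
        assert rho > 0
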