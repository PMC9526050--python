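import numpy as np
import pandas as pd
import pytest

from admixisle.admix_sim import (
    ContributionSchedule,
    FounderRegistry,
    SimConfig,
    autozygosity_truth,
    founder_haplotype,
    ibd_truth,
    make_migrant,
    mate,
    mate_assortative,
    meiosis_gamete,
    simulate,
)
from admixisle.genome_io import Chromosome, GeneticMap
from conftest import truth_from_individuals


class TestSchedule:
    def test_oversubscribed_generation_rejected(self):
        with pytest.raises(ValueError, match="hybrid"):
            ContributionSchedule([1.0, 0.7], [1.0, 0.0], [0.0, 0.7], [0.0, 0.0])

    def test_founding_must_be_sources_only(self):
        with pytest.raises(ValueError, match="founding"):
            ContributionSchedule([0.5], [1.0], [0.0], [0.0])

    def test_constant_requires_nonzero_source_sums(self):
        with pytest.raises(ValueError, match="found"):
            ContributionSchedule.constant(5, 0.0, 0.1, 0.0, 0.1)

    def test_constant_migration_is_stationary_split(self):
        s = ContributionSchedule.constant_migration(5, 0.65, 0.01)
        assert s.s1f[0] == pytest.approx(0.65)
        assert s.s1f[1] == pytest.approx(0.0065)
        assert s.hf[0] == pytest.approx(0.0)


class TestSimulate:
    def test_identical_seeds_identical_output(self):
        gmap = GeneticMap.uniform([80, 60], x_mb=50)
        sched = ContributionSchedule.constant_migration(4, 0.6, 0.02)
        a = simulate(SimConfig(gmap=gmap, N=50, schedule=sched, seed=7, rho=0.3))
        b = simulate(SimConfig(gmap=gmap, N=50, schedule=sched, seed=7, rho=0.3))
        pd.testing.assert_frame_equal(a.tracts.df, b.tracts.df)
        pd.testing.assert_frame_equal(a.truth.individuals, b.truth.individuals)
        pd.testing.assert_frame_equal(
            a.truth.founder_segments(), b.truth.founder_segments()
        )
        c = simulate(SimConfig(gmap=gmap, N=50, schedule=sched, seed=8, rho=0.3))
        assert not a.tracts.df.equals(c.tracts.df)

    def test_pure_source1_founding(self):
        gmap = GeneticMap.uniform([80], x_mb=50)
        sched = ContributionSchedule.constant(1, 1.0, 1.0, 0.0, 0.0)
        res = simulate(SimConfig(gmap=gmap, N=40, schedule=sched, seed=1))
        assert set(res.tracts.df["ancestry"]) == {"S1"}

    def test_generation_one_haplotypes_are_single_ancestry(self):
        gmap = GeneticMap.uniform([80], x_mb=50)
        sched = ContributionSchedule.constant_migration(1, 0.5, 0.0)
        res = simulate(SimConfig(gmap=gmap, N=60, schedule=sched, seed=3))
        per_hap = res.tracts.df.groupby(["sample", "hap", "chrom"]).size()
        assert (per_hap == 1).all()

    def test_male_x_is_single_haplotype(self, small_sim, small_map):
        sex = small_sim.samples.sex_of()
        x = small_sim.tracts.df[small_sim.tracts.df["chrom"] == "chrX"]
        male_haps = x[x["sample"].map(sex) == "M"]["hap"].unique()
        assert set(male_haps) == {0}
        female_haps = x[x["sample"].map(sex) == "F"]["hap"].unique()
        assert set(female_haps) == {0, 1}

    def test_founder_segments_match_tract_ancestry(self, small_sim, small_map):
        ids = sorted(small_sim.truth._haps)[:5]
        segs = small_sim.truth.founder_segments(ids)
        src = small_sim.truth.founder_source
        segs["ancestry"] = segs["founder"].map(src)
        for key, grp in segs.groupby(["sample", "hap", "chrom"]):
            tr = small_sim.tracts.df
            tr = tr[
                (tr["sample"] == key[0]) & (tr["hap"] == key[1]) & (tr["chrom"] == key[2])
            ]
            # every founder segment must lie inside a tract of the same ancestry
            for row in grp.itertuples(index=False):
                cover = tr[(tr["start"] <= row.start) & (tr["end"] >= row.end)]
                assert len(cover) == 1
                assert cover["ancestry"].iloc[0] == row.ancestry


class TestAssortativeMating:
    def test_random_pairing_near_zero_correlation(self):
        rng = np.random.default_rng(0)
        anc = rng.beta(2, 2, size=1000)
        pairs, r = mate_assortative(anc, rng.beta(2, 2, size=1000), 0.0, rng)
        assert abs(r) < 0.1
        assert sorted(pairs[:, 0]) == list(range(1000))

    def test_strong_assortment_reaches_high_correlation(self):
        rng = np.random.default_rng(1)
        am = rng.beta(2, 2, size=1000)
        af = rng.beta(2, 2, size=1000)
        _, r = mate_assortative(am, af, 0.99, rng)
        assert r > 0.9

    @pytest.mark.parametrize("rho", [0.2, 0.4, 0.6])
    def test_calibration_hits_target(self, rho):
        rng = np.random.default_rng(2)
        am = rng.beta(5, 5, size=1000)
        af = rng.beta(5, 5, size=1000)
        _, r = mate_assortative(am, af, rho, rng)
        assert abs(r - rho) < 0.05

    def test_degenerate_pool_reports_nan(self):
        rng = np.random.default_rng(3)
        pairs, r = mate_assortative(np.ones(50), np.ones(50), 0.5, rng)
        assert np.isnan(r)
        assert len(pairs) == 50

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            mate_assortative([], [], 0.2, rng)
        with pytest.raises(ValueError):
            mate_assortative([0.5], [0.5], 1.0, rng)


class TestMeiosis:
    def test_negligible_genetic_length_returns_parent(self):
        ch = Chromosome("chr1", 100_000_000, rate_cm_per_mb=1e-12)
        rng = np.random.default_rng(0)
        hA = founder_haplotype(ch.length_bp, 0, True)
        hB = founder_haplotype(ch.length_bp, 2, False)
        for _ in range(20):
            g = meiosis_gamete((hA, hB), ch, rng)
            assert g is hA or g is hB

    def test_single_haplotype_transmitted_intact(self):
        ch = Chromosome("chrX", 100_000_000, is_x=True)
        rng = np.random.default_rng(0)
        hA = founder_haplotype(ch.length_bp, 0, True)
        assert meiosis_gamete((hA,), ch, rng) is hA

    def test_poisson_crossover_mean(self):
        ch = Chromosome("chr1", 100_000_000)  # 1 Morgan
        rng = np.random.default_rng(11)
        hA = founder_haplotype(ch.length_bp, 0, False)
        hB = founder_haplotype(ch.length_bp, 2, False)
        counts = [
            len(meiosis_gamete((hA, hB), ch, rng)[0]) - 1 for _ in range(10_000)
        ]
        assert np.mean(counts) == pytest.approx(1.0, abs=0.03)

    def test_homozygous_source1_parent_gives_pure_gamete(self):
        ch = Chromosome("chr1", 100_000_000)
        rng = np.random.default_rng(5)
        src = [True, True]
        hA = founder_haplotype(ch.length_bp, 0, True)
        hB = founder_haplotype(ch.length_bp, 2, True)
        for _ in range(50):
            g = meiosis_gamete((hA, hB), ch, rng, src)
            assert g[2] == ch.length_bp  # entirely S1


class TestPedigreeTruth:
    def _family(self, gmap, seed):
        rng = np.random.default_rng(seed)
        reg = FounderRegistry()
        chroms = gmap.chromosomes
        mo = make_migrant(reg, chroms, "F", True, "mo")
        fa = make_migrant(reg, chroms, "M", False, "fa")
        return rng, reg, chroms, mo, fa

    def test_offspring_of_unrelated_founders_has_no_roh(self):
        gmap = GeneticMap.uniform([100, 80])
        rng, reg, chroms, mo, fa = self._family(gmap, 0)
        child = mate(mo, fa, "F", rng, reg.src_is_s1, chroms, id_="c")
        truth = truth_from_individuals([child], reg, gmap)
        assert len(autozygosity_truth(truth, gmap)) == 0

    def test_unrelated_migrants_share_no_ibd(self):
        gmap = GeneticMap.uniform([100, 80])
        _, reg, chroms, mo, fa = self._family(gmap, 0)
        truth = truth_from_individuals([mo, fa], reg, gmap)
        assert len(ibd_truth(truth, gmap)) == 0

    def test_parent_offspring_ibd_totals_one_genome_exactly(self):
        gmap = GeneticMap.uniform([100, 80])
        rng, reg, chroms, mo, fa = self._family(gmap, 1)
        child = mate(mo, fa, "M", rng, reg.src_is_s1, chroms, id_="c")
        truth = truth_from_individuals([mo, child], reg, gmap)
        ibd = ibd_truth(truth, gmap, pairs=[("mo", "c")])
        assert ibd.df["cM"].sum() == pytest.approx(gmap.total_cm("autosomes"))

    def test_selfing_gives_half_autozygosity(self):
        # selfing is possible only in this harness; expectation F = 1/2
        gmap = GeneticMap.uniform([100] * 35)  # 35 Morgans
        fracs = []
        for rep in range(20):
            rng, reg, chroms, mo, _ = self._family(gmap, 100 + rep)
            child = mate(mo, mo, "F", rng, reg.src_is_s1, chroms, id_="c")
            truth = truth_from_individuals([child], reg, gmap)
            roh = autozygosity_truth(truth, gmap)
            fracs.append(roh.df["cM"].sum() / gmap.total_cm("autosomes"))
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.03)

    def test_unknown_pair_rejected(self, small_sim, small_map):
        with pytest.raises(ValueError, match="unknown sample"):
            ibd_truth(small_sim.truth, small_map, pairs=[("nope", "nah")])
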