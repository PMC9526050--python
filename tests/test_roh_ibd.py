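import numpy as np
import pandas as pd
import pytest

from admixisle.admix_sim import (
    ContributionSchedule,
    FounderRegistry,
    SimConfig,
    autozygosity_truth,
    ibd_truth,
    make_migrant,
    mate,
    simulate,
)
from admixisle.genome_io import GeneticMap
from admixisle.roh_ibd import (
    ancestry_switches_in_roh,
    boundary_from_generations,
    classify_roh,
    ibd_network,
    kinship_proxy,
    mann_whitney,
    pairwise_ibd_totals,
    roh_summaries,
)
from conftest import tracts_from_rows, truth_from_individuals


def _roh_df(lengths_bp, sample="s1", chrom="chr1"):
    rows = []
    pos = 0
    for L in lengths_bp:
        rows.append(
            ("ROH", sample, np.nan, "", np.nan, chrom, pos, pos + L, L / 1e6, "")
        )
        pos += L + 1_000_000
    return pd.DataFrame(
        rows,
        columns=["kind", "sample1", "hap1", "sample2", "hap2",
                 "chrom", "start", "end", "cM", "class"],
    )


class TestBoundaryRule:
    def test_twenty_generations_gives_two_and_a_half_mb(self):
        assert boundary_from_generations(20) == pytest.approx(2.5)

    @pytest.mark.parametrize("g,mb", [(10, 5.0), (50, 1.0)])
    def test_formula(self, g, mb):
        assert boundary_from_generations(g) == pytest.approx(mb)

    def test_strictly_decreasing_in_g(self):
        vals = [boundary_from_generations(g) for g in range(1, 60)]
        assert all(a > b for a, b in zip(vals[:-1], vals[1:]))

    def test_rate_conversion(self):
        assert boundary_from_generations(20, rate_cm_per_mb=2.0) == pytest.approx(1.25)

    def test_small_g_rejected(self):
        with pytest.raises(ValueError):
            boundary_from_generations(0)


class TestClassifyROH:
    def test_fixed_boundary_labels(self):
        df = _roh_df([500_000, 3_000_000])
        cls = classify_roh(df, scheme="fixed", boundary_mb=2.5)
        assert cls.labels.tolist() == ["shorter", "long"]

    def test_gmm3_recovers_separated_modes(self):
        rng = np.random.default_rng(0)
        lengths = np.concatenate(
            [
                10 ** rng.normal(np.log10(m), 0.08, 400)
                for m in (100_000, 500_000, 2_000_000)
            ]
        ).astype(int)
        cls = classify_roh(_roh_df(lengths), scheme="gmm3")
        b1, b2 = cls.boundaries_bp
        assert 100_000 < b1 < 500_000
        assert 500_000 < b2 < 2_000_000

    def test_gmm3_boundaries_scale_with_units(self):
        rng = np.random.default_rng(1)
        lengths = np.concatenate(
            [10 ** rng.normal(np.log10(m), 0.1, 200) for m in (1e5, 5e5, 2e6)]
        ).astype(int)
        a = classify_roh(_roh_df(lengths), scheme="gmm3")
        b = classify_roh(_roh_df(lengths * 10), scheme="gmm3")
        np.testing.assert_allclose(
            np.array(b.boundaries_bp) / np.array(a.boundaries_bp), 10.0, rtol=0.01
        )

    def test_gmm3_needs_enough_segments(self):
        with pytest.raises(ValueError, match="at least 50"):
            classify_roh(_roh_df([1_000_000] * 10), scheme="gmm3")

    def test_gmm3_degenerate_lengths_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            classify_roh(_roh_df([1_000_000] * 60), scheme="gmm3")

    def test_fixed_requires_boundary(self):
        with pytest.raises(ValueError, match="boundary_mb"):
            classify_roh(_roh_df([1_000_000]), scheme="fixed")


class TestROHSummaries:
    def test_totals_sum_lengths(self):
        df = _roh_df([1_000_000, 1_000_000])
        cls = classify_roh(df, scheme="fixed", boundary_mb=2.5)
        out = roh_summaries(df, cls)
        row = out.per_individual.set_index("sample").loc["s1"]
        assert row["total"] == pytest.approx(2.0)

    def test_class_totals_partition_total(self, small_sim, small_map):
        roh = autozygosity_truth(small_sim.truth, small_map)
        if len(roh) == 0:
            pytest.skip("no ROH in fixture")
        cls = classify_roh(roh, scheme="fixed", boundary_mb=2.5)
        out = roh_summaries(roh, cls)
        per = out.per_individual
        np.testing.assert_allclose(per["shorter"] + per["long"], per["total"])

    def test_zero_roh_individuals_enter_with_zero(self):
        df = _roh_df([1_000_000])
        cls = classify_roh(df, scheme="fixed", boundary_mb=2.5)
        anc = pd.Series({"s1": 0.5, "s2": 0.7, "s3": 0.4})
        out = roh_summaries(df, cls, ancestry=anc)
        per = out.per_individual.set_index("sample")
        assert per.loc["s2", "total"] == 0.0
        assert len(out.correlations) == 3  # shorter, long, total

    def test_founder_bottleneck_inflates_roh(self):
        gmap = GeneticMap.uniform([100] * 5)
        sched = ContributionSchedule.constant_migration(8, 0.5, 0.0)
        wins = 0
        for rep in range(20):
            big = simulate(SimConfig(gmap=gmap, N=100, schedule=sched,
                                     seed=500 + rep, population="big"))
            tight = simulate(SimConfig(gmap=gmap, N=100, schedule=sched,
                                       seed=900 + rep, n_founders=10, population="tight"))
            tot_big = autozygosity_truth(big.truth, gmap).df.groupby("sample1")["cM"].sum()
            tot_tight = autozygosity_truth(tight.truth, gmap).df.groupby("sample1")["cM"].sum()
            big_all = tot_big.reindex([s for s in big.truth._haps], fill_value=0.0)
            tight_all = tot_tight.reindex([s for s in tight.truth._haps], fill_value=0.0)
            _, p = mann_whitney(tight_all, big_all, alternative="greater")
            wins += p < 0.05
        assert wins >= 18


class TestAncestrySwitches:
    def test_roh_inside_single_tract_has_no_switch(self):
        gmap = GeneticMap.uniform([100])
        ts = tracts_from_rows(
            [("s1", 0, "chr1", 0, 100_000_000, "S1"), ("s1", 1, "chr1", 0, 100_000_000, "S1")],
            gmap,
        )
        df = _roh_df([2_000_000])
        cls = classify_roh(df, scheme="fixed", boundary_mb=2.5)
        out = ancestry_switches_in_roh(df, ts, cls)
        assert out.per_segment["n_switches"].tolist() == [0]

    def test_single_breakpoint_counts_once_across_homologs(self):
        gmap = GeneticMap.uniform([100])
        # both haplotypes switch at the same position inside the ROH (they are
        # copies inside an autozygous segment) -> deduplicated to one switch
        rows = []
        for h in (0, 1):
            rows += [
                ("s1", h, "chr1", 0, 1_000_000, "S1"),
                ("s1", h, "chr1", 1_000_000, 100_000_000, "S2"),
            ]
        ts = tracts_from_rows(rows, gmap)
        df = _roh_df([2_000_000])
        cls = classify_roh(df, scheme="fixed", boundary_mb=2.5)
        out = ancestry_switches_in_roh(df, ts, cls)
        assert out.per_segment["n_switches"].tolist() == [1]
        assert out.per_segment["per_mb"].iloc[0] == pytest.approx(0.5)

    def test_boundary_on_edge_not_counted(self):
        gmap = GeneticMap.uniform([100])
        rows = []
        for h in (0, 1):
            rows += [
                ("s1", h, "chr1", 0, 2_000_000, "S1"),
                ("s1", h, "chr1", 2_000_000, 100_000_000, "S2"),
            ]
        ts = tracts_from_rows(rows, gmap)
        df = _roh_df([2_000_000])  # ROH is [0, 2_000_000): switch sits on its edge
        cls = classify_roh(df, scheme="fixed", boundary_mb=2.5)
        out = ancestry_switches_in_roh(df, ts, cls)
        assert out.per_segment["n_switches"].tolist() == [0]

    def test_roh_outside_coverage_rejected(self):
        gmap = GeneticMap.uniform([100])
        ts = tracts_from_rows(
            [("s2", 0, "chr1", 0, 100_000_000, "S1"), ("s2", 1, "chr1", 0, 100_000_000, "S1")],
            gmap,
        )
        df = _roh_df([2_000_000])  # sample s1 has no tracts
        cls = classify_roh(df, scheme="fixed", boundary_mb=2.5)
        with pytest.raises(ValueError, match="coverage"):
            ancestry_switches_in_roh(df, ts, cls)


class TestIBDTotals:
    def _ibd_df(self, rows):
        return pd.DataFrame(
            rows,
            columns=["kind", "sample1", "hap1", "sample2", "hap2",
                     "chrom", "start", "end", "cM", "class"],
        )

    def test_min_length_filter_then_sum(self):
        df = self._ibd_df(
            [
                ("IBD", "a", 0, "b", 0, "chr1", 0, 4_000_000, 4.0, ""),
                ("IBD", "a", 0, "b", 1, "chr1", 0, 6_000_000, 6.0, ""),
            ]
        )
        out = pairwise_ibd_totals(df, min_cm=5)
        assert out["total_cm"].tolist() == [6.0]

    def test_unordered_pairs_collapse(self):
        df = self._ibd_df(
            [
                ("IBD", "b", 0, "a", 0, "chr1", 0, 10_000_000, 10.0, ""),
                ("IBD", "a", 1, "b", 1, "chr2", 0, 10_000_000, 10.0, ""),
            ]
        )
        out = pairwise_ibd_totals(df, min_cm=5)
        assert len(out) == 1
        assert out.loc[0, "total_cm"] == 20.0

    def test_empty_input(self):
        out = pairwise_ibd_totals(self._ibd_df([]), min_cm=5)
        assert len(out) == 0


class TestIBDNetwork:
    def test_absolute_threshold(self):
        totals = pd.DataFrame(
            {"sample1": ["a", "a"], "sample2": ["b", "c"], "total_cm": [100.0, 200.0]}
        )
        edges, graph = ibd_network(totals, edge_cm=150)
        assert len(edges) == 1
        assert graph.has_edge("a", "c")

    def test_top_quantile_count(self):
        rng = np.random.default_rng(0)
        totals = pd.DataFrame(
            {
                "sample1": [f"a{i}" for i in range(100)],
                "sample2": [f"b{i}" for i in range(100)],
                "total_cm": rng.uniform(10, 300, 100),
            }
        )
        edges, _ = ibd_network(totals, edge_cm=None, top_quantile=0.03)
        assert len(edges) == 3

    def test_empty_totals(self):
        totals = pd.DataFrame(columns=["sample1", "sample2", "total_cm"])
        edges, graph = ibd_network(totals, edge_cm=150)
        assert len(edges) == 0
        assert graph.number_of_edges() == 0

    def test_double_threshold_rejected(self):
        totals = pd.DataFrame(columns=["sample1", "sample2", "total_cm"])
        with pytest.raises(ValueError, match="not both"):
            ibd_network(totals, edge_cm=150, top_quantile=0.03)


class TestKinshipProxy:
    def test_parent_offspring_is_exactly_one_quarter(self):
        gmap = GeneticMap.uniform([100, 80])
        rng = np.random.default_rng(0)
        reg = FounderRegistry()
        chroms = gmap.chromosomes
        mo = make_migrant(reg, chroms, "F", True, "mo")
        fa = make_migrant(reg, chroms, "M", False, "fa")
        child = mate(mo, fa, "F", rng, reg.src_is_s1, chroms, id_="c")
        truth = truth_from_individuals([mo, child], reg, gmap)
        ibd = ibd_truth(truth, gmap, pairs=[("mo", "c")])
        kin = kinship_proxy(ibd, gmap)
        assert kin.loc[("c", "mo")] == pytest.approx(0.25)

    def test_grandparent_halves_kinship(self):
        gmap = GeneticMap.uniform([100] * 35)
        vals = []
        for rep in range(20):
            rng = np.random.default_rng(700 + rep)
            reg = FounderRegistry()
            chroms = gmap.chromosomes
            gma = make_migrant(reg, chroms, "F", True, "gma")
            gpa = make_migrant(reg, chroms, "M", False, "gpa")
            mo = mate(gma, gpa, "F", rng, reg.src_is_s1, chroms, id_="mo")
            fa = make_migrant(reg, chroms, "M", False, "fa")
            child = mate(mo, fa, "F", rng, reg.src_is_s1, chroms, id_="c")
            truth = truth_from_individuals([gma, child], reg, gmap)
            ibd = ibd_truth(truth, gmap, pairs=[("gma", "c")])
            vals.append(ibd.df["cM"].sum() / (4 * gmap.total_cm("autosomes")))
        assert np.mean(vals) == pytest.approx(0.125, abs=0.02)
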