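import pandas as pd
import pytest

from admixisle.admix_sim import (
    ContributionSchedule,
    SimConfig,
    SimTruth,
    simulate,
)
from admixisle.genome_io import AncestryTractSet, GeneticMap


@pytest.fixture(scope="session")
def small_map() -> GeneticMap:
    return GeneticMap.uniform([120, 100, 80], x_mb=100)


@pytest.fixture(scope="session")
def small_sim(small_map):
    """One modest admixed population shared by read-only tests."""
    sched = ContributionSchedule.constant_migration(10, 0.65, 0.01)
    return simulate(
        SimConfig(gmap=small_map, N=200, schedule=sched, seed=42, rho=0.4)
    )


def tracts_from_rows(rows, gmap) -> AncestryTractSet:
    """Build a tract set from (sample, hap, chrom, start, end, ancestry) tuples."""
    df = pd.DataFrame(
        rows, columns=["sample", "hap", "chrom", "start", "end", "ancestry"]
    )
    return AncestryTractSet(df, gmap)


def truth_from_individuals(inds, registry, gmap) -> SimTruth:
    """Wrap hand-built individuals into a truth object for ROH/IBD functions."""
    return SimTruth(
        individuals=pd.DataFrame(
            {"sample": [i.id for i in inds], "sex": [i.sex for i in inds]}
        ),
        couples=pd.DataFrame(),
        founder_source={
            i: ("S1" if s else "S2") for i, s in enumerate(registry.src_is_s1)
        },
        gmap=gmap,
        _haps={i.id: i.haps for i in inds},
        _sex={i.id: i.sex for i in inds},
    )
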