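"""ROH length classification, ancestry switches inside ROH, IBD totals and kinship.

Runs of homozygosity (ROH) arise when both homologs descend from a recent
common ancestor; segment length reflects the time depth of that ancestor.
Two classification schemes are provided: a 3-component Gaussian mixture on
log10 segment length (class A/B/C with boundaries at the density
intersections of adjacent components) and a single fixed shorter/long
boundary, for which the rule of thumb "a time depth of m meioses gives a
mean IBD segment length of 100/m cM" supplies a principled default.

Pairwise IBD segment totals (after a minimum-length filter) feed a
relatedness network and a simple kinship proxy: the shared genetic length
over the four homolog pairs divided by four genome lengths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .genome_io import AncestryTractSet, GeneticMap, SampleTable, SegmentTable

__all__ = [
    "boundary_from_generations",
    "classify_roh",
    "ROHClassification",
    "roh_summaries",
    "ancestry_switches_in_roh",
    "pairwise_ibd_totals",
    "ibd_network",
    "kinship_proxy",
    "mann_whitney",
]


def boundary_from_generations(g: float, rate_cm_per_mb: float = 1.0) -> float:
    """Shorter/long ROH boundary (Mb) for common ancestors ``g`` generations back.

    Lineages meeting in an ancestor ``g`` generations ago are separated by
    ``m = 2 g`` meioses, giving a mean IBD segment length of ``100 / m`` cM,
    converted to Mb at the constant rate (default 1 cM/Mb).
    """
    if g < 1:
        raise ValueError("g must be at least 1")
    m = 2.0 * g
    return (100.0 / m) / rate_cm_per_mb


def mann_whitney(x, y, alternative: str = "two-sided"):
    """Mann-Whitney U with exact enumeration for small tie-free samples.

    Uses the exact distribution when both groups have fewer than 20
    observations and there are no ties; otherwise the normal approximation
    with continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    both = np.concatenate([x, y])
    no_ties = len(np.unique(both)) == len(both)
    method = "exact" if (len(x) < 20 and len(y) < 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _roh_frame(segments) -> pd.DataFrame:
    df = segments.df if isinstance(segments, SegmentTable) else segments
    roh = df[df["kind"] == "ROH"] if "kind" in df.columns else df
    if roh.empty:
        raise ValueError("no ROH segments")
    return roh


@dataclass
class ROHClassification:
    """Length-class labels for ROH segments under one scheme."""

    scheme: str  # "gmm3" or "fixed"
    boundaries_bp: tuple[float, ...]
    labels: pd.Series  # aligned with the classified ROH frame's index
    class_names: tuple[str, ...]
    diagnostics: dict

    def boundary_mb(self) -> tuple[float, ...]:
        return tuple(b / 1e6 for b in self.boundaries_bp)


def _gaussian_intersection(m1, s1, w1, m2, s2, w2):
    """Intersection of two weighted Gaussian densities between their means."""
    a = 1.0 / (2 * s1**2) - 1.0 / (2 * s2**2)
    b = m2 / s2**2 - m1 / s1**2
    c = m1**2 / (2 * s1**2) - m2**2 / (2 * s2**2) + np.log((w1 * s2) / (w2 * s1))
    if abs(a) < 1e-12:
        x = -c / b if b != 0 else None
        roots = [x] if x is not None else []
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            roots = []
        else:
            sq = np.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [r for r in roots if m1 < r < m2]
    return inside[0] if inside else None


def classify_roh(segments, scheme: str = "gmm3", *, boundary_mb: float | None = None,
                 seed: int = 0, n_init: int = 20) -> ROHClassification:
    """Attach length-class labels to ROH segments.

    ``gmm3`` fits a 3-component Gaussian mixture to log10(length in bp) with
    k-means initialisation and ``n_init`` restarts at a fixed seed; class
    boundaries sit at the density intersections between adjacent components
    (midpoint of the component means when the densities do not cross between
    them).  ``fixed`` cuts at a single ``boundary_mb`` (e.g. from
    :func:`boundary_from_generations`), yielding classes shorter/long.
    """
    roh = _roh_frame(segments)
    lengths = (roh["end"] - roh["start"]).to_numpy(dtype=float)
    if scheme == "fixed":
        if boundary_mb is None:
            raise ValueError("fixed scheme requires boundary_mb")
        b = boundary_mb * 1e6
        labels = pd.Series(np.where(lengths < b, "shorter", "long"), index=roh.index)
        return ROHClassification("fixed", (b,), labels, ("shorter", "long"), {})
    if scheme != "gmm3":
        raise ValueError(f"unknown scheme {scheme!r}")
    if len(lengths) < 50:
        raise ValueError("gmm3 needs at least 50 segments; use the fixed scheme")
    logl = np.log10(lengths)
    if np.ptp(logl) < 1e-9:
        raise ValueError("degenerate ROH lengths; use the fixed scheme")
    gm = GaussianMixture(
        n_components=3, n_init=n_init, init_params="kmeans", random_state=seed
    ).fit(logl.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_.ravel()[order]
    cuts = []
    for i in (0, 1):
        x = _gaussian_intersection(means[i], sds[i], weights[i], means[i + 1], sds[i + 1], weights[i + 1])
        if x is None:
            x = 0.5 * (means[i] + means[i + 1])
        cuts.append(x)
    boundaries = tuple(10.0 ** np.array(cuts))
    names = ("A", "B", "C")
    labels = pd.Series(
        np.select(
            [lengths < boundaries[0], lengths < boundaries[1]], ["A", "B"], default="C"
        ),
        index=roh.index,
    )
    diag = {"means_log10": means, "sds_log10": sds, "weights": weights}
    return ROHClassification("gmm3", boundaries, labels, names, diag)


@dataclass
class ROHSummary:
    per_individual: pd.DataFrame  # sample, total_cm, per-class cm columns
    correlations: pd.DataFrame | None  # class, r, p vs S1 ancestry
    population_tests: pd.DataFrame | None  # pop1, pop2, U, p (total ROH)


def roh_summaries(
    segments,
    classification: ROHClassification,
    ancestry: pd.Series | None = None,
    samples: SampleTable | None = None,
) -> ROHSummary:
    """Per-individual ROH totals by class, ancestry correlations, population tests.

    Individuals present in ``ancestry`` (or the sample table) but without any
    ROH enter with zero totals.  Correlations are Pearson r of each class
    total (cM) against S1 ancestry; populations are compared pairwise on
    total ROH with Mann-Whitney U tests.
    """
    roh = _roh_frame(segments).copy()
    roh["cls"] = classification.labels
    per_class = roh.pivot_table(
        index="sample1", columns="cls", values="cM", aggfunc="sum", fill_value=0.0
    )
    for name in classification.class_names:
        if name not in per_class.columns:
            per_class[name] = 0.0
    per_class = per_class[list(classification.class_names)]
    per_class["total"] = per_class.sum(axis=1)
    universe = per_class.index
    if ancestry is not None:
        universe = universe.union(ancestry.index)
    if samples is not None:
        universe = universe.union(samples.df["sample"])
    per_class = per_class.reindex(universe).fillna(0.0)
    per_class.index.name = "sample"

    correlations = None
    if ancestry is not None:
        anc = ancestry.reindex(per_class.index)
        ok = anc.notna()
        if ok.sum() < 3:
            raise ValueError("need at least 3 individuals with ancestry for correlations")
        rows = []
        for col in list(classification.class_names) + ["total"]:
            v = per_class.loc[ok, col]
            if v.std() == 0 or anc[ok].std() == 0:
                rows.append((col, np.nan, np.nan))
                continue
            r, p = stats.pearsonr(v, anc[ok])
            rows.append((col, float(r), float(p)))
        correlations = pd.DataFrame(rows, columns=["class", "r", "p"])

    population_tests = None
    if samples is not None:
        pop = samples.df.set_index("sample")["population"]
        totals = per_class["total"]
        groups = {
            name: totals[pop.reindex(totals.index) == name].to_numpy()
            for name in sorted(pop.unique())
        }
        rows = []
        for p1, p2 in itertools.combinations(sorted(groups), 2):
            if len(groups[p1]) == 0 or len(groups[p2]) == 0:
                continue
            u, pv = mann_whitney(groups[p1], groups[p2])
            rows.append((p1, p2, u, pv))
        population_tests = pd.DataFrame(rows, columns=["pop1", "pop2", "U", "p"])

    return ROHSummary(per_class.reset_index(), correlations, population_tests)


@dataclass
class SwitchReport:
    per_segment: pd.DataFrame  # sample, chrom, start, end, cls, mb, n_switches, per_mb
    per_class: pd.DataFrame  # cls, n, frac_with_switch, mean_per_mb, sd_per_mb
    class_test: tuple[float, float] | None  # Mann-Whitney on per-Mb rates


def ancestry_switches_in_roh(
    segments, tracts: AncestryTractSet, classification: ROHClassification | None = None
) -> SwitchReport:
    """Count local-ancestry breakpoints strictly inside each ROH.

    Inside an autozygous segment the two homologs are copies, so breakpoints
    found on either haplotype are deduplicated by position before counting.
    Only boundaries where the ancestry actually changes count as switches.
    """
    roh = _roh_frame(segments).copy()
    if classification is not None:
        roh["cls"] = classification.labels
    else:
        roh["cls"] = roh["class"].replace("", "all")
    tdf = tracts.df
    lengths = {c.name: c.length_bp for c in tracts.gmap}
    # switch positions per (sample, chrom): tract ends where the next tract differs
    switch_pos: dict[tuple[str, str], np.ndarray] = {}
    for (sample, chrom), grp in tdf.groupby(["sample", "chrom"], sort=False):
        pos = set()
        for _, hgrp in grp.groupby("hap", sort=False):
            anc = hgrp["ancestry"].to_numpy()
            ends = hgrp["end"].to_numpy()
            change = anc[:-1] != anc[1:]
            pos.update(ends[:-1][change].tolist())
        switch_pos[(sample, chrom)] = np.array(sorted(pos), dtype=np.int64)

    rows = []
    covered = {(s, c) for s, c in tdf[["sample", "chrom"]].drop_duplicates().itertuples(index=False)}
    for idx, seg in roh.iterrows():
        key = (seg["sample1"], seg["chrom"])
        if key not in covered:
            raise ValueError(f"ROH at {key} outside tract coverage")
        pos = switch_pos.get(key, np.empty(0, dtype=np.int64))
        n = int(np.sum((pos > seg["start"]) & (pos < seg["end"])))
        mb = (seg["end"] - seg["start"]) / 1e6
        rows.append((seg["sample1"], seg["chrom"], seg["start"], seg["end"], seg["cls"], mb, n, n / mb))
    per_segment = pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "cls", "mb", "n_switches", "per_mb"]
    )
    agg = per_segment.groupby("cls")["per_mb"]
    per_class = pd.DataFrame(
        {
            "n": per_segment.groupby("cls").size(),
            "frac_with_switch": per_segment.groupby("cls")["n_switches"].apply(lambda v: float((v > 0).mean())),
            "mean_per_mb": agg.mean(),
            "sd_per_mb": agg.std(ddof=1),
        }
    ).reset_index()
    class_test = None
    classes = per_class["cls"].tolist()
    if len(classes) == 2:
        g1 = per_segment.loc[per_segment["cls"] == classes[0], "per_mb"]
        g2 = per_segment.loc[per_segment["cls"] == classes[1], "per_mb"]
        if len(g1) and len(g2):
            class_test = mann_whitney(g1, g2)
    return SwitchReport(per_segment, per_class, class_test)


def pairwise_ibd_totals(ibd, min_cm: float = 5.0) -> pd.DataFrame:
    """Total IBD cM per unordered sample pair after a minimum-length filter.

    Segments shorter than ``min_cm`` are dropped (mirroring the detectability
    floor applied to called IBD); remaining lengths are summed over all
    homolog pairs and chromosomes.  Pairs with nothing left are absent.
    """
    df = ibd.df if isinstance(ibd, SegmentTable) else ibd
    df = df[df["kind"] == "IBD"] if "kind" in df.columns else df
    df = df[df["cM"] >= min_cm]
    if df.empty:
        return pd.DataFrame(columns=["sample1", "sample2", "total_cm"])
    a = df["sample1"].to_numpy()
    b = df["sample2"].to_numpy()
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    out = (
        pd.DataFrame({"sample1": lo, "sample2": hi, "total_cm": df["cM"].to_numpy()})
        .groupby(["sample1", "sample2"], as_index=False)["total_cm"]
        .sum()
    )
    return out.sort_values(["sample1", "sample2"]).reset_index(drop=True)


def ibd_network(
    totals: pd.DataFrame, edge_cm: float | None = 150.0, top_quantile: float | None = None
):
    """Edge list (and networkx graph) of strongly IBD-sharing pairs.

    Either an absolute threshold ``edge_cm`` (pairs sharing more than this
    total) or ``top_quantile`` (the top fraction of nonzero pair totals), not
    both.  Edge weights carry the log-transformed total.
    """
    import networkx as nx

    if edge_cm is not None and top_quantile is not None:
        raise ValueError("supply either edge_cm or top_quantile, not both")
    nonzero = totals[totals["total_cm"] > 0]
    if top_quantile is not None:
        k = int(np.ceil(top_quantile * len(nonzero)))
        edges = nonzero.sort_values(
            ["total_cm", "sample1", "sample2"], ascending=[False, True, True]
        ).head(k)
    else:
        if edge_cm is None:
            raise ValueError("one of edge_cm or top_quantile is required")
        edges = nonzero[nonzero["total_cm"] > edge_cm]
    edges = edges.copy().sort_values(["sample1", "sample2"]).reset_index(drop=True)
    edges["log_cm"] = np.log10(edges["total_cm"])
    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        graph.add_edge(row.sample1, row.sample2, total_cm=row.total_cm, weight=row.log_cm)
    return edges, graph


def kinship_proxy(ibd, gmap: GeneticMap, min_cm: float = 0.0) -> pd.Series:
    """IBD-segment kinship proxy: shared autosomal cM over four genome lengths.

    For each unordered pair, kinship = (sum of shared cM over the 4 homolog
    pairs) / (4 L), with L the total autosomal map length.  Parent-offspring
    and full-sib pairs both have expectation 0.25.
    """
    L = gmap.total_cm("autosomes")
    if L <= 0:
        raise ValueError("autosomal map length must be positive")
    df = ibd.df if isinstance(ibd, SegmentTable) else ibd
    df = df[df["kind"] == "IBD"] if "kind" in df.columns else df
    auto = {c.name for c in gmap.autosomes}
    df = df[df["chrom"].isin(auto)]
    if min_cm > 0:
        df = df[df["cM"] >= min_cm]
    totals = pairwise_ibd_totals(df.assign(kind="IBD"), min_cm=0.0)
    out = totals.set_index(["sample1", "sample2"])["total_cm"] / (4.0 * L)
    out.name = "kinship"
    return out
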