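"""Global ancestry proportions, LAD windows and the paired X-vs-autosome test.

Local ancestry disequilibrium (LAD) is the association between the ancestry
states at two loci on the same haplotype.  Here it is measured as the Pearson
correlation across haplotypes of the source-1 indicator at the two anchors of
a genomic window (the covariance is carried along for diagnostics).  Under
random mating LAD decays by a factor (1 - c) per generation, which is what
the timing module inverts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import AncestryTractSet, SampleTable

logger = logging.getLogger(__name__)

__all__ = [
    "global_ancestry",
    "pooled_ancestry",
    "population_summary",
    "lad_windows",
    "LADWindowSet",
    "x_vs_auto_test",
]


def global_ancestry(tracts: AncestryTractSet, scope: str = "autosomes") -> pd.Series:
    """Per-sample S1 proportion, cM-weighted, over autosomes or the X.

    On the X, females contribute two haplotypes and males one (their tract
    tables carry a single X haplotype), so the proportion is simply S1
    genetic length over total genetic length present in scope.
    """
    gmap = tracts.gmap
    if scope == "autosomes":
        names = {c.name for c in gmap.autosomes}
    elif scope in ("X", "x"):
        names = {gmap.x.name} if gmap.x is not None else set()
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if not names:
        raise ValueError(f"scope {scope!r} is empty in the map")
    df = tracts.with_cm()
    df = df[df["chrom"].isin(names)]
    if df.empty:
        raise ValueError(f"no tracts in scope {scope!r}")
    total = df.groupby("sample")["cM"].sum()
    s1 = df[df["ancestry"] == "S1"].groupby("sample")["cM"].sum()
    out = s1.reindex(total.index).fillna(0.0) / total
    out.name = f"anc_{scope}"
    return out


def pooled_ancestry(tracts: AncestryTractSet, scope: str = "X") -> float:
    """Haplotype-dosage-pooled S1 proportion over a scope.

    Total S1 genetic length over total genetic length present, so on the X
    females weigh twice as much as males — the quantity the sex-bias model's
    pooled-X expectation predicts.
    """
    gmap = tracts.gmap
    if scope == "autosomes":
        names = {c.name for c in gmap.autosomes}
    elif scope in ("X", "x"):
        names = {gmap.x.name} if gmap.x is not None else set()
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if not names:
        raise ValueError(f"scope {scope!r} is empty in the map")
    df = tracts.with_cm()
    df = df[df["chrom"].isin(names)]
    if df.empty:
        raise ValueError(f"no tracts in scope {scope!r}")
    return float(df.loc[df["ancestry"] == "S1", "cM"].sum() / df["cM"].sum())


def population_summary(proportions: pd.Series, samples: SampleTable) -> pd.DataFrame:
    """Mean/median/quartiles of an ancestry proportion per population."""
    pop = samples.df.set_index("sample")["population"]
    df = pd.DataFrame({"value": proportions, "population": pop.reindex(proportions.index)})
    if df["population"].isna().any():
        missing = df.index[df["population"].isna()][0]
        raise ValueError(f"sample {missing!r} missing from the sample table")
    g = df.groupby("population")["value"]
    out = g.agg(n="count", mean="mean", median="median",
                q25=lambda v: v.quantile(0.25), q75=lambda v: v.quantile(0.75))
    return out.reset_index()


@dataclass
class LADWindowSet:
    """Per-window LAD values: one row per (chrom, anchor pair)."""

    df: pd.DataFrame  # chrom, anchor1_bp, anchor2_bp, dist_cm, lad_corr, lad_cov, n_hap
    n_dropped: int = 0

    @property
    def mean_lad(self) -> float:
        return float(self.df["lad_corr"].mean())

    def __len__(self) -> int:
        return len(self.df)


def lad_windows(
    tracts: AncestryTractSet,
    window_mb: float = 10.0,
    overlap_mb: float = 1.0,
    step_mb: float | None = None,
) -> LADWindowSet:
    """LAD at the endpoints of sliding autosomal windows.

    Successive window starts advance by ``window_mb - overlap_mb`` (so
    consecutive windows share ``overlap_mb``); pass ``step_mb`` to override,
    e.g. ``step_mb=1`` for a dense 1-Mb sliding grid.  Trailing incomplete
    windows are dropped.  At each anchor pair the S1 indicator of every
    haplotype is read off at the exact anchor position and correlated across
    haplotypes; anchor pairs with zero variance at either anchor are dropped
    and logged.
    """
    step = float(step_mb) if step_mb is not None else window_mb - overlap_mb
    if step <= 0 or window_mb <= 0:
        raise ValueError("window and step must be positive")
    gmap = tracts.gmap
    df = tracts.df
    w_bp = int(round(window_mb * 1e6))
    step_bp = int(round(step * 1e6))

    rows = []
    n_dropped = 0
    any_window = False
    for ch in gmap.autosomes:
        starts = np.arange(0, ch.length_bp - w_bp + 1, step_bp, dtype=np.int64)
        if len(starts) == 0:
            continue
        any_window = True
        anchors = np.unique(np.concatenate([starts, starts + w_bp]))
        # clamp end anchors landing exactly at chromosome end into the last tract
        anchors = np.minimum(anchors, ch.length_bp - 1)
        sub = df[df["chrom"] == ch.name]
        groups = sub.groupby(["sample", "hap"], sort=True)
        mats = []
        for _, grp in groups:
            ends = grp["end"].to_numpy()
            anc = (grp["ancestry"].to_numpy() == "S1")
            idx = np.searchsorted(ends, anchors, side="right")
            mats.append(anc[idx])
        if len(mats) < 20:
            raise ValueError("need at least 20 haplotypes for LAD")
        M = np.asarray(mats, dtype=float)  # haplotypes x anchors
        pos_col = {p: j for j, p in enumerate(anchors)}
        Mc = M - M.mean(axis=0)
        var = (Mc ** 2).mean(axis=0)
        for s in starts:
            a1 = pos_col[min(s, ch.length_bp - 1)]
            a2 = pos_col[min(s + w_bp, ch.length_bp - 1)]
            cov = float((Mc[:, a1] * Mc[:, a2]).mean())
            if var[a1] <= 0 or var[a2] <= 0:
                n_dropped += 1
                logger.info("dropping zero-variance LAD window %s:%d-%d", ch.name, s, s + w_bp)
                continue
            corr = cov / np.sqrt(var[a1] * var[a2])
            rows.append(
                (ch.name, int(s), int(s + w_bp), w_bp * ch.rate_cm_per_mb / 1e6,
                 corr, cov, M.shape[0])
            )
    if not any_window:
        raise ValueError("no chromosome long enough for a complete window")
    out = pd.DataFrame(
        rows,
        columns=["chrom", "anchor1_bp", "anchor2_bp", "dist_cm", "lad_corr", "lad_cov", "n_hap"],
    )
    return LADWindowSet(out, n_dropped)


def x_vs_auto_test(auto: pd.Series, x: pd.Series) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank of X vs autosomal ancestry.

    Uses the normal approximation with tie correction; zero differences are
    dropped.  Refuses with fewer than 6 informative (nonzero-difference)
    pairs.
    """
    common = auto.index.intersection(x.index)
    a = auto.loc[common].to_numpy(dtype=float)
    b = x.loc[common].to_numpy(dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    informative = int(np.sum(b - a != 0))
    if informative < 6:
        raise ValueError(
            f"only {informative} informative pairs; at least 6 required for the signed-rank test"
        )
    res = stats.wilcoxon(b, a, zero_method="wilcox", method="approx", correction=False)
    return float(res.statistic), float(res.pvalue)
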