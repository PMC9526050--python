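"""Ancestry-assortative mating: parental decomposition, correlation, permutation null.

Each phased haplotype of an individual is one parental gamete, so the S1
genetic fraction of haplotype k on a chromosome is a moment estimator of the
transmitting parent's ancestry on that chromosome.  Chromosomes are analysed
independently (matching haplotypes across chromosomes to parents is not
attempted), the spousal correlation is summarised as the median per-chromosome
Pearson R, and significance comes from shuffling one parental column across
individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import AncestryTractSet

logger = logging.getLogger(__name__)

__all__ = [
    "parental_ancestry",
    "assortment_correlation",
    "permutation_null",
    "AssortmentResult",
]

MIN_INDIVIDUALS = 10


def parental_ancestry(tracts: AncestryTractSet) -> pd.DataFrame:
    """Per-chromosome parental-gamete ancestry estimates (autosomes only).

    Returns rows (sample, chrom, a1, a2) where ``a1``/``a2`` are the S1
    genetic fractions of haplotypes 0/1.  Parent labels are arbitrary: which
    physical parent transmitted which haplotype is unknown and may differ
    between chromosomes.
    """
    gmap = tracts.gmap
    auto = {c.name for c in gmap.autosomes}
    df = tracts.with_cm()
    df = df[df["chrom"].isin(auto)]
    total = df.groupby(["sample", "chrom", "hap"])["cM"].sum()
    s1 = df[df["ancestry"] == "S1"].groupby(["sample", "chrom", "hap"])["cM"].sum()
    frac = (s1.reindex(total.index).fillna(0.0) / total).unstack("hap")
    if frac.isna().any().any() or frac.shape[1] != 2:
        bad = frac.index[frac.isna().any(axis=1)][0] if frac.isna().any().any() else "?"
        raise ValueError(f"missing haplotype for {bad}")
    out = frac.reset_index()
    out.columns = ["sample", "chrom", "a1", "a2"]
    return out


def _sym_r(a1: np.ndarray, a2: np.ndarray) -> float:
    """Pearson R on the symmetrised pair set {(a1,a2)} U {(a2,a1)}."""
    x = np.concatenate([a1, a2])
    m = x.mean()
    v = x.var()
    if v <= 0:
        return np.nan
    return float((np.mean(a1 * a2) - m * m) / v)


def _ordered_r(a1: np.ndarray, a2: np.ndarray) -> float:
    if a1.std() <= 0 or a2.std() <= 0:
        return np.nan
    return float(np.corrcoef(a1, a2)[0, 1])


@dataclass
class AssortmentResult:
    """Per-chromosome spousal-ancestry correlations and their permutation p."""

    per_chrom: pd.DataFrame  # chrom, n, r_sym, r_ordered
    median_r: float
    B: int | None = None
    p: float | None = None
    seed: int | None = None


def assortment_correlation(pairs: pd.DataFrame, symmetrized: bool = True) -> AssortmentResult:
    """Median per-chromosome Pearson R of parental-ancestry pairs.

    By default R is computed on the symmetrised set {(a1,a2)} U {(a2,a1)}
    since parent labels are arbitrary; the ordered R is reported alongside.
    Chromosomes with zero variance are skipped with a warning.
    """
    rows = []
    for chrom, grp in pairs.groupby("chrom", sort=True):
        if len(grp) < MIN_INDIVIDUALS:
            raise ValueError(
                f"chromosome {chrom}: {len(grp)} individuals, need >= {MIN_INDIVIDUALS}"
            )
        a1 = grp["a1"].to_numpy(dtype=float)
        a2 = grp["a2"].to_numpy(dtype=float)
        r_s = _sym_r(a1, a2)
        r_o = _ordered_r(a1, a2)
        if np.isnan(r_s):
            logger.warning("chromosome %s skipped: zero ancestry variance", chrom)
            continue
        rows.append((chrom, len(grp), r_s, r_o))
    per_chrom = pd.DataFrame(rows, columns=["chrom", "n", "r_sym", "r_ordered"])
    if per_chrom.empty:
        raise ValueError("no chromosome with ancestry variance")
    col = "r_sym" if symmetrized else "r_ordered"
    return AssortmentResult(per_chrom=per_chrom, median_r=float(per_chrom[col].median()))


def permutation_null(
    pairs: pd.DataFrame, B: int, seed: int, symmetrized: bool = True
) -> AssortmentResult:
    """Random-mating permutation null for the median spousal correlation.

    Each of the ``B`` shuffles permutes the ``a2`` column across individuals
    within every chromosome and recomputes the median-across-chromosomes R.
    The empirical two-sided p-value uses the add-one correction
    ``(1 + #{|R_perm| >= |R_obs|}) / (1 + B)`` and is deterministic given
    ``seed``.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    obs = assortment_correlation(pairs, symmetrized=symmetrized)
    rng = np.random.default_rng(seed)
    chrom_data = []
    for chrom, grp in pairs.groupby("chrom", sort=True):
        a1 = grp["a1"].to_numpy(dtype=float)
        a2 = grp["a2"].to_numpy(dtype=float)
        if np.isnan(_sym_r(a1, a2)):
            continue
        if symmetrized:
            x = np.concatenate([a1, a2])
            chrom_data.append((a1, a2, x.mean(), x.var()))
        else:
            chrom_data.append((a1, a2, None, None))
    perm_r = np.empty(B)
    for b in range(B):
        rs = []
        for a1, a2, m, v in chrom_data:
            p = rng.permutation(len(a2))
            if symmetrized:
                rs.append((np.mean(a1 * a2[p]) - m * m) / v)
            else:
                rs.append(_ordered_r(a1, a2[p]))
        perm_r[b] = np.median(rs)
    p = float((1 + np.sum(np.abs(perm_r) >= abs(obs.median_r))) / (1 + B))
    return AssortmentResult(
        per_chrom=obs.per_chrom, median_r=obs.median_r, B=B, p=p, seed=seed
    )
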