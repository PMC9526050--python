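"""Sex-biased admixture: constant-contribution X/autosome expectations and grid search.

The model tracks the expected source-1 ancestry of autosomes and of the X
under constant per-generation contributions ``s1f, s1m, s2f, s2m`` (fractions
of mothers/fathers that are new migrants from source 1/source 2), with hybrid
fractions ``hf = 1 - s1f - s2f`` and ``hm = 1 - s1m - s2m``:

    autosomes:    H_g   = 1/2 (s1f + hf H_{g-1}) + 1/2 (s1m + hm H_{g-1})
    X in females: HXf_g = 1/2 (s1f + hf HXf_{g-1}) + 1/2 (s1m + hm HXm_{g-1})
    X in males:   HXm_g = s1f + hf HXf_{g-1}

The founding generation (g = 1) is built from sources only with the sex-wise
renormalised splits ``s1f/(s1f+s2f)`` and ``s1m/(s1m+s2m)``.  The population
X ancestry pools females and males by X dosage (2 per female, 1 per male)
using the proportion of females ``pf`` in the sample:

    H_X = (2 pf HXf_G + (1 - pf) HXm_G) / (1 + pf)

Inference enumerates the full constrained lattice of the four contributions
and keeps the parameter sets whose model-predicted (autosomal, X) ancestry
falls within the smallest Euclidean distances of the observed pair; the
sex bias of each source is summarised by the female fraction of its total
contribution, f1 = s1f/(s1f+s1m) and f2 = s2f/(s2f+s2m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["expected_hx_ha", "grid_search", "female_fraction", "SexBiasGrid"]


def _recursion(s1f, s1m, s2f, s2m, G):
    """Vectorised ancestry recursion; returns (H_auto, HXf, HXm) at generation G."""
    s1f, s1m, s2f, s2m = (np.asarray(a, dtype=float) for a in (s1f, s1m, s2f, s2m))
    hf = 1.0 - s1f - s2f
    hm = 1.0 - s1m - s2m
    if np.any(hf < -1e-12) or np.any(hm < -1e-12):
        raise ValueError("contributions exceed 1 (negative hybrid fraction)")
    sf = s1f + s2f
    sm = s1m + s2m
    if np.any(sf <= 0) or np.any(sm <= 0):
        raise ValueError("founding requires s1f+s2f > 0 and s1m+s2m > 0")
    split_f = s1f / sf
    split_m = s1m / sm
    H = 0.5 * (split_f + split_m)
    HXf = 0.5 * (split_f + split_m)
    HXm = split_f * np.ones_like(H)
    for _ in range(int(G) - 1):
        H_new = 0.5 * (s1f + hf * H) + 0.5 * (s1m + hm * H)
        HXf_new = 0.5 * (s1f + hf * HXf) + 0.5 * (s1m + hm * HXm)
        HXm_new = s1f + hf * HXf
        H, HXf, HXm = H_new, HXf_new, HXm_new
    return H, HXf, HXm


def expected_hx_ha(s1f, s1m, s2f, s2m, G: int, pf: float = 0.5):
    """Expected autosomal and dosage-pooled X ancestry at generation ``G``.

    ``pf`` is the proportion of females in the sample.  Inputs may be scalars
    or equally-shaped arrays.
    """
    if G < 1:
        raise ValueError("G must be at least 1")
    if not 0 <= pf <= 1:
        raise ValueError("pf must lie in [0, 1]")
    H, HXf, HXm = _recursion(s1f, s1m, s2f, s2m, G)
    HX = (2.0 * pf * HXf + (1.0 - pf) * HXm) / (1.0 + pf)
    if np.ndim(H) == 0 or (hasattr(H, "shape") and H.shape == ()):
        return float(H), float(HX)
    return H, HX


def female_fraction(s1f, s1m):
    """Female share of a source's total contribution: s1f / (s1f + s1m).

    Undefined (NaN) when both contributions are zero.
    """
    s1f = np.asarray(s1f, dtype=float)
    s1m = np.asarray(s1m, dtype=float)
    tot = s1f + s1m
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tot > 0, s1f / np.where(tot > 0, tot, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass
class SexBiasGrid:
    """Result of the lattice search over sex-specific contributions."""

    retained: pd.DataFrame  # s1f, s1m, s2f, s2m, H_auto, H_X, dist, f1, f2
    increment: float
    keep: float
    n_feasible: int
    pf: float
    G: int
    obs: tuple[float, float]

    @property
    def median_f1(self) -> float:
        return float(self.retained["f1"].median())

    @property
    def median_f2(self) -> float:
        return float(self.retained["f2"].median())


def grid_search(
    obs_h_auto: float,
    obs_h_x: float,
    pf: float,
    G: int,
    increment: float = 0.02,
    keep: float = 0.001,
) -> SexBiasGrid:
    """Enumerate the contribution lattice and keep the best-fitting fraction.

    All feasible ``(s1f, s1m, s2f, s2m)`` on the ``increment`` lattice
    (per-sex sums in (0, 1]) are scored by the Euclidean distance between
    model-predicted and observed (autosomal, X) ancestry; the smallest
    ``keep`` fraction is retained (count rounded up, ties at the cutoff
    broken by lexicographic parameter order).
    """
    if not (0 < obs_h_auto < 1 and 0 < obs_h_x < 1):
        raise ValueError("observed ancestries must lie in (0, 1)")
    n = int(round(1.0 / increment))
    vals = np.linspace(0.0, 1.0, n + 1)
    i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    ok = (i + j <= n) & (i + j > 0)  # per-sex sum in (0, 1]
    pf_pairs = np.column_stack([vals[i[ok]], vals[j[ok]]])  # (s1, s2) per sex
    k = len(pf_pairs)
    if k == 0:
        raise ValueError("empty feasible grid")
    # cross product of female and male (s1, s2) pairs
    fi = np.repeat(np.arange(k), k)
    mi = np.tile(np.arange(k), k)
    s1f, s2f = pf_pairs[fi, 0], pf_pairs[fi, 1]
    s1m, s2m = pf_pairs[mi, 0], pf_pairs[mi, 1]
    H, HX = expected_hx_ha(s1f, s1m, s2f, s2m, G, pf)
    dist = np.sqrt((H - obs_h_auto) ** 2 + (HX - obs_h_x) ** 2)
    n_keep = math.ceil(keep * len(dist))
    order = np.lexsort((s2m, s2f, s1m, s1f, dist))
    top = order[:n_keep]
    retained = pd.DataFrame(
        {
            "s1f": s1f[top], "s1m": s1m[top], "s2f": s2f[top], "s2m": s2m[top],
            "H_auto": H[top], "H_X": HX[top], "dist": dist[top],
            "f1": female_fraction(s1f[top], s1m[top]),
            "f2": female_fraction(s2f[top], s2m[top]),
        }
    ).reset_index(drop=True)
    return SexBiasGrid(
        retained=retained,
        increment=increment,
        keep=keep,
        n_feasible=len(dist),
        pf=pf,
        G=G,
        obs=(obs_h_auto, obs_h_x),
    )
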