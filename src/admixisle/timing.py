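"""Admixture dating from the decay of local ancestry disequilibrium (LAD).

The expected LAD between two loci at recombination fraction ``c`` after ``g``
generations of admixture with spousal ancestry correlation ``rho`` and
per-generation migration ``m`` follows a coupled recursion in the mean
ancestry ``H_t`` and the cross-locus ancestry covariance ``D_t``:

    H_{t+1}      = m1 + h * H_t
    E[Z1 Z2]_{t+1} = m1 + h * (H_t^2 + D_t * (1 - c * (1 - rho)))
    D_{t+1}      = E[Z1 Z2]_{t+1} - H_{t+1}^2

with migrant inflow split between the sources as ``m1 = m * h0`` and
``m2 = m * (1 - h0)`` (which keeps the mean ancestry stationary at ``h0``)
and resident fraction ``h = 1 - m``.  The recursion starts at the admixture
pulse: ``H_0 = h0``, ``D_0 = h0 (1 - h0)``.  The returned value is the
correlation ``D_g / (H_g (1 - H_g))``; with ``m = 0`` it reduces to the
closed form ``(1 - c (1 - rho))^g``.

The cross-homolog coupling term ``rho * D_t`` is exact in both limits
(``rho = 0``: random-mating decay ``(1 - c)^g``; ``rho = 1``: no decay) and
is validated against the forward simulator rather than assumed.

Counting convention: ``g`` counts rounds of ancestry-mixing meiosis after
the founding cohort.  A population observed at generation ``G`` of the
forward simulator has experienced ``G - 1`` such rounds, because the
founding cohort still carries single-ancestry haplotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestry_stats import LADWindowSet, lad_windows
from .genome_io import GeneticMap

__all__ = [
    "expected_lad",
    "haldane_c",
    "fit_generations",
    "TimingFit",
    "simulate_lad_reference",
    "generations_to_years",
]


def haldane_c(dist_cm):
    """Haldane map function: recombination fraction from genetic distance in cM."""
    d = np.asarray(dist_cm, dtype=float) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def expected_lad(c, g: int, rho: float, m: float, h0: float):
    """Expected LAD correlation at recombination fraction ``c``.

    ``c`` may be a scalar or array in (0, 0.5]; ``g >= 0`` integer;
    ``rho`` in [0, 1]; ``m`` in [0, 1); ``h0`` in (0, 1).
    """
    c = np.asarray(c, dtype=float)
    scalar = c.ndim == 0
    c = np.atleast_1d(c)
    if np.any((c <= 0) | (c > 0.5)):
        raise ValueError("c must lie in (0, 0.5]")
    if g < 0 or int(g) != g:
        raise ValueError("g must be a non-negative integer")
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    if not 0 <= m < 1:
        raise ValueError("m must lie in [0, 1)")
    if not 0 < h0 < 1:
        raise ValueError("h0 must lie in (0, 1)")
    m1 = m * h0
    h = 1.0 - m
    decay = 1.0 - c * (1.0 - rho)
    H = h0
    D = np.full_like(c, h0 * (1.0 - h0))
    for _ in range(int(g)):
        ez = m1 + h * (H * H + D * decay)
        H = m1 + h * H
        D = ez - H * H
    out = D / (H * (1.0 - H))
    return float(out[0]) if scalar else out


@dataclass
class TimingFit:
    """Integer-grid fit of the number of admixture generations."""

    grid: np.ndarray
    sse: np.ndarray
    best_g: int
    settings: dict
    at_boundary: bool
    bootstrap_ci: tuple[int, int] | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"g": self.grid, "sse": self.sse})


def _sse_curve(lad_corr, c, grid, rho, m, h0):
    return np.array(
        [float(np.sum((lad_corr - expected_lad(c, g, rho, m, h0)) ** 2)) for g in grid]
    )


def fit_generations(
    lad,
    rho: float,
    m: float,
    h0: float,
    g_min: int = 5,
    g_max: int = 25,
    dist_cm=None,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> TimingFit:
    """Grid fit of admixture generations against observed per-window LAD.

    ``lad`` is a :class:`LADWindowSet` (or an array of LAD values with
    matching ``dist_cm``).  The SSE over windows is minimised over the
    integer grid ``g_min..g_max``; ties break toward smaller ``g`` and a
    best fit on the grid boundary raises a warning.  Optional bootstrap over
    windows gives a percentile interval for the best ``g``.
    """
    if isinstance(lad, LADWindowSet):
        if len(lad) == 0:
            raise ValueError("empty window set")
        values = lad.df["lad_corr"].to_numpy()
        dist = lad.df["dist_cm"].to_numpy()
    else:
        values = np.atleast_1d(np.asarray(lad, dtype=float))
        if dist_cm is None:
            raise ValueError("dist_cm required when lad is not a LADWindowSet")
        dist = np.broadcast_to(np.asarray(dist_cm, dtype=float), values.shape)
        if values.size == 0:
            raise ValueError("empty window set")
    c = haldane_c(dist)
    grid = np.arange(int(g_min), int(g_max) + 1)
    sse = _sse_curve(values, c, grid, rho, m, h0)
    best = int(grid[int(np.argmin(sse))])  # argmin takes the first (smallest g) on ties
    at_boundary = best in (grid[0], grid[-1])
    if at_boundary:
        warnings.warn(f"best g = {best} lies on the grid boundary [{g_min}, {g_max}]")
    ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_bootstrap, dtype=int)
        n = len(values)
        for b in range(n_bootstrap):
            idx = rng.integers(n, size=n)
            s = _sse_curve(values[idx], c[idx], grid, rho, m, h0)
            boots[b] = int(grid[int(np.argmin(s))])
        ci = (int(np.percentile(boots, 2.5)), int(np.percentile(boots, 97.5)))
    return TimingFit(
        grid=grid,
        sse=sse,
        best_g=best,
        settings={"rho": rho, "m": m, "h0": h0, "g_min": g_min, "g_max": g_max},
        at_boundary=at_boundary,
        bootstrap_ci=ci,
    )


def simulate_lad_reference(
    g: int,
    rho: float,
    m: float,
    h0: float,
    gmap: GeneticMap,
    reps: int,
    seed: int,
    N: int = 1000,
    window_mb: float = 10.0,
    overlap_mb: float = 1.0,
) -> pd.DataFrame:
    """Monte-Carlo mean and SE of per-window LAD from matched forward simulations.

    ``g`` counts ancestry-mixing rounds, so the simulator runs ``g + 1``
    generations (the founding cohort contributes none).
    """
    from .admix_sim import ContributionSchedule, SimConfig, simulate

    if reps < 5:
        raise ValueError("need at least 5 replicates")
    sched = ContributionSchedule.constant_migration(g + 1, h0, m)
    per_rep = []
    for r in range(reps):
        cfg = SimConfig(gmap=gmap, N=N, schedule=sched, seed=seed + r, rho=rho)
        res = simulate(cfg)
        win = lad_windows(res.tracts, window_mb=window_mb, overlap_mb=overlap_mb)
        per_rep.append(
            win.df.set_index(["chrom", "anchor1_bp", "anchor2_bp"])["lad_corr"]
        )
    stacked = pd.concat(per_rep, axis=1)
    out = pd.DataFrame(
        {
            "mean_lad": stacked.mean(axis=1),
            "se_lad": stacked.std(axis=1, ddof=1) / np.sqrt(stacked.notna().sum(axis=1)),
            "n_reps": stacked.notna().sum(axis=1),
        }
    ).reset_index()
    return out


def generations_to_years(
    g: float,
    anchor_year: float,
    generation_time: tuple[float, float] = (20.0, 30.0),
    point_generation_time: float = 25.0,
) -> dict:
    """Convert a generation count to a calendar interval before ``anchor_year``."""
    if g < 0:
        raise ValueError("g must be non-negative")
    lo, hi = generation_time
    return {
        "point": anchor_year - point_generation_time * g,
        "interval": (anchor_year - hi * g, anchor_year - lo * g),
    }
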