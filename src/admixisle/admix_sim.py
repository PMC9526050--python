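"""Forward-in-time simulator of a two-source admixed population.

The model: every generation, a fixed number of diploid offspring is produced
by monogamous couples.  Each mother (father) slot is filled by a brand-new
source-1 migrant with probability ``s1f`` (``s1m``), a new source-2 migrant
with probability ``s2f`` (``s2m``), and otherwise by a resident of the
previous generation sampled uniformly with replacement.  Couples are formed
by ancestry-assortative matching with a target spousal Pearson correlation
``rho``.  Autosomes recombine in both sexes with Poisson crossovers (no
interference); the X recombines only in females, and sons inherit a single
maternal X.  Migrants carry fresh founder haplotypes, so identity by descent
(ROH, pairwise IBD) is known exactly from founder-segment bookkeeping.

Generation 1 is the first cohort born on-site: its parent slots are filled by
migrants only, with maternal source split ``s1f/(s1f+s2f)`` and paternal
split ``s1m/(s1m+s2m)``.  Haplotypes of generation-1 individuals therefore
carry a single ancestry each; ancestry-mixing recombination accumulates from
generation 2 onward.

Founder-segment keys encode ``founder_id * 2 + founder_haplotype``; a
haplotype is a triple ``(ends, keys, s1_bp)`` where ``ends`` are ascending
segment end positions (last equals the chromosome length), ``keys`` the
parallel founder keys, and ``s1_bp`` the cached source-1 physical length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .genome_io import (
    AncestryTractSet,
    GeneticMap,
    SampleTable,
    SegmentTable,
    SEGMENT_COLUMNS,
)

__all__ = [
    "ContributionSchedule",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "simulate",
    "mate_assortative",
    "meiosis_gamete",
    "founder_haplotype",
    "Individual",
    "mate",
    "FounderRegistry",
    "make_migrant",
    "autozygosity_truth",
    "ibd_truth",
]


# ---------------------------------------------------------------------------
# contribution schedules


@dataclass
class ContributionSchedule:
    """Per-generation sex-specific migrant fractions from the two sources.

    Arrays are indexed by generation ``t = 1..G`` (position ``t-1``).  The
    founding generation must have no resident parents: ``s1f+s2f`` and
    ``s1m+s2m`` equal 1 at ``t = 1``.
    """

    s1f: np.ndarray
    s1m: np.ndarray
    s2f: np.ndarray
    s2m: np.ndarray

    def __post_init__(self) -> None:
        arrs = [np.asarray(a, dtype=float) for a in (self.s1f, self.s1m, self.s2f, self.s2m)]
        self.s1f, self.s1m, self.s2f, self.s2m = arrs
        G = len(self.s1f)
        if any(len(a) != G for a in arrs) or G < 1:
            raise ValueError("schedule arrays must share a positive length")
        if np.any([(a < 0) | (a > 1) for a in arrs]):
            raise ValueError("contributions must lie in [0, 1]")
        if np.any(self.s1f + self.s2f > 1 + 1e-12) or np.any(self.s1m + self.s2m > 1 + 1e-12):
            raise ValueError("per-sex contributions must sum to at most 1 (negative hybrid fraction)")
        if abs(self.s1f[0] + self.s2f[0] - 1) > 1e-9 or abs(self.s1m[0] + self.s2m[0] - 1) > 1e-9:
            raise ValueError("founding generation must be built from sources only (hf = hm = 0 at t=1)")

    @property
    def G(self) -> int:
        return len(self.s1f)

    @property
    def hf(self) -> np.ndarray:
        return 1.0 - self.s1f - self.s2f

    @property
    def hm(self) -> np.ndarray:
        return 1.0 - self.s1m - self.s2m

    @classmethod
    def constant(
        cls,
        G: int,
        s1f: float,
        s1m: float,
        s2f: float,
        s2m: float,
        founding_f: float | None = None,
        founding_m: float | None = None,
    ) -> "ContributionSchedule":
        """Constant contributions for t >= 2; founding row renormalised by sex.

        By default the founding maternal source-1 split is ``s1f/(s1f+s2f)``
        and the paternal split ``s1m/(s1m+s2m)`` (both sex-specific sums must
        then be positive).  ``founding_f``/``founding_m`` override the
        founding source-1 splits directly, which also permits schedules whose
        ongoing contribution from one sex is zero.
        """
        if founding_f is None and s1f + s2f <= 0:
            raise ValueError("constant schedule needs s1f+s2f > 0 (or founding_f) to found the population")
        if founding_m is None and s1m + s2m <= 0:
            raise ValueError("constant schedule needs s1m+s2m > 0 (or founding_m) to found the population")
        a = np.full(G, float(s1f)); b = np.full(G, float(s1m))
        c = np.full(G, float(s2f)); d = np.full(G, float(s2m))
        a[0] = founding_f if founding_f is not None else s1f / (s1f + s2f)
        c[0] = 1.0 - a[0]
        b[0] = founding_m if founding_m is not None else s1m / (s1m + s2m)
        d[0] = 1.0 - b[0]
        return cls(a, b, c, d)

    @classmethod
    def constant_migration(cls, G: int, h0: float, m: float) -> "ContributionSchedule":
        """Sex-symmetric founding at ancestry ``h0`` plus migration rate ``m``.

        Migration is split between the sources proportionally to ``h0`` so
        mean ancestry stays stationary at ``h0``.
        """
        if not 0 < h0 < 1:
            raise ValueError("h0 must lie in (0, 1)")
        if not 0 <= m < 1:
            raise ValueError("m must lie in [0, 1)")
        a = np.full(G, m * h0); c = np.full(G, m * (1 - h0))
        a[0], c[0] = h0, 1 - h0
        return cls(a.copy(), a.copy(), c.copy(), c.copy())


@dataclass
class SimConfig:
    """Simulation settings; ``seed`` is mandatory for reproducibility."""

    gmap: GeneticMap
    N: int
    schedule: ContributionSchedule
    seed: int
    rho: float = 0.0
    sex_ratio: float = 0.5
    n_sample: int | None = None
    n_founders: int | None = None
    population: str = "pop1"

    def __post_init__(self) -> None:
        if self.N < 20:
            raise ValueError("N must be at least 20")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_founders is not None and self.n_founders < 2:
            raise ValueError("n_founders must be at least 2")

    @property
    def G(self) -> int:
        return self.schedule.G


# ---------------------------------------------------------------------------
# haplotypes and meiosis

# a haplotype is (ends: list[int], keys: list[int], s1_bp: int)


def founder_haplotype(length_bp: int, key: int, is_s1: bool):
    """Single-segment haplotype of a fresh migrant founder."""
    return ([int(length_bp)], [int(key)], int(length_bp) if is_s1 else 0)


def _recombine(hA, hB, cuts, phase, src_is_s1):
    """Merge two parental haplotypes along sorted cut positions.

    ``phase`` selects the starting parent; segments alternate at each cut.
    Adjacent output segments with the same founder key are coalesced, so the
    result is always maximal.
    """
    srcs = (hA, hB)
    out_e: list[int] = []
    out_k: list[int] = []
    s1 = 0
    cur = phase
    prev = 0
    idx = [0, 0]
    L = hA[0][-1]
    for cut in (*cuts, L):
        ends, keys, _ = srcs[cur]
        i = idx[cur]
        while ends[i] <= prev:
            i += 1
        while ends[i] < cut:
            e = ends[i]
            k = keys[i]
            if out_k and out_k[-1] == k:
                out_e[-1] = e
            else:
                out_e.append(e)
                out_k.append(k)
            if src_is_s1[k >> 1]:
                s1 += e - prev
            prev = e
            i += 1
        k = keys[i]
        if out_k and out_k[-1] == k:
            out_e[-1] = cut
        else:
            out_e.append(cut)
            out_k.append(k)
        if src_is_s1[k >> 1]:
            s1 += cut - prev
        prev = cut
        idx[cur] = i
        cur = 1 - cur
    return (out_e, out_k, s1)


def meiosis_gamete(haps, chrom, rng, src_is_s1=None):
    """Produce one gamete from one or two parental haplotypes.

    A single haplotype (male X) is transmitted intact.  For a pair, the
    crossover count is Poisson in the genetic length (Morgans), positions are
    uniform in genetic distance (hence uniform in bp under the constant
    per-chromosome rate), and the starting parent is a fair coin flip.
    """
    if len(haps) == 1:
        return haps[0]
    hA, hB = haps
    if src_is_s1 is None:
        src_is_s1 = _SourceLookup()
    k = rng.poisson(chrom.length_morgans)
    phase = int(rng.integers(2))
    if k == 0:
        return (hA, hB)[phase]
    pos = rng.integers(1, chrom.length_bp, size=k)
    if k == 1:
        cuts = [int(pos[0])]
    else:
        cuts = sorted(set(pos.tolist()))
    return _recombine(hA, hB, cuts, phase, src_is_s1)


class _SourceLookup:
    """Permissive source lookup for standalone meiosis calls (all S2)."""

    def __getitem__(self, fid):
        return False


# ---------------------------------------------------------------------------
# individuals


class Individual:
    __slots__ = ("id", "sex", "haps", "anc", "mother", "father")

    def __init__(self, id, sex, haps, anc, mother="", father=""):
        self.id = id
        self.sex = sex
        self.haps = haps  # list over chromosomes of tuples of haplotypes
        self.anc = anc  # autosomal S1 fraction
        self.mother = mother
        self.father = father


def _auto_anc(haps, chroms):
    """cM-weighted autosomal S1 fraction from cached per-haplotype s1_bp."""
    num = 0.0
    den = 0.0
    for ci, ch in enumerate(chroms):
        if ch.is_x:
            continue
        for h in haps[ci]:
            num += h[2] * ch.rate_cm_per_mb
            den += h[0][-1] * ch.rate_cm_per_mb
    return num / den if den else float("nan")


class FounderRegistry:
    """Grows the founder-id space and remembers each founder's source."""

    def __init__(self):
        self.src_is_s1: list[bool] = []

    def new(self, is_s1: bool) -> int:
        self.src_is_s1.append(bool(is_s1))
        return len(self.src_is_s1) - 1


def make_migrant(reg: FounderRegistry, chroms, sex: str, is_s1: bool, id_: str) -> Individual:
    fid = reg.new(is_s1)
    haps = []
    for ch in chroms:
        if ch.is_x and sex == "M":
            haps.append((founder_haplotype(ch.length_bp, 2 * fid, is_s1),))
        else:
            haps.append(
                (
                    founder_haplotype(ch.length_bp, 2 * fid, is_s1),
                    founder_haplotype(ch.length_bp, 2 * fid + 1, is_s1),
                )
            )
    return Individual(id_, sex, haps, 1.0 if is_s1 else 0.0)


def _batched_gametes(parents, ci, ch, rng, src_is_s1):
    """One gamete per parent for one chromosome, with batched RNG draws.

    Every parent must carry two haplotypes on this chromosome (mothers
    always; fathers on autosomes).
    """
    n = len(parents)
    ks = rng.poisson(ch.length_morgans, n)
    phases = rng.integers(0, 2, n)
    total = int(ks.sum())
    flat = rng.integers(1, ch.length_bp, size=total) if total else None
    out = []
    off = 0
    for j in range(n):
        hA, hB = parents[j].haps[ci]
        k = ks[j]
        if k == 0:
            out.append(hA if phases[j] == 0 else hB)
            continue
        if k == 1:
            cuts = [int(flat[off])]
        else:
            cuts = sorted(set(flat[off:off + k].tolist()))
        off += k
        out.append(_recombine(hA, hB, cuts, int(phases[j]), src_is_s1))
    return out


def mate(mother: Individual, father: Individual, sex: str, rng, src_is_s1, chroms, id_="") -> Individual:
    """One offspring of a given couple (used by the generation loop and tests)."""
    haps = []
    for ci, ch in enumerate(chroms):
        mg = meiosis_gamete(mother.haps[ci], ch, rng, src_is_s1)
        if ch.is_x:
            if sex == "M":
                haps.append((mg,))
            else:
                haps.append((mg, father.haps[ci][0]))
        else:
            pg = meiosis_gamete(father.haps[ci], ch, rng, src_is_s1)
            haps.append((mg, pg))
    child = Individual(id_, sex, haps, 0.0, mother.id, father.id)
    child.anc = _auto_anc(haps, chroms)
    return child


# ---------------------------------------------------------------------------
# assortative mating


def mate_assortative(mother_anc, father_anc, rho, rng):
    """Pair parent pools so spousal ancestries correlate at about ``rho``.

    Mothers are sorted by ancestry and matched against fathers ordered by
    ancestry rank plus Gaussian rank noise; the noise scale is calibrated by
    bisection on the realised Pearson correlation.  Returns ``(pairs, r)``
    where ``pairs`` is an array of (mother_index, father_index) rows and
    ``r`` the realised correlation (NaN when either pool is degenerate).
    """
    am = np.asarray(mother_anc, dtype=float)
    af = np.asarray(father_anc, dtype=float)
    n = len(am)
    if n == 0 or len(af) != n:
        raise ValueError("parent pools must be non-empty and of equal length")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    if am.std() < 1e-12 or af.std() < 1e-12:
        perm = rng.permutation(n)
        return np.column_stack([np.arange(n), perm]), float("nan")
    if rho == 0:
        perm = rng.permutation(n)
        r = float(np.corrcoef(am, af[perm])[0, 1])
        return np.column_stack([np.arange(n), perm]), r

    order_m = np.argsort(am, kind="stable")
    rank_f = np.empty(n)
    rank_f[np.argsort(af, kind="stable")] = np.arange(n) / n
    noise = rng.standard_normal(n)

    def realised(sigma):
        order_f = np.argsort(rank_f + sigma * noise, kind="stable")
        r = float(np.corrcoef(am[order_m], af[order_f])[0, 1])
        return order_f, r

    lo, hi = 0.0, 1.0
    order_f, r_lo = realised(lo)
    if r_lo <= rho:  # even perfect rank matching cannot exceed rho
        pairs = np.column_stack([order_m, order_f])
        return pairs, r_lo
    _, r_hi = realised(hi)
    while r_hi > rho and hi < 1e4:
        hi *= 4.0
        _, r_hi = realised(hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        order_f, r_mid = realised(mid)
        if abs(r_mid - rho) < 0.005:
            break
        if r_mid > rho:
            lo = mid
        else:
            hi = mid
    order_f, r = realised(0.5 * (lo + hi))
    pairs = np.column_stack([order_m, order_f])
    return pairs, r


# ---------------------------------------------------------------------------
# the generation loop


@dataclass
class SimTruth:
    """Ground truth emitted by :func:`simulate`.

    ``individuals`` describes every emitted sample (its true autosomal S1
    ancestry and its parents' ancestries); ``couples`` lists every mating pair
    with both spousal ancestries; founder segments are available per sample
    through :meth:`founder_segments`.
    """

    individuals: pd.DataFrame
    couples: pd.DataFrame
    founder_source: dict[int, str]
    gmap: GeneticMap
    _haps: dict[str, list] = field(repr=False, default_factory=dict)
    _sex: dict[str, str] = field(repr=False, default_factory=dict)

    def founder_segments(self, samples: Iterable[str] | None = None) -> pd.DataFrame:
        """Tidy per-haplotype founder-segment intervals."""
        rows = []
        ids = list(samples) if samples is not None else sorted(self._haps)
        chroms = self.gmap.chromosomes
        for sid in ids:
            for ci, ch in enumerate(chroms):
                for hi, hap in enumerate(self._haps[sid][ci]):
                    start = 0
                    for e, k in zip(hap[0], hap[1]):
                        rows.append((sid, hi, ch.name, start, e, k >> 1, k & 1))
                        start = e
        return pd.DataFrame(
            rows,
            columns=["sample", "hap", "chrom", "start", "end", "founder", "founder_hap"],
        )


@dataclass
class SimResult:
    tracts: AncestryTractSet
    samples: SampleTable
    truth: SimTruth


def _fill_parent_pool(n_slots, s1, s2, prev_pool, sex, reg, chroms, rng, t, pop, founding_pool=None):
    """Fill mother/father slots with fresh migrants or previous-generation residents."""
    u = rng.random(n_slots)
    if founding_pool is not None:
        idx = rng.integers(len(founding_pool), size=n_slots)
        return [founding_pool[i] for i in idx]
    if prev_pool:
        res_idx = rng.integers(len(prev_pool), size=n_slots)
    pool = []
    mcount = 0
    for j in range(n_slots):
        if u[j] < s1:
            pool.append(make_migrant(reg, chroms, sex, True, f"{pop}_m{t}{sex}{mcount}"))
            mcount += 1
        elif u[j] < s1 + s2 or not prev_pool:
            pool.append(make_migrant(reg, chroms, sex, False, f"{pop}_m{t}{sex}{mcount}"))
            mcount += 1
        else:
            pool.append(prev_pool[res_idx[j]])
    return pool


def simulate(config: SimConfig) -> SimResult:
    """Run the forward model and emit tracts, sample metadata and truth.

    Deterministic given ``config.seed``: identical configs give byte-identical
    output tables.
    """
    rng = np.random.default_rng(config.seed)
    gmap = config.gmap
    chroms = gmap.chromosomes
    reg = FounderRegistry()
    sched = config.schedule
    N = config.N
    n_pairs = N // 2
    if n_pairs < 2:
        raise ValueError("N too small for pairing")
    pop = config.population

    founding_f = founding_m = None
    if config.n_founders is not None:
        nf = max(1, config.n_founders // 2)
        split_f = sched.s1f[0] / (sched.s1f[0] + sched.s2f[0])
        split_m = sched.s1m[0] / (sched.s1m[0] + sched.s2m[0])
        uf = rng.random(nf)
        um = rng.random(nf)
        founding_f = [
            make_migrant(reg, chroms, "F", uf[i] < split_f, f"{pop}_f0F{i}") for i in range(nf)
        ]
        founding_m = [
            make_migrant(reg, chroms, "M", um[i] < split_m, f"{pop}_f0M{i}") for i in range(nf)
        ]

    females: list[Individual] = []
    males: list[Individual] = []
    couples_rows = []
    population_now: list[Individual] = []

    for t in range(1, sched.G + 1):
        s1f, s1m = sched.s1f[t - 1], sched.s1m[t - 1]
        s2f, s2m = sched.s2f[t - 1], sched.s2m[t - 1]
        mothers = _fill_parent_pool(
            n_pairs, s1f, s2f, females, "F", reg, chroms, rng, t, pop,
            founding_pool=founding_f if t == 1 else None,
        )
        fathers = _fill_parent_pool(
            n_pairs, s1m, s2m, males, "M", reg, chroms, rng, t, pop,
            founding_pool=founding_m if t == 1 else None,
        )
        pairs, _r = mate_assortative(
            [m.anc for m in mothers], [f.anc for f in fathers], config.rho, rng
        )
        couples = [(mothers[i], fathers[j]) for i, j in pairs]
        for mo, fa in couples:
            couples_rows.append((t, mo.id, fa.id, mo.anc, fa.anc))

        src = reg.src_is_s1
        child_sex = np.where(rng.random(N) < config.sex_ratio, "F", "M")
        pick = rng.integers(n_pairs, size=N)
        width = len(str(N))
        child_mothers = [couples[p][0] for p in pick]
        child_fathers = [couples[p][1] for p in pick]
        child_haps = [[] for _ in range(N)]
        for ci, ch in enumerate(chroms):
            mat = _batched_gametes(child_mothers, ci, ch, rng, src)
            if ch.is_x:
                for j in range(N):
                    if child_sex[j] == "M":
                        child_haps[j].append((mat[j],))
                    else:
                        child_haps[j].append((mat[j], child_fathers[j].haps[ci][0]))
            else:
                pat = _batched_gametes(child_fathers, ci, ch, rng, src)
                for j in range(N):
                    child_haps[j].append((mat[j], pat[j]))
        population_now = []
        for j in range(N):
            child = Individual(
                f"{pop}_g{t}_{j:0{width}d}", child_sex[j], child_haps[j],
                0.0, child_mothers[j].id, child_fathers[j].id,
            )
            child.anc = _auto_anc(child.haps, chroms)
            population_now.append(child)
        females = [c for c in population_now if c.sex == "F"]
        males = [c for c in population_now if c.sex == "M"]
        if not females or not males:
            raise RuntimeError("a generation ended up single-sex; increase N")

    emitted = population_now
    if config.n_sample is not None and config.n_sample < N:
        keep = np.sort(rng.choice(N, size=config.n_sample, replace=False))
        emitted = [population_now[i] for i in keep]

    # parent ancestry lookup for the emitted generation
    anc_by_id = {}
    for t, mid, fid_, manc, fanc in couples_rows:
        anc_by_id[mid] = manc
        anc_by_id[fid_] = fanc

    ind_rows = [
        (
            c.id, sched.G, c.sex, c.mother, c.father,
            anc_by_id.get(c.mother, np.nan), anc_by_id.get(c.father, np.nan), c.anc,
        )
        for c in emitted
    ]
    individuals = pd.DataFrame(
        ind_rows,
        columns=[
            "sample", "generation", "sex", "mother", "father",
            "mother_anc", "father_anc", "anc_auto",
        ],
    ).sort_values("sample", kind="mergesort").reset_index(drop=True)
    couples_df = pd.DataFrame(
        couples_rows, columns=["generation", "mother", "father", "mother_anc", "father_anc"]
    )

    src = reg.src_is_s1
    tract_rows = []
    for c in emitted:
        for ci, ch in enumerate(chroms):
            for hi, hap in enumerate(c.haps[ci]):
                start = 0
                cur_anc = None
                cur_start = 0
                for e, k in zip(hap[0], hap[1]):
                    a = "S1" if src[k >> 1] else "S2"
                    if a != cur_anc:
                        if cur_anc is not None:
                            tract_rows.append((c.id, hi, ch.name, cur_start, start, cur_anc))
                        cur_anc = a
                        cur_start = start
                    start = e
                tract_rows.append((c.id, hi, ch.name, cur_start, start, cur_anc))
    tracts = AncestryTractSet(
        pd.DataFrame(tract_rows, columns=["sample", "hap", "chrom", "start", "end", "ancestry"]),
        gmap,
    )
    samples = SampleTable(
        pd.DataFrame(
            {
                "sample": [c.id for c in emitted],
                "sex": [c.sex for c in emitted],
                "population": pop,
                "generation": sched.G,
                "mother": [c.mother for c in emitted],
                "father": [c.father for c in emitted],
            }
        )
    )
    truth = SimTruth(
        individuals=individuals,
        couples=couples_df,
        founder_source={i: ("S1" if s else "S2") for i, s in enumerate(src)},
        gmap=gmap,
        _haps={c.id: c.haps for c in emitted},
        _sex={c.id: c.sex for c in emitted},
    )
    return SimResult(tracts, samples, truth)


# ---------------------------------------------------------------------------
# truth-derived ROH and IBD


def _shared_intervals(hapA, hapB):
    """Maximal intervals where two haplotypes carry the same founder key."""
    eA, kA, _ = hapA
    eB, kB, _ = hapB
    out = []
    i = j = 0
    prev = 0
    cur_start = None
    while i < len(eA) and j < len(eB):
        e = min(eA[i], eB[j])
        same = kA[i] == kB[j]
        if same and cur_start is None:
            cur_start = prev
        if not same and cur_start is not None:
            if prev > cur_start:
                out.append((cur_start, prev))
            cur_start = None
        if not same:
            cur_start = None
        prev = e
        if eA[i] == e:
            i += 1
        if eB[j] == e:
            j += 1
    if cur_start is not None and prev > cur_start:
        out.append((cur_start, prev))
    # merge touching intervals (keys may change inside a shared run)
    merged = []
    for s, e in out:
        if merged and merged[-1][1] == s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def autozygosity_truth(truth: SimTruth, gmap: GeneticMap, samples=None) -> SegmentTable:
    """True ROH: maximal intervals where the two homologs share a founder haplotype."""
    if not truth._haps:
        raise ValueError("founder tracking missing from truth")
    rows = []
    ids = list(samples) if samples is not None else sorted(truth._haps)
    for sid in ids:
        haps = truth._haps[sid]
        for ci, ch in enumerate(gmap.chromosomes):
            pair = haps[ci]
            if len(pair) != 2:
                continue  # hemizygous male X
            for s, e in _shared_intervals(pair[0], pair[1]):
                rows.append(
                    ("ROH", sid, np.nan, "", np.nan, ch.name, s, e,
                     (e - s) * ch.rate_cm_per_mb / 1e6, "")
                )
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    if df.empty:
        df = df.astype({"start": np.int64, "end": np.int64, "cM": float})
    return SegmentTable(df, gmap)


def ibd_truth(truth: SimTruth, gmap: GeneticMap, pairs=None, samples=None) -> SegmentTable:
    """True pairwise IBD: intervals of identical founder origin, per homolog pair.

    Provide either an explicit ``pairs`` list of (sample1, sample2) or a
    ``samples`` subset (all unordered pairs within it); the pair list is the
    caller's responsibility to keep manageable (it grows quadratically).
    """
    if not truth._haps:
        raise ValueError("founder tracking missing from truth")
    if pairs is None:
        ids = sorted(samples) if samples is not None else sorted(truth._haps)
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    rows = []
    for a, b in pairs:
        if a not in truth._haps or b not in truth._haps:
            raise ValueError(f"unknown sample in pair ({a}, {b})")
        s1, s2 = (a, b) if a <= b else (b, a)
        ha, hb = truth._haps[s1], truth._haps[s2]
        for ci, ch in enumerate(gmap.chromosomes):
            for i, hA in enumerate(ha[ci]):
                for j, hB in enumerate(hb[ci]):
                    for s, e in _shared_intervals(hA, hB):
                        rows.append(
                            ("IBD", s1, i, s2, j, ch.name, s, e,
                             (e - s) * ch.rate_cm_per_mb / 1e6, "")
                        )
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    if df.empty:
        df = df.astype({"start": np.int64, "end": np.int64, "cM": float})
    return SegmentTable(df, gmap)
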