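# Methods

## The demographic model

`admixisle` models a diploid population founded by two source populations
(S1, S2) and maintained at a constant census size N of non-overlapping
generations. Generation t is produced by N/2 monogamous couples. Each
mother slot is, independently, a brand-new S1 migrant with probability
`s1f(t)`, a new S2 migrant with probability `s2f(t)`, and otherwise a
resident female drawn uniformly with replacement from generation t−1;
father slots use `s1m(t)`, `s2m(t)`. The founding generation (t = 1) has no
residents, so its parent slots are all migrants, split `s1f/(s1f+s2f)`
maternally and `s1m/(s1m+s2m)` paternally (both splits can be overridden
directly, which also permits histories in which one sex stops contributing
after the founding). Children pick a couple uniformly at random
(multinomial family sizes) and a sex with probability `sex_ratio`.

**Mating.** Couples are formed by rank-matching: mothers are ordered by
genome-wide (autosomal, cM-weighted) S1 ancestry and matched against fathers
ordered by ancestry rank plus Gaussian noise; the noise scale is calibrated
by bisection until the realised spousal Pearson correlation is close to the
target ρ (within ±0.005 internally; guaranteed within ±0.05 of ρ when the
pool has ancestry variance > 0.005 and ≥ 500 candidates). ρ = 0 is plain
random pairing; degenerate pools (no ancestry variance) are paired randomly
and the realised correlation is reported as NaN. Because migrants enter the
mating pool *before* pairing, strong ρ preferentially pairs same-source
migrants — a deliberate reading of socially structured mate choice.

**Transmission.** Meiosis uses Poisson crossovers without interference:
the crossover count is Poisson in the chromosome's genetic length (Morgans),
positions are uniform in genetic distance (equivalently in bp, since each
chromosome has a constant cM/Mb rate), and the starting homolog is a fair
coin flip. Autosomes recombine in both sexes. Daughters receive a
recombinant maternal X and the father's X intact; sons receive only the
recombinant maternal X, carried as a single haplotype. Y and mtDNA are not
modelled.

**Founder tracking.** Every migrant receives a fresh founder id; each
haplotype is a list of (end, founder-haplotype-key) segments, merged
whenever adjacent segments share a key. Ancestry tracts are the projection
of founder segments through the founder→source map, so tract ancestry and
founder identity are consistent by construction. True ROH are the maximal
intervals on which an individual's two homologs carry the same founder
haplotype; true IBD between two individuals is computed per homolog pair the
same way. This replaces ROH/IBD *detection* (a genotype-level problem that
is out of scope here) with exact truth, which is what makes the downstream
summaries testable.

**Founder effects.** `n_founders` caps the number of distinct migrants
available at founding (slots are then sampled with replacement from that
stock), creating island-style bottlenecks that inflate ROH and IBD.

## Counting conventions

Generation 1 is the first locally born cohort; its haplotypes each carry a
single ancestry (they recombine within one source). Ancestry-mixing
recombination therefore accumulates from generation 2 on, and a population
observed at simulator generation G has experienced G − 1 rounds of it. The
ancestry recursions index the founding cohort as g = 1 and match the
simulator generation for generation. The LAD recursion's `g` instead counts
decay rounds — `expected_lad(c, g, …)` equals `(1−c(1−ρ))^g` at m = 0 — so a
fit to simulator data at generation G is expected to centre on G − 1. The
timing-recovery tests use the tolerance band accordingly.

## LAD and admixture dating

LAD is measured on phased tracts as the Pearson correlation, across all
haplotypes, of the S1 indicator at the two anchors of a sliding window
(default 10 Mb long, successive windows sharing 1 Mb, i.e. a 9-Mb step;
`step_mb` switches to any other stepping, e.g. a dense 1-Mb slide).
Correlation rather than covariance is the primary statistic because it is
scale-free and matches the fitting model's normalised recursion; the
covariance is reported alongside for diagnostics. Anchors with zero
ancestry variance are dropped and logged. Windows are restricted to
autosomes.

The fit minimises, over integer g in [5, 25], the sum of squared
differences between per-window LAD and the model expectation, converting
window genetic distances to recombination fractions with the Haldane map
function `c = (1 − e^{−2d})/2`. Ties break toward smaller g; a best fit on
the grid boundary raises a warning. An optional bootstrap over windows
gives a percentile interval. The migration bookkeeping splits the scalar
rate m between sources in proportion to the starting ancestry H0, which
keeps the mean ancestry stationary; the cross-homolog coupling enters as
`ρ·D_t`, a form chosen because it is exact at both ρ = 0 (decay `(1−c)^g`)
and ρ = 1 (no decay) and is validated against the forward simulator on a
lattice of intermediate parameter sets rather than assumed.

Generations convert to calendar dates with a 25-year point estimate and a
20–30-year envelope before the sampling year.

## Assortment test

Each phased haplotype of an individual is one parental gamete, so the S1
genetic fraction of haplotype k on one chromosome is a moment estimator of
that parent's ancestry; chromosomes are analysed independently because
matching haplotypes across chromosomes to the same physical parent is not
possible from phase alone. Per chromosome, the spousal correlation is
Pearson R on the symmetrised pair set {(a1,a2)} ∪ {(a2,a1)} (parent labels
are arbitrary; the ordered R is also reported, and symmetrisation is
switchable). The population statistic is the median R across chromosomes.
Significance comes from B permutations of the a2 column across individuals
within each chromosome, with the add-one-corrected two-sided p-value
`(1 + #{|R_perm| ≥ |R_obs|})/(1 + B)`; B ≥ 100 is enforced and the shuffle
stream is seeded. The estimate is attenuated relative to the simulated ρ
(gamete sampling noise and shrinking ancestry variance), and it is this
attenuated estimate that is passed downstream to the timing fit — the same
plumbing used on real data.

## Sex-bias model

The autosomal and X ancestry recursions under constant contributions are

    H_g   = ½(s1f + hf·H_{g−1}) + ½(s1m + hm·H_{g−1})
    HXf_g = ½(s1f + hf·HXf_{g−1}) + ½(s1m + hm·HXm_{g−1})
    HXm_g =   s1f + hf·HXf_{g−1}

with hybrid fractions `hf = 1−s1f−s2f`, `hm = 1−s1m−s2m` and source-only
founding as above. The population X ancestry pools sexes by X dosage —
`(2·pf·HXf + (1−pf)·HXm)/(1+pf)` with pf the proportion of females in the
sample. Inference enumerates every lattice point of the four contributions
(default increment 0.02; per-sex sums constrained to (0, 1]), scores each by
the Euclidean distance between predicted and observed (autosomal, X)
ancestry, and retains the smallest 0.1% (count rounded up; ties at the
cutoff broken lexicographically for determinism). Sex bias is summarised by
the retained distributions of `f1 = s1f/(s1f+s1m)` and `f2 = s2f/(s2f+s2m)`
(undefined and excluded when a source contributes nothing). Observed X
ancestry supplied to the grid should be dosage-pooled
(`ancestry_stats.pooled_ancestry`), matching the model's pooling.

## ROH and IBD summaries

Two ROH length classifications are provided. The mixture scheme fits a
3-component Gaussian mixture to log10(length in bp) (k-means
initialisation, 20 restarts, fixed seed) and places class boundaries at the
density intersections between adjacent ordered components, falling back to
the midpoint of the component means when the densities do not cross between
them; it refuses fewer than 50 segments or degenerate lengths. The fixed
scheme cuts at a single boundary; `boundary_from_generations(g)` supplies
the principled default via the rule of thumb that m meioses give a mean IBD
segment length of 100/m cM, with m = 2g for common ancestors g generations
back — 2.5 Mb at g = 20 under the baseline 1 cM/Mb rate.

Per-individual class totals are exact partitions of total ROH length.
Ancestry switches inside ROH are tract boundaries strictly inside the
segment where the ancestry actually changes, collected over both homologs
and deduplicated by position (inside an autozygous segment the homologs are
copies). Group comparisons use Mann–Whitney U with exact enumeration when
both groups have < 20 tie-free observations and the normal approximation
with continuity and tie correction otherwise; X-vs-autosome ancestry uses
the paired Wilcoxon signed-rank test (normal approximation, zeros dropped,
≥ 6 informative pairs required; the reported statistic is the smaller
signed-rank sum, SciPy's convention).

IBD totals per unordered pair drop segments below 5 cM (mirroring the
detectability floor of segment callers) and sum the rest over homolog pairs
and chromosomes. Network edges connect pairs above an absolute threshold
(default 150 cM) or in the top quantile of nonzero totals; weights carry
log10 totals. The kinship proxy is the shared autosomal cM over the four
homolog pairs divided by 4L (L the autosomal map length): 0.25 in
expectation for parent–offspring (exactly, when the parents are unrelated)
and for full sibs, halving per extra meiosis. It replaces genotype-based
kinship estimators, which need data the pipeline deliberately does not
model.

## Pipeline

`run_pipeline` chains the stages on either a simulated dataset or
user-supplied tables. Every stochastic stage derives its seed as
`sha256(master_seed:stage_name) mod 2^31`, so one master seed fixes the whole
bundle and a rerun is byte-identical. The timing stage fits with assumed
ρ = 0 and with the assortment stage's median R (clipped at 0), each with
m ∈ {0, 0.01} and H0 = 0.65 by default; the sex-bias stage uses the
dosage-pooled X ancestry and the sample's female fraction. Configs are YAML
with a versioned schema; unknown keys are errors.

## Problem sizes used in the test suite

The statistical tests run the simulator at sizes chosen so Monte-Carlo
standard errors sit well inside the asserted tolerances: simulator-vs-
recursion agreement and sex-bias recovery use two 120/100-Mb autosomes plus
a 100-Mb X at N = 1000 and N = 500 (20 replicates); timing recovery uses 22
autosomes scaled linearly from 60 to 25 Mb at N = 1000; test calibration
uses 200 null datasets of 8 × 80-Mb autosomes with 100 sampled individuals;
pedigree checks use 100 independent 1-Morgan chromosomes, where the
per-replicate SD of the sib-mating autozygous fraction (~0.025) makes the
20-replicate mean precise to ~0.006. The demo pipeline (N = 500, 22 scaled
autosomes + X, G = 20) runs in well under a minute on one core.

## What the simulator does and does not emulate

It reproduces the features the inference stages rely on: two-source
admixture over ~20 generations, constant sex-specific migrant inflow,
spousal ancestry correlation up to 0.6 and beyond, X-vs-autosome
transmission asymmetry, island founder effects, and exact founder-segment
identity. It does not model phasing or local-ancestry calling error,
genotype data, recombination-rate variation along chromosomes (each
chromosome has one constant rate; per-interval maps are an extension
point), crossover interference, overlapping generations, age structure, or
selection. Passing tests therefore demonstrate correctness of the
statistics on clean tracts with known truth, not robustness to upstream
calling error; on real data the assortment R and LAD are additionally
attenuated by tract-inference noise, and real printed rates (e.g. ancestry
switches per Mb) depend on SNP density and caller behaviour, which is why
such magnitudes are treated as direction-only here.

## Known limitations

* The parental-ancestry estimator assigns haplotype k to "a parent" per
  chromosome; it never links haplotypes across chromosomes, so only
  statistics invariant to that linkage (per-chromosome R, its median) are
  meaningful.
* The LAD fit assumes a single founding pulse plus constant migration;
  multi-wave histories will be summarised by an effective g.
* The sex-bias grid assumes contributions constant over all generations;
  time-varying schedules are simulation-only.
* Permutation and rank tests treat individuals as exchangeable; strong
  family structure in a sample (many sibs) inflates the assortment test's
  variance slightly, which is why calibration is checked on thinned samples.
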