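# Methods

This note documents the models implemented in `ibdscape`, their
assumptions, the numerical choices behind them, what the synthetic-data
generators do and do not emulate, and known limitations.

## Units and conventions

Genetic positions are centimorgans with 0-based half-open intervals; two
intervals overlap when their intersection is non-empty. All spatial-model
mathematics is carried out in Morgans and kilometres; conversion to cM
happens only at I/O boundaries. The default genome map ships 22 autosomal
genetic lengths (~35.9 Morgans total, rounded from published human linkage
maps) and is fully configurable.

## IBD segment filtering

Segment detectors are prone to false positives concentrated at problem
regions of the assembly. The filter counts, at each genomic position, the
number of overlapping segments across all pairs; positions whose count
exceeds a threshold (default 25,000, or automatically ~1.67× the
genome-wide mean coverage) become "forbidden" intervals, and intervals
closer than 0.1 cM are merged. A segment overlapping forbidden intervals
is kept only if its largest contiguous extent outside their union is at
least 3 cM — long flanking support is evidence the segment is genuine.

Numerical choices: coverage is evaluated on a regular cM grid (default
step 0.05 cM) as the computable surrogate for "every genomic position";
the flank rule requires one sufficient side (or inter-region gap), not
both — both the grid step and the flank threshold are parameters. The
filter is idempotent by construction.

Relatedness matrices L (total shared cM) and N (segment count) are built
per segment-length window — defaults [3, 10), [10, 18) and [18, ∞) cM —
with self-IBD set to zero and close-relative pairs (kinship ≥ 0.1
convention) zeroed. Regional relatedness divides the summed pairwise L by
n₁n₂ pairs for distinct strata and n(n−1)/2 within a stratum; the paper's
printed normalisation conditions only on region, but two disjoint
(region, group) strata in one region have n₁n₂ distinct pairs, which is
what we use. Estimates over fewer than a display threshold of pairs
(10,000 by convention) are reported as suppressed rather than as noisy
numbers.

Distance-binned decay curves use the bins {[0,1), [1,101), [101,201), …}
km with same-location pairs in the first bin and bin means assigned to
midpoints (51 km for [1,101)); empty bins are flagged NaN, never
zero-filled.

## Census migration model

Census microdata rows (year, age, group, birthplace, residence, weight)
for 20–30 year-olds are pooled into 30-year generations (1900–1920 →
generation 3, 1930–1950 → 2, 1960–1980 → 1). Backward transition matrices
are column-normalised including an external-inflow term, so column sums
equal the internally-born share. The composed matrix P̄ = P⁽³⁾P⁽²⁾P⁽¹⁾
accumulates all three-generation migration routes; a single-generation
variant (P̄ = P⁽³⁾) serves birth-region analyses. The relatedness metric
I_ij = Σ_k P̄_ki P̄_kj / N_k assumes constant pre-migration population
sizes and random mating within regions — deliberately coarse, capturing
the first-order effect that shared ancestral regions with small
populations generate excess coancestry.

The Mantel test permutes the *elements* of the census matrix (the variant
used for the South-to-North comparison) rather than rows and columns
jointly; the classical joint row/column permutation is available behind
`variant="rowcol"`. Permutations with correlation greater than or equal
to the observed one count as rejections (ties are conservative), so the
exhaustive p-value is bounded below by 1/n!. Exhaustive mode is limited
to 9 permuted units (9! ≈ 3.6×10⁵); larger problems use seeded random
permutations.

## Diffusion–coalescent isolation by distance

Assumptions: an unbounded, homogeneous two-dimensional habitat; constant
effective diploid density n (coalescence probability 1/(2n·dA) per
generation for co-located lineages, i.e. haploid deme size 2n·dA);
isotropic Gaussian dispersal with constant D; independence of segment
length and coalescence location; the Erlang segment-length law given the
coalescence time. The closed form for E[f | R] was derived from the
defining double integral using ∫ u K₂(u) du = −u K₁(u) − 2K₀(u), giving a
prefactor 1/(16πnD) and a factor 2 on the K₀ difference; it is verified
against adaptive double quadrature to 10⁻⁶ relative error and against the
small-R expansion [ln(l_max/l_min) − (l_max−l_min)R²/4D]/(16πnD).

Expected total sharing sums 2·L_c·E[f] over chromosomes with the window
capped at each chromosome length, plus the background b. The factor 2
per chromosome follows the convention that a diploid pair carries two
independent haplotype-pair comparisons per chromosome under the model's
assumptions; the synthetic generator uses the same convention, so fitted
parameters are internally consistent.

The coalescence density p(t | R) is improper over t ∈ (0, ∞) in two
dimensions (a planar population of unbounded extent never forces
coalescence); all derived quantities integrate it against rapidly
decaying kernels and are finite.

**Fitting.** Weighted least squares between bin means and E[L | R]:
logarithmic grid initialisation (n ∈ [0.1, 100] km⁻², D ∈ [1, 1000]
km²/gen, background profiled in closed form and clipped at 0), then
Nelder-Mead refinement in (log n, log D). Deterministic. Three weighting
schemes: `"se"` (1/SE², the default), `"unit"`, and `"model"` — a
two-pass GLS in which a unit-weight fit supplies Var(bin mean) ∝
predicted mean, the compound-Poisson sampling variance of per-pair IBD
totals. The model weighting exists because per-pair totals are heavy
tailed (rare long segments dominate), so per-bin sample SEs correlate
with the bin means and 1/SE² systematically over-weights bins that by
chance drew few segments, biasing b down and D up; the two-pass GLS is
unbiased in calibration runs. With (n, D) held fixed, only b is
re-estimated — the cross-window background-prediction mode. A log-scale
objective is available behind `log_scale=True`; the default objective is
linear-scale WLS.

**Finite-genome correction.** The sliding-window construction treats the
observed segment at a locus x on a chromosome of length L as the
intersection of the infinite-genome segment (exponential extensions
Exp(2t) on either side) with [0, L], and integrates coalescence times
from t = 1 (excluding sub-generation coalescence). Per-chromosome
censored fractions are precomputed on a 96-point logarithmic t-grid with
Gauss-Legendre quadrature in the locus position and an
exponentially-substituted inner integral, so repeated evaluation during
refits is cheap. The correction reproduces the uncorrected model in the
long-chromosome/small-t_min limit to <1% and, refitted to curves
generated by the uncorrected model at realistic parameters, lowers the
density estimate while leaving the diffusion constant within a few
percent — provided the same-location bin is excluded, since at R ≈ 0 the
t < 1 mass that the correction removes is concentrated there.

**TMRCA.** Given segment length l (Morgans) and an exponential
coalescent prior with haploid size N, the posterior of the coalescence
time is Gamma(3, 2l + 1/N); the exact posterior mean 3/(2l + 1/N)
approaches the familiar 3/(2l) for large N (~8.3 generations at 18 cM).

## Discrete-pulse tract model

States of the chromosome-along Markov chain are (arrival epoch t, source
population); a lineage in an epoch-t state switches at rate t − 1 per
Morgan (one unit per post-admixture meiosis), the crossover depth k is
uniform on 1..t−1, and the restarted lineage exits into epoch v ≥ k+1
with probability m_v·∏_{k<u<v}(1 − m_u). Stationarity of the arrival
distribution under this generator is verified to machine precision.
Expected per-bin tract counts come from phase-type sojourn laws
(sub-generator restricted to the ancestry's states) with two-sided
censoring: closed-form handling of tracts touching either chromosome end.
The machinery is validated exactly against direct simulation of the chain
itself, and conserves total expected tract length per ancestry
(π(A) × genome length) to 10⁻⁶ relative.

Model families use the underscore nomenclature (one letter per source
population and one string per event, oldest first; `p` = pulse, `x` = no
migration). Present-day ancestry totals are held fixed; free parameters
are the event times plus one relative-contribution parameter per
population contributing to two events (pp: 1; pp_xp: 3; pxp_xpx: 2;
ppp_xpx: 3; pxp_xpx_xpx and xpp_pxx_xpx: 4). Pulse magnitudes are solved
from the totals youngest-first; infeasible combinations raise. A pulse at
fractional time k + f sends shares (1 − f) and f of its migrant mass to
generations k and k + 1; the founding pulse becomes full replacement at
k + 1 plus a magnitude-(1 − f) pulse at k, which realises the same linear
mass split while keeping the oldest generation fully migrant-derived.

**Fitting.** Poisson likelihood per (bin, ancestry) over non-excluded
bins — by default the bins below 11.7 cM (two bins of width 5.85 cM),
where local-ancestry false positives concentrate; predictions are still
reported for excluded bins. Brute-force grid over event times
(0.25-generation steps for single-event families, 1-generation steps
otherwise, range 1–20) and contribution splits (0.05/0.1 steps), then
Nelder-Mead refinement. Deterministic. AIC = 2k − 2ℓ and
BIC = k·ln(n) − 2ℓ with k as above and n the number of fitted
(bin, ancestry) points.

**Calendar calibration.** With a fixed onset year T, inferred admixture
time obeys g = 1 + (T_s − T)/τ, so g *grows* by one generation per τ
years of birth year; τ is estimated as 1/slope of the OLS line of g on
group mean birth year (decadal groups by default), and event times
convert to years via T = T_s − (g − 1)τ, rounded to integer years only at
the reporting layer.

**Sex bias.** Under a single admixture pulse, autosomal proportions obey
a = (m + f)/2 and X-chromosome proportions x = (m + 2f)/3, with m and f
the male and female contributor fractions per ancestry. The system is
solved by constrained least squares (SLSQP) with m, f ∈ [0, 1] per
ancestry and sum-to-one constraints when full simplexes are supplied;
with a single ancestry and an interior optimum this reduces to the exact
m = 4a − 3x, f = 3x − 2a, and infeasible unconstrained solutions pin to
the bounds (reporting the residual).

**Bootstrap.** All confidence intervals resample individuals (not
tracts) with replacement and take 2.5/97.5 percentiles; failing
replicates are dropped with a reported count; seeds make runs
reproducible. Calibration on 200 synthetic datasets (100 individuals,
mean-statistic) gives ~92–95% coverage.

## Synthetic-data generators

Every generator is a pure function of its arguments and seed.

* **Pairwise IBD**: segment counts are Poisson with the exact
  per-chromosome intensity implied by the model's length-density marginal
  q(l) (Bessel-K₂ form for R > 0, 1/(16πnDl) at R = 0), and lengths are
  drawn ∝ q(l)/l by inverse-CDF on a log grid, so the mean total shared
  length matches the analytic expectation *exactly* — no time-truncation
  knob is needed because the improper coalescence density is never
  sampled directly. Higher moments are implementation-defined (compound
  Poisson); the resulting per-pair totals are heavy tailed, which is why
  the model-variance GLS weighting exists. The background channel adds
  distance-independent segments with the R = 0 length shape and mean
  total b.
* **Cohort IBD** emulates a clinic-structured sampling design: all pairs
  at the same clinic-pair distance share a sampler; ground-truth
  parameters are returned alongside.
* **Wright–Fisher tracts**: forward simulation of N monoecious diploids
  (random mating, selfing excluded, constant size), per-meiosis
  recombination as a Poisson process of rate 1 per Morgan per chromosome,
  migrants entering per the discretized pulse schedule as pure-ancestry
  diploids. Output tracts tile chromosomes exactly.
* **Census tables**: Poisson-weighted counts around per-route
  intensities, with ground truth retained.
* **Hotspot injection** appends short spurious segments covering a target
  interval between random pairs (the injected segments are the trailing
  entries of the returned list).
* **Birth-year cohorts**: g = 1 + (year − onset)/τ plus Gaussian noise.
  A per-group noise of 0.25 generations reproduces the r² ≈ 0.88 observed
  for decadal birth-year groups; under that noise the τ estimator is
  unbiased with ~15% sampling spread for six groups.

What the generators do **not** emulate: genotypes or sequences, detector
error processes (the background term stands in for false positives),
realistic geography, population growth, assortative mating, or
phase-switch errors. Passing recovery tests therefore demonstrates
estimator correctness under the model's own assumptions, not robustness
to real-data artefacts.

## Problem sizes used in the test suite

Calibration experiments are sized to run on a single CPU in minutes: the
closed-form/quadrature comparison uses a 100-point parameter grid;
decay-curve recovery uses 5,000 pairs per bin across 59 bins (5-km bins
over 0–250 km — chosen to resolve the decay scale sqrt(D/l_min) ≈ 22 km,
which 100-km bins cannot — plus 100-km bins to 1,000 km) over 50 seeds;
the Wright–Fisher cross-validation uses 50 sampled diploid genomes on a
2.93-Morgan chromosome from a population of 2,000; bootstrap calibration
uses 200 datasets of 100 individuals.

## Known limitations

* The Markov tract model redraws the ancestor independently at every
  switch, whereas the true pedigree process alternates between the same
  two ancestor haplotypes at each meiosis. The approximation is excellent
  for minority ancestries and moderate-to-large g, but it is structurally
  biased for recent admixture: at g = 2 the exact probability of a
  whole-chromosome tract is α² + α(1−α)e^(−L) + … versus the Markov
  model's α·e^((g−1)(1−α)L); at large simulated sample sizes (10⁴
  haplotypes) the per-bin deviation from forward Wright–Fisher simulation
  reaches many Monte-Carlo standard errors, concentrated in the shortest
  bins and the whole-chromosome bin of the majority ancestry. Fitted
  times inherit a corresponding (small, g-dependent) bias.
* The isolation-by-distance model assumes spatial homogeneity; the
  background term absorbs both detector false positives and genuinely
  distance-independent coancestry, and the two cannot be separated.
* The census relatedness metric ignores population growth, differential
  fertility and within-region structure; it is a first-order comparator
  for Mantel testing, not a demographic inference.
* Segment-length windows treat detection as perfect above the length
  threshold; no power model is applied.
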