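# ibdscape

Spatial and temporal structure of genetic relatedness in admixed
populations: identity-by-descent (IBD) relatedness summaries with hotspot
filtering, a census-migration coalescent relatedness model, an analytical
diffusion–coalescent isolation-by-distance model, and discrete-pulse
admixture tract dating with calendar calibration — plus synthetic-data
generators so every stage can be exercised without access-controlled cohort
data.

The package is aimed at population geneticists analysing geographically
distributed genotype cohorts (e.g. African-American cohorts shaped by the
Great Migration), where both fine-scale isolation-by-distance and
large-scale historical migrations leave signatures in IBD sharing and
local-ancestry tract lengths.

## The models

**Isolation by distance.** Parent–offspring displacement is an isotropic
planar random walk with diffusion constant *D* (km²/generation) in a
population of effective diploid density *n* (km⁻²). The coalescence-time
density of two lineages sampled a distance *R* apart is

    p(t | R) = exp(−R² / 8Dt) / (16π n D t),

and with the Erlang law p(l | t) = (2t)² l e^(−2tl) for the length of the
IBD segment spanning a locus, the expected genome fraction shared through
segments with length in [l_min, l_max] (Morgans) has the closed form

    E[f | R] = [2(K₀(u₀) − K₀(u₁)) + u₀K₁(u₀) − u₁K₁(u₁)] / (16π n D),

with u_i = R·sqrt(l_i / D) and K_α the modified Bessel functions of the
second kind. Summing over chromosomes (capping l_max at each chromosome
length) and adding a distance-independent background *b* gives the expected
total shared length E[L | R] in cM, which is fitted to distance-binned IBD
data by weighted least squares. The per-generation RMS displacement is
sqrt(4D).

**Census relatedness.** Weighted census migration counts m_ij^(g)
(origin i → destination j, 30-year generations) are column-normalised into
backward ancestry probabilities P^(g), composed across generations
(P̄ = P⁽³⁾P⁽²⁾P⁽¹⁾), and converted into a symmetric relatedness metric
I_ij = Σ_k P̄_ki P̄_kj / N_k, comparable to the genomic relatedness matrix;
agreement is tested by an element-permutation Mantel test.

**Admixture tract dating.** Local-ancestry tract lengths are modelled by a
continuous-time Markov chain along the chromosome whose states are
(migrant-arrival epoch, source population), with switch rate t − 1 per
Morgan out of an epoch-t state and phase-type tract-length laws censored at
both chromosome ends. Discrete-pulse histories (`pp`, `pp_xp`,
`pxp_xpx_xpx`, ...) are fitted by Poisson maximum likelihood on binned
tract counts, compared by AIC/BIC, and converted to calendar years through
T = T_s − (g − 1)τ with the generation time τ calibrated by regressing
inferred admixture time on birth year.

## Worked example

Simulate a decay curve at the southern-cohort fit parameters
(n = 2.8 km⁻², D = 88.6 km²/gen, b = 0.0389 cM; 5,000 pairs per distance
bin) and refit it:

```python
import numpy as np
from ibdscape import (DiffusionParams, IbdDecayModel, simulate_decay_curve,
                      tmrca_expected, admixture_calendar_year)

truth = DiffusionParams(n=2.8, D=88.6, b=0.0389)
edges = np.concatenate([[0.0, 1.0], np.arange(6.0, 252.0, 5.0),
                        np.arange(301.0, 1002.0, 100.0)])
curve = simulate_decay_curve(truth, edges, 5000, window=(0.18, np.inf), seed=42)
res = IbdDecayModel(curve, window=(0.18, np.inf)).fit(weights="model")
print(res.summary())
```

```
Isolation-by-distance diffusion fit
===================================
  window              : [0.18, inf] Morgans
  density n           : 2.784 / km^2
  diffusion D         : 91.12 km^2/generation
  background b        : 0.03548 cM
  rms displacement    : 19.1 km/generation
  weighted SSR        : 0.638962
  bins used           : 59
  (n, D) fixed        : False
  converged           : True
```

The fit recovers the generating density and diffusion constant within a few
percent; the implied RMS displacement (~19 km/generation) is the local
migration scale. Two companion one-liners:

```python
>>> tmrca_expected(0.18, 1e6)          # 18 cM segments: recent ancestors
8.33        # generations
>>> admixture_calendar_year(1939.8, 5.8, 27.4)
1808.28     # calendar year of the first admixed generation
```

A command-line layer mirrors the library (`ibdscape ibd filter`,
`ibdscape census mantel`, `ibdscape spatial fit`, `ibdscape tracts fit`,
`ibdscape simulate cohort`, ...); see `ibdscape --help`.

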