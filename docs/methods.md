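# Methods

## The model

Populations live through discrete, non-overlapping generations in a hatching
environment that is either normoxia (`N`, encoded 0) or anoxia (`A`, encoded
1).  Offspring carry one of two phenotypes.  The normoxia-adapted phenotype
is the reference and has fitness 1 in both environments.  The anoxia-adapted
phenotype has fitness `exp(x_A) >= 1` when hatching in anoxia and
`exp(-x_N) <= 1` when hatching in normoxia, with `x_A, x_N >= 0` the log
fitness gain and loss.

A genotype is a maternal strategy:

* **NONE** — no maternal effect; every brood is normoxia-adapted.
* **DME** — deterministic maternal effect (anticipatory / transgenerational
  plasticity); the whole brood gets the phenotype suited to the environment
  the mother did *not* hatch in.
* **RME** — randomizing maternal effect (diversifying bet-hedging); a fixed
  fraction `q` of every brood is anoxia-adapted, independent of the maternal
  environment.

Because brood mates compete within one generation, a brood's reproductive
output on a maternal-to-offspring environment transition `(i, j)` is the
arithmetic phenotype mixture `w_k(i, j) = f w_anox(j) + (1 - f)`, where `f`
is the brood's anoxia-adapted fraction.  Across generations the right
average is geometric:

```
G_k = exp( Σ_{i,j} p(i,j) · log w_k(i,j) )
```

with `p(i, j)` the frequencies of maternal environment `i` followed by
offspring environment `j`.  `G_NONE = 1` identically; selection in a
fluctuating environment compares each strategy's `G` to that baseline.

**Optimal bet-hedging fraction.**  RME output depends only on the offspring
environment, so `G_RME(q)` depends on `p` only through the marginal
environment frequencies `(π_A, π_N)`:
`log G(q) = π_A log(1 + q a) + π_N log(1 + q b)` with
`a = w_anox(A) - 1 >= 0`, `b = w_anox(N) - 1 <= 0`.  `log G` is concave and
its first-order condition is linear in `q` after clearing denominators,
giving the closed form `q* = -(π_A a + π_N b)/(a b)` clipped by the boundary
checks (`q* = 0` when the arithmetic mean effect `π_A a + π_N b <= 0`,
`q* = 1` when the derivative at 1 is still nonnegative, and the degenerate
`a = b = 0` case tie-breaks to the ancestral `q* = 0`).  A 10^4-point grid
search is kept in the test suite as an independent oracle.

**Random fitness effects.**  `x_A` and `x_N` are independent draws from an
exponential distribution with *rate* `gamma`.  The rate parameterization is
forced by the calibration that the mean multiplicative anoxia advantage
`E[exp(x_A)] = gamma/(gamma - 1)` equals about 2 at `gamma = 2`; a
mean-parameterized exponential would make that expectation infinite.  The
two draws are independent rather than symmetric because the empirically
motivated illustration pair (2.63, 0.335) has `ln 2.63 != -ln 0.335`.  When
the ancestral advantage is enforced, draws are rejected until `x_A < x_N`
(strict inequality; ties have probability zero), which keeps the ancestral
phenotype's 50/50 geometric mean higher.  The 2-fold calibration is a
property of the raw draws; the rejection filter conditions the distribution.

## Environmental sequences

Designed sequences are balanced (equal numbers of `N` and `A`):

* *Predictable* (near-alternating): a uniformly random run-length
  decomposition produces exactly the requested number of equal adjacent
  pairs — a sequence with `r` runs has exactly `n - r` of them.  The
  60-generation design with 3 repeats has mother-offspring repeat
  probability 3/59 ≈ 0.05.
* *Unpredictable*: a seeded hill-climb over swaps of oppositely labelled
  positions (balance-preserving), with sideways moves and a 10^5-proposal
  budget, drives the adjacent equal-pair count (and optionally the
  distance-2 count) to exact targets: 27/59 ≈ 0.46, and e.g. 30/58 ≈ 0.52
  at distance 2.  Only the target statistics are reproduced, not any
  archived sequence.
* *Constant*: a block of anoxia then a block of normoxia.
* *Markov*: a symmetric two-state chain with switching probability σ; its
  stationary transition frequencies are σ/2 off-diagonal and (1 - σ)/2 on
  the diagonal, and the lag-1 autocorrelation converges to 1 - 2σ.

Lag convention: repeat probabilities are indexed by distance, so distance 1
is the mother-offspring comparison (n - 1 pairs) and distance 2 the
grandmother-offspring comparison (n - 2 pairs).  Some experimental
literature counts the generations themselves and calls these "lag two" and
"lag three"; the docstrings state the mapping once.

Diagnostics use the standard biased autocorrelation estimator (mean-centered,
lag-0 normalized) and the raw cumulative periodogram at Fourier frequencies
j/n, mean-removed, untapered, normalized to end at 1.  No taper is applied;
the periodogram is a qualitative diagnostic here, and tapering conventions
differ across packages.

## Fixation probability and Wright–Fisher simulation

The effective selection coefficient of an invader is its excess geometric
mean fitness, `s = G_mut/G_res - 1` (the resident has `G = 1`).  Fixation
probability uses the diffusion approximation

```
U = (1 - exp(-c Ne s p0)) / (1 - exp(-c Ne s))
```

with the neutral limit `U -> p0` taken analytically and both tails
overflow-safe.  The scaling constant defaults to `c = 2`: the organism
modelled is a selfing hermaphrodite, so transmission is effectively haploid;
`c = 4` (diploid-genic convention) is available as an option.  With both
invaders present at low frequency, the probability that the deterministic
allele prevails is `U_DME` when `G_DME >= G_RME` and `U_DME (1 - U_RME)`
otherwise.

Simulations use multinomial Wright–Fisher sampling: each generation the
sampling probability of genotype `k` is `freq_k w_k / Σ freq w`, and `N`
individuals are drawn.  The maternal environment is global — all mothers of
generation `t` hatched in `env_{t-1}` — so an environment sequence of
length `n_gen + 1` drives a run and no per-individual bookkeeping is
needed; this matches the experimental design, where a whole population
shares one hatching environment per generation.  Default invasion settings
are `N = Ne = 10^3` and `p0 = 0.01`; the variant that seeds both invaders
at 0.005 each is available by passing three strategies and the
corresponding initial frequencies.

**Switching-rate sweep.**  For each random fitness-effect pair and each
switching probability σ, both strategies' `G` (RME at `q*`), `s`, and `U`
are computed under the stationary transition frequencies.  Because the
stationary chain is symmetric, the marginal environment frequencies are
0.5/0.5 at every σ; `q*` and `U_RME` are therefore σ-independent (the
"constant benefit" of bet-hedging), while `U_DME` increases steeply with σ.
The sweep returns per-σ means of raw `U_DME` and `U_RME`, their per-σ
ratio, the adjusted establishment probability, and a pooled overall ratio
`mean(U_RME)/mean(U_DME)` over draws × grid.  Note the pooled ratio is
dominated by the low-σ half of the grid where `U_DME ≈ 0`, which inflates
it well above 1/10; the per-σ ratio at the fast switching rate actually
realized by the alternating regime (σ = 0.95) is ≈ 0.12, and that is the
figure the acceptance script reports as the randomizing-to-deterministic
fixation ratio.

**Known discrepancy.**  Under slow switching (σ = 0.55) with the
illustration pair and `q* ≈ 0.445`, `ln G_RME ≈ 0.097` per generation
carries an invader from logit(0.01) ≈ -4.6 to ≈ +1.2 by generation 60, and
roughly a third of replicate runs lose the allele early when the
environment delivers runs of normoxia.  The mean frequency at generation 60
over replicates is therefore ≈ 0.5 with a large spread (a published
single-run endpoint of 0.91 sits near the 75th percentile of the replicate
distribution).  The acceptance script reports the replicate mean as
computed; this is a real property of the model at these parameters, not a
numerical artifact.

## Assay analysis

Growth rate is the offspring L1 count divided by the 5,000 seeded maternal
L1s; its natural log estimates absolute fitness.  Evolved measurements are
expressed as `ln(value / ancestral block mean)` within thawing block ×
treatment cells, which cancels multiplicative block effects.  Records with
zero growth are excluded before the log with a logged count (zero growth
never occurred in the real assays; the choice only affects degenerate
synthetic inputs).  Inferential machinery is deliberately simple: cell
means with seeded nonparametric bootstrap standard errors replace
mixed-model machinery, which is routine and out of scope here.

Regime-level per-transition intervals use a *two-way cluster bootstrap*
(populations × blocks) with a `t(n_pops - 1)` multiplier.  Populations
carry independent drift histories, while the per-block ancestral means
inject noise shared across populations within a block; resampling both
cluster dimensions captures both components, and the t multiplier corrects
the small-cluster anticonservatism of plain percentile intervals (with four
populations a percentile interval covers well below nominal).

Geometric mean fitness over experienced transitions weights the two
alternating transitions 0.5/0.5 for the predictable regime and uses a
population's empirical transition frequencies for the unpredictable regime.

**Expected adaptation.**  For a candidate 12-generation sequence `s` with
per-transition relative fitness `w(i, j)`, the per-generation advantage is

```
A_s = ( Π_{t=1..12} w(env_{t-1}, env_t) )^(1/12)
```

The 12th root makes `A_s` a per-generation quantity (the raw product is
also reported).  The first generation's maternal environment uses a cyclic
boundary (`env_0 := env_12`) by default, which keeps all 2^12 sequences
distinct, makes every transition well defined, and renders `A_s` invariant
under cyclic rotation; a `prepend` boundary (duplicate the first
environment) is exposed as an option.  The full enumeration scores all
4,096 sequences and carries each sequence's normoxia frequency.  Relative
fitness inputs may be population-specific or regime-averaged; the API takes
whatever mapping the caller supplies and asserts nothing about which is
more faithful.

## Synthetic assay data

The generator mirrors the real design: 18 thawing blocks, 4 replicate
populations per regime, 3 measurements per population × treatment, with the
ancestor present in every block.  Values are
`ancestor_mean(i,j) · exp(effect + block + population + residual)` with
Normal(0, σ) effects on the log scale — log-normal because the analysis
models log growth rates — and defaults σ_block = σ_pop = 0.1, σ_res = 0.2,
chosen as moderate noise relative to effect sizes of 0.2–0.3 on the log
scale.  Default ancestor means (1.5, 0.45, 1.4, 0.55 for NN, NA, AN, AA)
encode the observation that anoxia roughly halves offspring survival while
maternal environment matters little in the ancestor; the default evolved
effects (+0.20 NN, +0.25 NA, 0.00 AN, -0.30 AA) reproduce the qualitative
pattern measured in the near-alternating regime.  Raw counts are Poisson
with mean 5,000 × rate, so dividing by the seeding count recovers a noisy
growth rate with unit variance-to-mean count dispersion.  Fecundity and
hatchability can be synthesized with the same machinery; the constraint
growth ≈ fecundity × hatchability is documented, not enforced.

What the generator does *not* emulate: selection during the assay,
frequency dependence, non-lognormal residuals, block-by-treatment
interactions, and within-brood variance structure.  Passing recovery tests
therefore show the pipeline is consistent and approximately unbiased under
its own assumptions, not that those assumptions hold for any real assay.

## Numerical choices and problem sizes

- Fixation formula: analytic neutral limit below |c Ne s| = 1e-9; the
  strongly deleterious branch switches to the asymptotic form below
  exponent -700 to avoid overflow.
- `optimal_q` is exact to floating point; the test oracle grid is 10^4+1
  points with a 1e-3 agreement tolerance.
- Swap-search budget 10^5 proposals; infeasible targets caught by a closed
  feasibility bound (a balanced length-n sequence has 0..n-2 equal adjacent
  pairs) before searching where possible.
- Default problem sizes in tests and the acceptance script: 10^6 draws for
  the exponential calibration, 2,000 fitness draws for the switching-rate
  sweep, 50–200 replicate invasions for fixation summaries, 2×10^4 neutral
  and 3×10^3 selected runs for the simulation-vs-diffusion checks, and 100
  simulated experiments for pipeline recovery.  These sizes make all checks
  stable at their stated tolerances while keeping the full suite fast.

## Limitations

- Two phenotypes, one locus, no mutation, recombination, dominance,
  overlapping generations or demographic stochasticity in N.
- RME uses a single fixed fraction `q`; environment-conditional
  randomization ("adaptive coin-flipping") is out of scope.
- The diffusion formula treats the geometric mean as a constant selection
  coefficient; under strong environmental variance in fitness it
  overestimates establishment (see the known discrepancy above).
- Mixed-model inference on assay tables is intentionally not provided.
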