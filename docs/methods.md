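# Methods

## Model

Two traits per haploid individual: signaling `s` (the green beard) and
altruism `a`, in arbitrary trait units. Phenotypes within a group of `N`
satisfy the simultaneous linear system

    z_i = a_i + e_i + Ψ Σ_{j≠i} z_j          (sum aggregation, default)
    z_i = a_i + e_i + Ψ (1/(N-1)) Σ_{j≠i} z_j (mean aggregation)

with the interaction matrix `Ψ = [[0, 0], [ψ, 0]]`: partners' signaling
phenotypes raise the focal individual's expressed altruism, with `ψ` of
either sign. Because this `Ψ` is strictly lower triangular the system is
feed-forward (signaling resolves first, altruism second) and the library
solves it in one pass; for a general 2×2 `Ψ` it performs one exact joint
linear solve over the 2N stacked unknowns per group and raises on a
singular operator. Fixed-point iteration is never used — the system is
linear, so an exact solve avoids a convergence policy.

Fitness is linear in one's own phenotype and in the summed phenotypes of
the `N-1` partners:

    W_i = α + z_iᵀ β_N + Σ_{j≠i} z_jᵀ β_S

In the green-beard configuration `β_N = (0, β_N)` with `β_N < 0` (cost of
own altruism) and `β_S = (0, β_S)` with `β_S > 0` (benefit of altruism
received). Note the fitness always sums partners' contributions; the
`sum`/`mean` switch applies only to how signaling enters phenotype
expression. Mean aggregation is algebraically the sum model with an
effective interaction `ψ/(N-1)`, which is how the analytic overlays and
the threshold are computed in that mode.

The genotypic response to selection is implemented exactly as the
interacting-phenotypes literature writes it, including the relatedness-r
form, its r = 0 specialization, and the green-beard closed form
`Δā = G β_N + (N-1) G Ψᵀ β_S` (the transposed interaction matrix is
nilpotent, which collapses the general operator inverse). The
phenotypic response is `Δz̄ = [I − (N−1)Ψ]⁻¹ Δā`; for the green-beard
interaction this is `(Δā_s, Δā_a + (N−1)ψ Δā_s)`, which is why expressed
altruism can rise while the altruism genotype declines whenever
`ψ Δā_s > 0`.

The threshold correlation `ρ_T = −β_N/((N−1)β_S ψ) · sqrt(var_a/var_s)`
may exceed 1 in magnitude, meaning no admissible genetic correlation can
rescue altruism in that parameter region; `is_evolvable` encodes that
predicate. Its sign follows `ψ`: a negative interaction requires a
negative correlation.

## Simulator

Populations hold `m·n` clonal individuals. Each generation:

1. individuals sit in `m` uniformly random groups of `n` (contiguous
   blocks of the population array);
2. phenotypes are resolved per group; optional i.i.d. normal residuals
   with `residual_sd` (default 0: the life cycle treats phenotype as
   genotype plus partners' signaling);
3. fitness is computed per the regime; values below `fitness_floor`
   (default 0) are raised to the floor and counted — negative sampling
   weights are meaningless, and the clamp count is reported so analyses
   can verify they operate in a clamp-rare regime;
4. `m·n` offspring are drawn i.i.d. with replacement with probability
   proportional to clamped fitness (uniformly if all weights are zero);
   offspring copy genotype and haplotype label exactly — no mutation, no
   recombination;
5. an i.i.d.-with-replacement draw is already exchangeable, so the
   contiguous blocks of the offspring array form uniformly random new
   groups without an extra shuffle.

Per-generation statistics (genotype means/variances/covariance and
correlation, phenotype means, haplotype count, mean clamped fitness,
clamp count) describe the *parental* generation; the response to
selection is the offspring-minus-parent difference of genotype means,
each measured before selection acts on its own generation. A
monomorphic trait reports exactly zero variance (floating-point
variance of identical values would report ~1e−34 dust) and the genetic
correlation is NaN whenever either variance is zero; tables encode that
as an empty field.

Initial genotypes are i.i.d. bivariate normal with mean 0, standard
deviation `sd0 = 1/3` in both traits and correlation `rho0`, constructed
from standard normals via `a_a = ρ x_s + sqrt(1−ρ²) x_a` so the
degenerate cases ρ = ±1 are exact. These defaults — together with
`β_N = −1`, `β_S = 1`, `ψ = 1`, groups of 15, 50 groups, 500
generations — are the reference study conditions and are not tuned per
experiment.

`α` only shifts the fitness baseline; the model leaves its scale free.
The default `α = 1` keeps mean fitness near 1 at initialization so
simulated responses are directly comparable to the closed form divided
by realized mean fitness. Oracle comparisons use `α = 60`: the fitness
standard deviation at the reference conditions is ≈ 17.5 (the 14
partners' altruism phenotypes are mutually correlated through shared
group signaling, so partner sums fluctuate far more than independence
would suggest), and `α = 60` puts the floor ≈ 3.4 sd below the mean,
making clamping rarer than 1e−3 per individual. That value follows from
the variance calculation, not from fitting.

Cheater-invasion experiments evolve a population for a 500-generation
burn-in, replace one uniformly chosen individual with a cheater carrying
a fresh haplotype label and genotype `(+3·sd0, −3·sd0)` — extreme but
on-scale, and configurable — then run 500 more generations. A trial
counts as an invasion when the cheater haplotype's final frequency is at
least 0.5; fixation is the typical outcome and the majority rule covers
the rare unresolved runs, whose final frequencies are also reported.
Fixation is absorbing (clones never mutate), so the dynamics loops stop
early once a population is monomorphic; trajectory output keeps the full
length unless early stopping is requested.

## Randomness and reproducibility

Every multi-trial operation derives one child generator per trial from
the root seed plus structural indices (grid point, batch, trial) via
`SeedSequence`, so any table is reproducible bit for bit from its
manifest and trivially parallelisable. No experiment runs without a
recorded seed.

## Finite-population correction

The closed form `Δā = G β_N + (N−1) G Ψᵀ β_S` is the infinite-population
covariance `C0 = cov(a_i, W_i)` between genotype and own fitness
(Robertson–Price). In a finite population of `P = m·n`, fitness-
proportional sampling is competition for shared offspring slots, and the
expected mean change per generation is

    E[Δā] · W̄ = (1 − 1/P) C0 − ((N−1)/P) C1

where `C1 = cov(a_i, W_j)` for groupmates i ≠ j; for the green-beard
configuration

    C1_s = β_N ψ G₁₁ + β_S (G₁₂ + (N−2) ψ G₁₁)
    C1_a = β_N ψ G₁₂ + β_S (G₂₂ + (N−2) ψ G₁₂)

(an individual's beard raises its neighbours' altruism and hence their
fitness, and those neighbours compete against it). At 50 groups of 15
the correction is ≈ 2%, invisible at a few hundred Monte-Carlo trials
but ≈ 7 standard errors at 5,000. `greenbeard_response_finite` exposes
the corrected expectation; the oracle tests compare the simulated
response against it, while the pooled covariance estimator in
`mc_selection_covariance` (which pools individuals across independent
populations rather than averaging per-population covariances) is
unbiased for `C0` itself and validates the infinite-population formula
directly.

## Numerical choices

- Algebraic-equivalence tests use 1e−10 absolute tolerance on unit-scale
  inputs: pure linear algebra with one matrix inverse, no iteration.
- Singularity of the response bracket, the phenotype system and the
  phenotypic-response operator is detected via the condition number
  (reciprocal condition below machine epsilon) and raised as a named
  linear-algebra error.
- `G` must be positive semidefinite within 1e−12 slack for rounded
  inputs; the genetic correlation is NaN when a variance is 0.
- The empirical threshold crossing is located by linear interpolation
  between the two grid points bracketing the sign change of the mean
  altruism response — the response is linear in the genetic covariance,
  hence in ρ, so a line is the correct local model. A grid that does not
  bracket the crossing produces a warning and a NaN estimate.
- Monte-Carlo checks use 3-standard-error bands with empirical SEs;
  stochastic suite sizes (2,000–5,000 one-generation trials, 20
  long-term replicates, 200–400 invasion trials per grid point) were
  chosen so those bands resolve the effects under test while the whole
  suite stays desk-scale.

## What the generator does and does not emulate

The synthetic populations realize the model's own assumptions: bivariate
normal genotypes, equal-sized groups re-formed at random every
generation, clonal reproduction, constant population size, no mutation.
They do not emulate features of real populations — mutation and
recombination (which would replenish variance and loosen the
signaling–altruism linkage), diploidy, overlapping generations, variable
group sizes, assortment by signal, or between-group interactions. A
passing suite therefore certifies the algebra and the simulator against
each other under the stated assumptions, not the biological generality
of green-beard altruism.

## Known limitations

- Analytic relatedness (r > 0) responses are implemented, but the
  simulator only builds randomly formed (r = 0) groups.
- Nonlinear or epistatic indirect effects, more than two traits, and
  partner-number "dilution" exponents between the sum and mean
  aggregation extremes are out of scope.
- Long-run haplotype fixation slows as evolved signaling inflates mean
  fitness (late-stage selective differences scale like 1/W̄ under the
  summed social benefit), so with the default clamp-at-zero fitness
  policy a substantial minority of reference-condition populations still
  hold 2–3 haplotypes at generation 500; conclusions that depend on
  universal fixation by a fixed horizon are sensitive to the fitness
  normalization chosen.
- The location of the cheater-invasion-rate maximum over group size is
  likewise protocol-sensitive: under this package's documented policy
  the cheater's relative advantage declines monotonically with group
  size (its advantage grows linearly in N while mean fitness grows
  quadratically), so the sweep's maximum sits at the smallest group size
  simulated rather than at an interior group size.
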