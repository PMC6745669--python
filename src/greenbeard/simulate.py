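"""Agent-based simulator of green-beard evolution.

Populations of ``m * n`` haploid, asexual individuals carry immutable
two-trait genotypes (signaling, altruism).  Each generation the
population is shuffled into ``m`` random groups of ``n``, phenotypes are
resolved within groups (partners' beards elicit altruism), fitness is
assigned, and the next generation is drawn i.i.d. with replacement with
probability proportional to fitness.  There is no mutation and no
recombination, so offspring are exact clones, the set of haplotypes can
only shrink, and fixation is absorbing.

The heavy lifting is vectorised over plain numpy arrays; the
:class:`Population` container and :class:`Individual` records are thin
views over those arrays.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Iterator

import numpy as np

from greenbeard.core import TraitVector, _check_aggregation

__all__ = [
    "Individual",
    "SimConfig",
    "Population",
    "GenerationStats",
    "ResponseEstimate",
    "CovarianceEstimate",
    "InvasionResult",
    "init_population",
    "assign_groups",
    "step_generation",
    "run_evolution",
    "one_generation_response",
    "introduce_cheater",
    "invasion_experiment",
    "mc_selection_covariance",
]


@dataclass(frozen=True)
class Individual:
    """One haploid individual: a lineage label and its (immutable) genotype."""

    haplotype_id: int
    genotype: TraitVector


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated population.

    Defaults follow the study conditions: genotypes start bivariate
    normal with mean 0, standard deviation ``sd0 = 1/3`` in both traits
    and correlation ``rho0``; selection gradients ``beta_n = -1`` (cost
    of altruism) and ``beta_s = 1`` (benefit received); interaction
    strength ``psi = 1``.  ``alpha`` is the baseline fitness (the model
    leaves its scale free; 1 keeps mean fitness near 1).  Fitness below
    ``fitness_floor`` is clamped up to the floor before sampling and the
    clamps are counted.  ``aggregation`` chooses whether partners'
    summed or mean signaling drives altruism expression.
    """

    m: int
    n: int
    rho0: float = 0.0
    sd0: float = 1.0 / 3.0
    psi: float = 1.0
    beta_n: float = -1.0
    beta_s: float = 1.0
    alpha: float = 1.0
    residual_sd: float = 0.0
    aggregation: str = "sum"
    fitness_floor: float = 0.0
    seed: int = 0
    generations: int = 500
    stop_when_fixed: bool = False

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"number of groups m must be >= 1, got {self.m}")
        if self.n < 2:
            raise ValueError(f"group size n must be >= 2, got {self.n}")
        if not abs(self.rho0) <= 1.0:
            raise ValueError(f"|rho0| must be <= 1, got {self.rho0}")
        if not self.sd0 > 0:
            raise ValueError(f"sd0 must be > 0, got {self.sd0}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.residual_sd < 0:
            raise ValueError(f"residual_sd must be >= 0, got {self.residual_sd}")
        if self.fitness_floor < 0:
            raise ValueError(f"fitness_floor must be >= 0, got {self.fitness_floor}")
        if self.generations < 1:
            raise ValueError(f"generations must be >= 1, got {self.generations}")
        if self.seed < 0:
            raise ValueError(f"seed must be a nonnegative integer, got {self.seed}")
        _check_aggregation(self.aggregation)

    @property
    def population_size(self) -> int:
        return self.m * self.n


@dataclass
class Population:
    """m*n individuals; groups are the contiguous blocks of n rows.

    ``genotypes`` has shape (m*n, 2) with columns (signaling, altruism);
    ``haplotype_ids`` labels clonal lineages.  Individual ``i`` belongs
    to group ``i // n``.
    """

    genotypes: np.ndarray
    haplotype_ids: np.ndarray
    m: int
    n: int

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.haplotype_ids = np.asarray(self.haplotype_ids, dtype=np.int64)
        if self.genotypes.shape != (self.m * self.n, 2):
            raise ValueError(
                f"genotypes must have shape ({self.m * self.n}, 2), "
                f"got {self.genotypes.shape}"
            )
        if self.haplotype_ids.shape != (self.m * self.n,):
            raise ValueError("haplotype_ids must have one entry per individual")

    @property
    def size(self) -> int:
        return self.m * self.n

    @property
    def group_index(self) -> np.ndarray:
        return np.repeat(np.arange(self.m), self.n)

    @property
    def n_haplotypes(self) -> int:
        return int(np.unique(self.haplotype_ids).size)

    def individuals(self) -> Iterator[Individual]:
        for hid, row in zip(self.haplotype_ids, self.genotypes):
            yield Individual(int(hid), TraitVector.from_array(row))


@dataclass(frozen=True)
class GenerationStats:
    """Per-generation summary, measured on the parental population
    before selection (phenotypes and fitness are the parents' own)."""

    generation: int
    mean_a_s: float
    mean_a_a: float
    mean_z_s: float
    mean_z_a: float
    var_a_s: float
    var_a_a: float
    cov_a: float
    corr_a: float  # NaN when either genetic variance is zero
    n_haplotypes: int
    mean_fitness: float
    n_fitness_clamped: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ResponseEstimate:
    """Mean one-generation genotypic response over replicate trials."""

    mean: TraitVector
    se: TraitVector
    mean_fitness: float
    clamp_fraction: float
    trials: int


@dataclass(frozen=True)
class CovarianceEstimate:
    """Monte-Carlo estimate of cov(genotype, fitness) per trait."""

    cov: TraitVector
    se: TraitVector
    samples: int


@dataclass(frozen=True)
class InvasionResult:
    """Outcome of repeated cheater-insertion trials."""

    invasion_rate: float
    se: float
    invaded: np.ndarray  # bool per trial
    final_frequency: np.ndarray  # cheater haplotype frequency per trial
    trials: int


# ---------------------------------------------------------------------------
# RNG plumbing: every multi-trial operation derives one child generator per
# trial from (root seed material, trial index), so runs are reproducible and
# trivially parallelisable.


def _seed_material(seed) -> tuple[int, ...]:
    if seed is None:
        raise ValueError("a seed is required")
    if isinstance(seed, (int, np.integer)):
        return (int(seed),)
    return tuple(int(s) for s in seed)


def trial_rng(seed, *indices: int) -> np.random.Generator:
    """Deterministic per-trial generator from root seed material."""
    return np.random.default_rng(
        np.random.SeedSequence(list(_seed_material(seed)) + [int(i) for i in indices])
    )


# ---------------------------------------------------------------------------
# Core array kernels.


def _draw_genotypes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. bivariate normal genotypes, exact for |rho0| = 1 too."""
    p = config.population_size
    x = rng.standard_normal((p, 2))
    rho = config.rho0
    a_s = x[:, 0]
    a_a = rho * x[:, 0] + np.sqrt(max(0.0, 1.0 - rho * rho)) * x[:, 1]
    return config.sd0 * np.column_stack([a_s, a_a])


def _phenotypes(
    genotypes: np.ndarray,
    m: int,
    n: int,
    psi: float,
    weight: float,
    residual_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    z = genotypes
    if residual_sd > 0:
        z = z + residual_sd * rng.standard_normal(z.shape)
    z_s = z[:, 0].reshape(m, n)
    partner_s = z_s.sum(axis=1, keepdims=True) - z_s
    z_a = z[:, 1].reshape(m, n) + psi * weight * partner_s
    return np.column_stack([z_s.ravel(), z_a.ravel()])


def _fitness(
    z: np.ndarray, m: int, n: int, alpha: float, beta_n: float, beta_s: float
) -> np.ndarray:
    z_a = z[:, 1].reshape(m, n)
    partner_a = z_a.sum(axis=1, keepdims=True) - z_a
    return (alpha + beta_n * z_a + beta_s * partner_a).ravel()


def _step_arrays(
    genotypes: np.ndarray,
    haplotype_ids: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
):
    """One generation on raw arrays.

    Returns (offspring genotypes, offspring ids, parent phenotypes,
    clamped parent fitness, number of clamped fitness values).  Offspring
    are drawn i.i.d. with replacement, so their order is already an
    exchangeable random shuffle and the contiguous blocks of n form
    uniformly random new groups.
    """
    m, n = config.m, config.n
    weight = 1.0 if config.aggregation == "sum" else 1.0 / (n - 1)
    z = _phenotypes(genotypes, m, n, config.psi, weight, config.residual_sd, rng)
    w = _fitness(z, m, n, config.alpha, config.beta_n, config.beta_s)
    clamped_mask = w < config.fitness_floor
    n_clamped = int(clamped_mask.sum())
    w_eff = np.where(clamped_mask, config.fitness_floor, w)
    total = w_eff.sum()
    p = genotypes.shape[0]
    if total > 0:
        parents = rng.choice(p, size=p, p=w_eff / total)
    else:  # all fitness at the floor: uniform parentage
        parents = rng.integers(0, p, size=p)
    return genotypes[parents], haplotype_ids[parents], z, w_eff, n_clamped


# ---------------------------------------------------------------------------
# Public operations.


def init_population(config: SimConfig, rng: np.random.Generator) -> Population:
    """Fresh population: genotypes i.i.d. bivariate normal with mean 0,
    standard deviation ``sd0`` in both traits and correlation ``rho0``;
    every individual starts as its own unique haplotype."""
    genotypes = _draw_genotypes(config, rng)
    return Population(
        genotypes=genotypes,
        haplotype_ids=np.arange(config.population_size, dtype=np.int64),
        m=config.m,
        n=config.n,
    )


def assign_groups(
    population: Population, m: int, n: int, rng: np.random.Generator
) -> Population:
    """Reshuffle individuals into m uniformly random groups of n.

    Returns a new population whose contiguous blocks of n rows are the
    groups; between-group interactions never occur downstream.
    """
    if population.size != m * n:
        raise ValueError(
            f"population of {population.size} cannot fill {m} groups of {n}"
        )
    perm = rng.permutation(population.size)
    return Population(
        genotypes=population.genotypes[perm],
        haplotype_ids=population.haplotype_ids[perm],
        m=m,
        n=n,
    )


def step_generation(
    population: Population, config: SimConfig, rng: np.random.Generator
) -> tuple[Population, GenerationStats]:
    """Advance one generation: resolve phenotypes within groups, assign
    fitness, clamp at the floor, sample m*n clonal offspring with
    probability proportional to fitness, and regroup.

    The returned statistics describe the *parental* population (its
    genotype moments, phenotypes, fitness and haplotype count)."""
    off_geno, off_ids, z, w_eff, n_clamped = _step_arrays(
        population.genotypes, population.haplotype_ids, config, rng
    )
    stats = _make_stats(0, population, z, w_eff, n_clamped)
    return Population(off_geno, off_ids, population.m, population.n), stats


def _make_stats(
    generation: int,
    population: Population,
    z: np.ndarray,
    w_eff: np.ndarray,
    n_clamped: int,
) -> GenerationStats:
    a_s = population.genotypes[:, 0]
    a_a = population.genotypes[:, 1]
    # a monomorphic trait has exactly zero variance; np.var would report
    # rounding dust (~1e-34) which breaks the clone-bookkeeping invariant
    s_const = bool((a_s == a_s[0]).all())
    a_const = bool((a_a == a_a[0]).all())
    var_s = 0.0 if s_const else float(a_s.var())
    var_a = 0.0 if a_const else float(a_a.var())
    cov = (
        0.0
        if (s_const or a_const)
        else float(((a_s - a_s.mean()) * (a_a - a_a.mean())).mean())
    )
    corr = cov / np.sqrt(var_s * var_a) if var_s > 0 and var_a > 0 else float("nan")
    return GenerationStats(
        generation=generation,
        mean_a_s=float(a_s.mean()),
        mean_a_a=float(a_a.mean()),
        mean_z_s=float(z[:, 0].mean()),
        mean_z_a=float(z[:, 1].mean()),
        var_a_s=var_s,
        var_a_a=var_a,
        cov_a=cov,
        corr_a=float(corr),
        n_haplotypes=population.n_haplotypes,
        mean_fitness=float(w_eff.mean()),
        n_fitness_clamped=n_clamped,
    )


def run_evolution(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[GenerationStats]:
    """Evolve a fresh population for ``config.generations`` generations.

    Returns one :class:`GenerationStats` row per generation.  Fixation is
    absorbing, so with ``config.stop_when_fixed`` the trajectory is
    truncated at the first monomorphic generation."""
    rng = trial_rng(config.seed) if rng is None else rng
    pop = init_population(config, rng)
    trajectory: list[GenerationStats] = []
    for gen in range(config.generations):
        pop, stats = step_generation(pop, config, rng)
        stats = replace(stats, generation=gen)
        trajectory.append(stats)
        if config.stop_when_fixed and stats.n_haplotypes == 1:
            break
    return trajectory


def one_generation_response(
    config: SimConfig, trials: int, seed=None
) -> ResponseEstimate:
    """Mean genotypic response over independent one-generation trials.

    Each trial draws a fresh population, advances one generation and
    records the offspring-minus-parent difference of mean genotypic
    values.  Returns the per-trait mean and standard error over trials,
    with the realized mean (clamped) fitness and clamp fraction for
    diagnosing the selection regime."""
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    seed = config.seed if seed is None else seed
    deltas = np.empty((trials, 2))
    fitness_sum = 0.0
    clamped = 0
    for t in range(trials):
        rng = trial_rng(seed, t)
        genotypes = _draw_genotypes(config, rng)
        ids = np.arange(config.population_size, dtype=np.int64)
        off_geno, _, _, w_eff, n_clamped = _step_arrays(genotypes, ids, config, rng)
        deltas[t] = off_geno.mean(axis=0) - genotypes.mean(axis=0)
        fitness_sum += w_eff.mean()
        clamped += n_clamped
    mean = deltas.mean(axis=0)
    se = deltas.std(axis=0, ddof=1) / np.sqrt(trials) if trials > 1 else np.full(2, np.nan)
    return ResponseEstimate(
        mean=TraitVector.from_array(mean),
        se=TraitVector.from_array(se),
        mean_fitness=fitness_sum / trials,
        clamp_fraction=clamped / (trials * config.population_size),
        trials=trials,
    )


def introduce_cheater(
    population: Population,
    cheater_genotype: TraitVector | None,
    rng: np.random.Generator,
    sd0: float = 1.0 / 3.0,
) -> tuple[Population, int]:
    """Replace one uniformly chosen individual by a cheater.

    The cheater carries a fresh haplotype id and, by default, an
    extreme-but-on-scale genotype: signaling +3 and altruism -3 initial
    standard deviations.  Returns the modified population and the
    cheater's haplotype id.
    """
    if population.size < 1:
        raise ValueError("population is empty")
    if cheater_genotype is None:
        cheater_genotype = TraitVector(3.0 * sd0, -3.0 * sd0)
    idx = int(rng.integers(population.size))
    genotypes = population.genotypes.copy()
    ids = population.haplotype_ids.copy()
    cheater_id = int(ids.max()) + 1
    genotypes[idx] = cheater_genotype.as_array()
    ids[idx] = cheater_id
    return (
        Population(genotypes, ids, population.m, population.n),
        cheater_id,
    )


def _run_dynamics(
    genotypes: np.ndarray,
    ids: np.ndarray,
    config: SimConfig,
    generations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Lean evolution loop (no statistics), stopping early at fixation,
    which is absorbing: a monomorphic clonal population can never change."""
    for _ in range(generations):
        if (ids == ids[0]).all():
            break
        genotypes, ids, *_ = _step_arrays(genotypes, ids, config, rng)
    return genotypes, ids


def invasion_experiment(
    config: SimConfig,
    burn_in: int = 500,
    post: int = 500,
    trials: int = 200,
    seed=None,
    cheater_genotype: TraitVector | None = None,
) -> InvasionResult:
    """Probability that a cheater lineage takes over an evolved population.

    Each trial evolves a fresh population for ``burn_in`` generations,
    replaces one random individual with a cheater (high signaling, low
    altruism genotype), evolves ``post`` further generations, and
    classifies the trial as *invaded* when the cheater haplotype's final
    frequency is at least 0.5 (fixation is the typical outcome; the
    majority rule covers the rare unresolved runs).  The rate comes with
    its binomial standard error.
    """
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    seed = config.seed if seed is None else seed
    invaded = np.zeros(trials, dtype=bool)
    final_freq = np.zeros(trials)
    for t in range(trials):
        rng = trial_rng(seed, t)
        genotypes = _draw_genotypes(config, rng)
        ids = np.arange(config.population_size, dtype=np.int64)
        genotypes, ids = _run_dynamics(genotypes, ids, config, burn_in, rng)
        pop = Population(genotypes, ids, config.m, config.n)
        pop, cheater_id = introduce_cheater(pop, cheater_genotype, rng, sd0=config.sd0)
        genotypes, ids = _run_dynamics(
            pop.genotypes, pop.haplotype_ids, config, post, rng
        )
        freq = float((ids == cheater_id).mean())
        final_freq[t] = freq
        invaded[t] = freq >= 0.5
    rate = float(invaded.mean())
    se = float(np.sqrt(rate * (1 - rate) / trials))
    return InvasionResult(rate, se, invaded, final_freq, trials)


def mc_selection_covariance(
    config: SimConfig, samples: int, seed=None
) -> CovarianceEstimate:
    """Brute-force Monte-Carlo estimate of cov(genotype, own fitness).

    Draws fresh randomly grouped populations, computes every
    individual's phenotype and (unclamped) fitness, and pools all
    individuals across samples into a single covariance estimate per
    trait.  Pooling across samples keeps the estimator free of the
    O(N/(mN)) within-sample bias that the groupmate fitness covariance
    induces in per-population covariances.  The standard error is taken
    across per-sample covariances.
    """
    if samples < 1:
        raise ValueError(f"samples must be >= 1, got {samples}")
    seed = config.seed if seed is None else seed
    m, n = config.m, config.n
    weight = 1.0 if config.aggregation == "sum" else 1.0 / (n - 1)
    p = config.population_size
    sum_a = np.zeros(2)
    sum_w = 0.0
    sum_aw = np.zeros(2)
    per_sample = np.empty((samples, 2))
    for t in range(samples):
        rng = trial_rng(seed, t)
        a = _draw_genotypes(config, rng)
        z = _phenotypes(a, m, n, config.psi, weight, config.residual_sd, rng)
        w = _fitness(z, m, n, config.alpha, config.beta_n, config.beta_s)
        sum_a += a.sum(axis=0)
        sum_w += w.sum()
        sum_aw += (a * w[:, None]).sum(axis=0)
        a_c = a - a.mean(axis=0)
        per_sample[t] = (a_c * (w - w.mean())[:, None]).sum(axis=0) / (p - 1)
    total = samples * p
    pooled = (sum_aw - sum_a * (sum_w / total)) / (total - 1)
    se = (
        per_sample.std(axis=0, ddof=1) / np.sqrt(samples)
        if samples > 1
        else np.full(2, np.nan)
    )
    return CovarianceEstimate(
        cov=TraitVector.from_array(pooled),
        se=TraitVector.from_array(se),
        samples=samples,
    )
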