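"""Closed-form selection-response algebra for a two-trait green-beard model.

The model tracks two quantitative traits per individual: a *signaling*
trait (the "green beard") and an *altruistic* trait.  Individuals live in
groups of size ``N``; the signaling phenotype of an individual's social
partners enhances the expression of its altruism phenotype (an indirect
genetic effect, IGE), while selection acts on altruism twice: against it
in its bearer (nonsocial gradient ``beta_N < 0``, the cost) and for the
altruism received from partners (social gradient ``beta_S > 0``, the
benefit).

Everything here is exact linear algebra on 2-vectors and 2x2 matrices:
phenotype resolution, Lande-Arnold-style genotypic response to selection
with and without relatedness, the green-beard closed form, the threshold
genetic correlation above which altruism can increase, and the map from
genotypic to phenotypic response.  Trait order is ``(signaling, altruism)``
throughout; the green-beard interaction matrix has its single nonzero
entry in row *altruism*, column *signaling*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TraitVector",
    "InteractionMatrix",
    "GMatrix",
    "SelectionRegime",
    "GroupSpec",
    "Aggregation",
    "resolve_phenotypes",
    "compute_fitness",
    "response_general",
    "response_r0",
    "greenbeard_response",
    "greenbeard_response_finite",
    "threshold_correlation",
    "is_evolvable",
    "phenotypic_response",
]

Aggregation = Literal["sum", "mean"]

_PSD_SLACK = 1e-12  # tolerance on g12^2 <= g11*g22 for rounded inputs


def _check_aggregation(aggregation: str) -> float:
    if aggregation not in ("sum", "mean"):
        raise ValueError(f"aggregation must be 'sum' or 'mean', got {aggregation!r}")
    return aggregation


@dataclass(frozen=True)
class TraitVector:
    """Ordered pair (signaling, altruism) of real trait values.

    Used interchangeably for genotypic values ``a``, phenotypes ``z``,
    environmental residuals ``e`` and selection gradients.
    """

    s: float
    a: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.s) and math.isfinite(self.a)):
            raise ValueError(f"trait values must be finite, got ({self.s}, {self.a})")

    def as_array(self) -> np.ndarray:
        return np.array([self.s, self.a], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "TraitVector":
        s, a = arr
        return cls(float(s), float(a))


@dataclass(frozen=True)
class InteractionMatrix:
    """2x2 matrix of indirect genetic effects.

    ``entries[i, j]`` maps partners' trait ``j`` onto the focal
    individual's trait ``i``.  The green-beard form is strictly lower
    triangular: a single coefficient ``psi`` (row altruism, column
    signaling) through which partners' beards elicit altruism; ``psi``
    may be negative.
    """

    entries: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries, dtype=float)
        if arr.shape != (2, 2):
            raise ValueError(f"interaction matrix must be 2x2, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("interaction matrix entries must be finite")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "entries", arr)

    @classmethod
    def greenbeard(cls, psi: float) -> "InteractionMatrix":
        """Partners' signaling -> focal altruism, with coefficient ``psi``."""
        return cls(np.array([[0.0, 0.0], [float(psi), 0.0]]))

    @classmethod
    def zero(cls) -> "InteractionMatrix":
        return cls(np.zeros((2, 2)))

    @property
    def psi(self) -> float:
        return float(self.entries[1, 0])

    @property
    def is_greenbeard(self) -> bool:
        e = self.entries
        return e[0, 0] == 0.0 and e[0, 1] == 0.0 and e[1, 1] == 0.0


@dataclass(frozen=True)
class GMatrix:
    """Additive genetic variance-covariance matrix of the two traits."""

    g11: float  # var of signaling genotype
    g22: float  # var of altruism genotype
    g12: float = 0.0  # covariance between the two

    def __post_init__(self) -> None:
        if self.g11 < 0 or self.g22 < 0:
            raise ValueError("genetic variances must be nonnegative")
        if self.g12**2 > self.g11 * self.g22 + _PSD_SLACK:
            raise ValueError(
                f"G is not positive semidefinite: g12^2 = {self.g12 ** 2:g} "
                f"> g11*g22 = {self.g11 * self.g22:g}"
            )

    @classmethod
    def from_correlation(cls, var_s: float, var_a: float, rho: float) -> "GMatrix":
        if abs(rho) > 1:
            raise ValueError(f"|rho| must be <= 1, got {rho}")
        return cls(g11=var_s, g22=var_a, g12=rho * math.sqrt(var_s * var_a))

    @property
    def rho(self) -> float:
        """Genetic correlation; NaN when either variance is zero."""
        denom = self.g11 * self.g22
        if denom == 0:
            return math.nan
        return self.g12 / math.sqrt(denom)

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.g11, self.g12], [self.g12, self.g22]])


@dataclass(frozen=True)
class SelectionRegime:
    """Linear fitness regime W = alpha + z.beta_N + (N-1) zbar'.beta_S.

    ``beta_n`` weights the individual's own phenotype (nonsocial
    selection), ``beta_s`` weights each partner's phenotype (social
    selection), and ``alpha`` is the positive baseline fitness.
    """

    beta_n: TraitVector
    beta_s: TraitVector
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise ValueError(f"alpha must be a positive real, got {self.alpha}")

    @classmethod
    def greenbeard(
        cls, beta_n: float, beta_s: float, alpha: float = 1.0
    ) -> "SelectionRegime":
        """Costly-altruism shape: beta_N = (0, beta_n<0), beta_S = (0, beta_s>0)."""
        if not beta_n < 0:
            raise ValueError(f"green-beard nonsocial gradient must be < 0, got {beta_n}")
        if not beta_s > 0:
            raise ValueError(f"green-beard social gradient must be > 0, got {beta_s}")
        return cls(TraitVector(0.0, beta_n), TraitVector(0.0, beta_s), alpha)


@dataclass(frozen=True)
class GroupSpec:
    """Population structure: m groups of n individuals, relatedness r.

    ``aggregation`` selects how partners' signaling enters phenotype
    expression: ``"sum"`` uses the summed signal of all n-1 partners
    (altruism scales with group size), ``"mean"`` their average.
    """

    n: int
    m: int = 1
    r: float = 0.0
    aggregation: Aggregation = "sum"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group size n must be >= 2, got {self.n}")
        if self.m < 1:
            raise ValueError(f"number of groups m must be >= 1, got {self.m}")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"relatedness r must be in [0, 1], got {self.r}")
        _check_aggregation(self.aggregation)


def _as_trait_array(vectors: Sequence[TraitVector] | np.ndarray) -> np.ndarray:
    arr = np.asarray(
        [v.as_array() if isinstance(v, TraitVector) else v for v in vectors],
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected a sequence of 2-trait vectors, got shape {arr.shape}")
    return arr


def _solve(matrix: np.ndarray, rhs: np.ndarray, name: str) -> np.ndarray:
    """Linear solve that rejects singular and numerically singular operators."""
    if np.linalg.cond(matrix) > 1 / np.finfo(float).eps:
        raise np.linalg.LinAlgError(f"operator {name} is singular")
    return np.linalg.solve(matrix, rhs)


def resolve_phenotypes(
    genotypes: Sequence[TraitVector] | np.ndarray,
    residuals: Sequence[TraitVector] | np.ndarray,
    psi: InteractionMatrix,
    aggregation: Aggregation = "sum",
) -> list[TraitVector]:
    """Resolve the simultaneous phenotype system of one group.

    Each member's phenotype is its genotype plus residual plus the
    interaction term contributed by its n-1 partners' phenotypes:
    ``z_i = a_i + e_i + Psi @ sum_{j != i} z_j`` under ``"sum"``
    aggregation, or with the partner mean instead of the sum under
    ``"mean"``.  The system is solved exactly as one joint linear solve;
    for the green-beard (strictly lower triangular) interaction it is
    feed-forward, so signaling resolves first and altruism follows in a
    single pass.
    """
    _check_aggregation(aggregation)
    a = _as_trait_array(genotypes)
    e = _as_trait_array(residuals)
    n = a.shape[0]
    if n < 2:
        raise ValueError(f"a group needs at least 2 members, got {n}")
    if e.shape != a.shape:
        raise ValueError("genotypes and residuals must have the same length")
    base = a + e
    weight = 1.0 if aggregation == "sum" else 1.0 / (n - 1)
    p = psi.entries

    if psi.is_greenbeard:
        z_s = base[:, 0]
        partner_s = z_s.sum() - z_s
        z_a = base[:, 1] + weight * p[1, 0] * partner_s
        z = np.column_stack([z_s, z_a])
    else:
        # stacked 2n x 2n system: (I - coupling (x) weight*Psi) z = a + e
        coupling = np.ones((n, n)) - np.eye(n)
        system = np.eye(2 * n) - np.kron(coupling, weight * p)
        z = _solve(system, base.ravel(), "I - (N-1) Psi (stacked phenotype system)")
        z = z.reshape(n, 2)
    return [TraitVector.from_array(row) for row in z]


def compute_fitness(
    own_z: TraitVector,
    partner_zs: Sequence[TraitVector] | np.ndarray,
    regime: SelectionRegime,
) -> float:
    """Fitness of a focal individual given its partners' phenotypes.

    ``W = alpha + own_z . beta_N + sum_partners z_j . beta_S``.  The value
    may be negative; clamping is a simulator policy, not applied here.
    """
    partners = _as_trait_array(partner_zs)
    if partners.shape[0] < 1:
        raise ValueError("fitness requires at least one social partner")
    w = (
        regime.alpha
        + float(own_z.as_array() @ regime.beta_n.as_array())
        + float(partners.sum(axis=0) @ regime.beta_s.as_array())
    )
    return w


_BRACKET_NAME = "I - (N-2) Psi^T - (N-1) Psi^T Psi^T"


def _bracket_inverse_apply(psi_t: np.ndarray, n: int, vec: np.ndarray) -> np.ndarray:
    bracket = np.eye(2) - (n - 2) * psi_t - (n - 1) * psi_t @ psi_t
    return _solve(bracket, vec, _BRACKET_NAME)


def response_general(
    g: GMatrix,
    psi: InteractionMatrix,
    regime: SelectionRegime,
    spec: GroupSpec,
) -> TraitVector:
    """One-generation genotypic response to selection with relatedness r.

    Implements the general interacting-phenotypes response
    ``da = G{[I-(N-2)Psi^T] + r(N-1)Psi^T} B^-1 beta_N
          + (N-1) G (rI + Psi^T) B^-1 beta_S``
    with ``B = I - (N-2)Psi^T - (N-1)Psi^T Psi^T``.
    """
    n, r = spec.n, spec.r
    psi_t = psi.entries.T
    gm = g.matrix
    eye = np.eye(2)
    term_n = gm @ ((eye - (n - 2) * psi_t) + r * (n - 1) * psi_t) @ _bracket_inverse_apply(
        psi_t, n, regime.beta_n.as_array()
    )
    term_s = (n - 1) * gm @ (r * eye + psi_t) @ _bracket_inverse_apply(
        psi_t, n, regime.beta_s.as_array()
    )
    return TraitVector.from_array(term_n + term_s)


def response_r0(
    g: GMatrix,
    psi: InteractionMatrix,
    regime: SelectionRegime,
    spec: GroupSpec,
) -> TraitVector:
    """Genotypic response for randomly formed groups (relatedness r = 0)."""
    n = spec.n
    psi_t = psi.entries.T
    gm = g.matrix
    eye = np.eye(2)
    term_n = gm @ (eye - (n - 2) * psi_t) @ _bracket_inverse_apply(
        psi_t, n, regime.beta_n.as_array()
    )
    term_s = (n - 1) * gm @ psi_t @ _bracket_inverse_apply(
        psi_t, n, regime.beta_s.as_array()
    )
    return TraitVector.from_array(term_n + term_s)


def greenbeard_response(
    g: GMatrix, psi_scalar: float, beta_n_scalar: float, beta_s_scalar: float, n: int
) -> TraitVector:
    """Closed-form genotypic response for the green-beard configuration.

    With the single-entry interaction matrix and altruism-only selection
    gradients the general response collapses (the transposed interaction
    matrix is nilpotent) to

        da_s = (N-1) beta_S psi G11 + beta_N G12
        da_a = (N-1) beta_S psi G12 + beta_N G22

    i.e. ``G beta_N + (N-1) G Psi^T beta_S``.
    """
    if n < 2:
        raise ValueError(f"group size n must be >= 2, got {n}")
    k = (n - 1) * beta_s_scalar * psi_scalar
    return TraitVector(
        s=k * g.g11 + beta_n_scalar * g.g12,
        a=k * g.g12 + beta_n_scalar * g.g22,
    )


def greenbeard_response_finite(
    g: GMatrix,
    psi_scalar: float,
    beta_n_scalar: float,
    beta_s_scalar: float,
    n: int,
    m: int,
) -> TraitVector:
    """Expected selection differential in a finite population of m groups.

    :func:`greenbeard_response` is the infinite-population covariance
    ``C0 = cov(a_i, W_i)`` between an individual's genotype and its own
    fitness.  In a finite population of ``P = m n`` individuals the mean
    genotypic change per generation under fitness-proportional sampling
    equals the *relative-fitness* covariance, which picks up a
    competition term from the covariance ``C1 = cov(a_i, W_j)`` between a
    genotype and a groupmate's fitness (an individual's beard raises its
    neighbours' altruism and hence their fitness, and those neighbours
    compete for the same offspring slots):

        E[da] * Wbar = (1 - 1/P) C0 - ((N-1)/P) C1

    with, for the green-beard configuration,

        C1_s = beta_N psi G11 + beta_S (G12 + (N-2) psi G11)
        C1_a = beta_N psi G12 + beta_S (G22 + (N-2) psi G12)

    The correction is O(N/P) and vanishes as the number of groups grows.
    """
    c0 = greenbeard_response(g, psi_scalar, beta_n_scalar, beta_s_scalar, n).as_array()
    c1 = np.array(
        [
            beta_n_scalar * psi_scalar * g.g11
            + beta_s_scalar * (g.g12 + (n - 2) * psi_scalar * g.g11),
            beta_n_scalar * psi_scalar * g.g12
            + beta_s_scalar * (g.g22 + (n - 2) * psi_scalar * g.g12),
        ]
    )
    p = m * n
    return TraitVector.from_array((1 - 1 / p) * c0 - ((n - 1) / p) * c1)


def threshold_correlation(
    beta_n_scalar: float,
    beta_s_scalar: float,
    psi_scalar: float,
    n: int,
    var_a: float,
    var_s: float,
) -> float:
    """Minimum genetic correlation for altruism to respond positively.

    ``rho_T = -beta_N / ((N-1) beta_S psi) * sqrt(var_a / var_s)``.

    The returned value may exceed 1 in magnitude, in which case no
    admissible correlation rescues altruism in that parameter region
    (see :func:`is_evolvable`).  Sign follows the interaction: positive
    ``psi`` (with the usual ``beta_N < 0``) demands a positive
    correlation, negative ``psi`` a negative one.
    """
    if n < 2:
        raise ValueError(f"group size n must be >= 2, got {n}")
    if not (var_a > 0 and var_s > 0):
        raise ValueError("trait variances must be positive")
    denom = (n - 1) * beta_s_scalar * psi_scalar
    if denom == 0:
        raise ValueError(
            "(N-1)*beta_S*psi is zero: the indirect term vanishes and a costly "
            "altruism response cannot be rescued by any genetic correlation"
        )
    return -beta_n_scalar / denom * math.sqrt(var_a / var_s)


def is_evolvable(rho_threshold: float) -> bool:
    """Whether the threshold correlation is attainable (|rho_T| <= 1)."""
    return abs(rho_threshold) <= 1.0


def phenotypic_response(
    delta_a: TraitVector, psi: InteractionMatrix, n: int
) -> TraitVector:
    """Map a genotypic response to the phenotypic response.

    ``dz = [I - (N-1) Psi]^-1 da``.  For the green-beard interaction this
    is ``(da_s, da_a + (N-1) psi da_s)``: a rising mean beard inflates
    expressed altruism, so the phenotypic mean can rise even while the
    altruism genotype declines.
    """
    if n < 2:
        raise ValueError(f"group size n must be >= 2, got {n}")
    operator = np.eye(2) - (n - 1) * psi.entries
    z = _solve(operator, delta_a.as_array(), "I - (N-1) Psi")
    return TraitVector.from_array(z)
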