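"""Two-phenotype maternal-effect fitness model.

Offspring come in two phenotypic states: *normoxia-adapted* (the ancestral
state, assigned relative fitness 1 in both environments) and
*anoxia-adapted*, with fitness exp(x_A) > 1 when hatching in anoxia and
exp(-x_N) < 1 when hatching in normoxia.  A genotype is a maternal
strategy deciding which phenotypes a mother produces:

* ``NONE`` -- no maternal effect; all offspring normoxia-adapted.
* ``DME`` -- deterministic maternal effect (transgenerational plasticity):
  all offspring get the phenotype suited to the environment the mother did
  *not* experience, so mothers hatched in normoxia produce anoxia-adapted
  broods and vice versa.
* ``RME`` -- randomizing maternal effect (diversifying bet-hedging): a
  fixed fraction ``q`` of each brood is anoxia-adapted, regardless of the
  maternal environment.

Because all offspring of one brood compete within a single generation, the
brood's reproductive output is the *arithmetic* phenotype mixture; the
*geometric* mean applies across generations.  The long-run growth of a
genotype in a fluctuating environment is its geometric mean fitness

    G_k = exp( sum_{i,j} p(i,j) * log w_k(i,j) ),

where p(i,j) are the frequencies of maternal-environment i followed by
offspring-environment j and w_k(i,j) the corresponding reproductive output.
Log fitness effects (x_A, x_N) are modelled as independent draws from an
Exponential distribution with *rate* gamma; gamma = 2 gives a mean
multiplicative anoxia advantage of E[exp(x_A)] = gamma/(gamma-1) = 2.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .envseq import Env, TransitionFrequencies

__all__ = [
    "StrategyKind",
    "Strategy",
    "PhenotypeFitness",
    "sample_fitness_effects",
    "offspring_anoxia_fraction",
    "transition_fitness",
    "geometric_mean_fitness",
    "optimal_q",
]


class StrategyKind(str, enum.Enum):
    NONE = "none"
    DME = "dme"
    RME = "rme"


@dataclass(frozen=True)
class Strategy:
    """A genotype's maternal-effect rule; use the ``none/dme/rme`` constructors."""

    kind: StrategyKind
    q: float | None = None

    def __post_init__(self) -> None:
        kind = StrategyKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is StrategyKind.RME:
            if self.q is None or not 0.0 <= self.q <= 1.0:
                raise ValueError(f"RME requires q in [0, 1], got {self.q}")
        elif self.q is not None:
            raise ValueError(f"q is only meaningful for RME, got q={self.q} for {kind}")

    @classmethod
    def none(cls) -> "Strategy":
        return cls(StrategyKind.NONE)

    @classmethod
    def dme(cls) -> "Strategy":
        return cls(StrategyKind.DME)

    @classmethod
    def rme(cls, q: float) -> "Strategy":
        return cls(StrategyKind.RME, q=float(q))

    def __str__(self) -> str:
        if self.kind is StrategyKind.RME:
            return f"RME(q={self.q:.4g})"
        return self.kind.name


@dataclass(frozen=True)
class PhenotypeFitness:
    """Log fitness effects of the anoxia-adapted phenotype.

    ``x_anoxia >= 0`` is its log-fitness gain when hatching in anoxia and
    ``x_normoxia >= 0`` its log-fitness loss when hatching in normoxia, so
    its fitness is ``exp(x_anoxia) >= 1`` in anoxia and
    ``exp(-x_normoxia) <= 1`` in normoxia.  The normoxia-adapted phenotype
    is the fitness-1 reference in both environments.
    """

    x_anoxia: float
    x_normoxia: float

    def __post_init__(self) -> None:
        if self.x_anoxia < 0 or self.x_normoxia < 0:
            raise ValueError(
                "log fitness effects must be nonnegative; got "
                f"x_anoxia={self.x_anoxia}, x_normoxia={self.x_normoxia}"
            )

    @property
    def w_in_anoxia(self) -> float:
        """Fitness of the anoxia-adapted phenotype hatching in anoxia (>= 1)."""
        return math.exp(self.x_anoxia)

    @property
    def w_in_normoxia(self) -> float:
        """Fitness of the anoxia-adapted phenotype hatching in normoxia (<= 1)."""
        return math.exp(-self.x_normoxia)

    @classmethod
    def from_fitness_values(cls, w_in_anoxia: float, w_in_normoxia: float) -> "PhenotypeFitness":
        """Build from the two phenotype-environment fitness values themselves."""
        if not (w_in_anoxia >= 1.0 and 0.0 < w_in_normoxia <= 1.0):
            raise ValueError(
                "expected w_in_anoxia >= 1 and 0 < w_in_normoxia <= 1, got "
                f"{w_in_anoxia}, {w_in_normoxia}"
            )
        return cls(math.log(w_in_anoxia), -math.log(w_in_normoxia))

    def phenotype_fitness(self, env: Env) -> float:
        return self.w_in_anoxia if env is Env.ANOXIA else self.w_in_normoxia


def _draw_effects(
    gamma: float,
    n: int,
    rng: np.random.Generator,
    enforce_ancestral_advantage: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized exponential draws, rejection-filtered to x_A < x_N if asked."""
    x_a = rng.exponential(scale=1.0 / gamma, size=n)
    x_n = rng.exponential(scale=1.0 / gamma, size=n)
    if enforce_ancestral_advantage:
        bad = x_a >= x_n
        while bad.any():
            k = int(bad.sum())
            x_a[bad] = rng.exponential(scale=1.0 / gamma, size=k)
            x_n[bad] = rng.exponential(scale=1.0 / gamma, size=k)
            bad = x_a >= x_n
    return x_a, x_n


def sample_fitness_effects(
    gamma: float,
    rng: np.random.Generator,
    enforce_ancestral_advantage: bool = True,
) -> PhenotypeFitness:
    """Draw random log fitness effects from Exponential(rate=gamma).

    ``gamma`` is the *rate* of the exponential distribution, so the mean
    multiplicative anoxia advantage is E[exp(x_A)] = gamma/(gamma-1)
    (about 2-fold at gamma=2); it diverges for gamma <= 1, which triggers a
    warning.  With ``enforce_ancestral_advantage`` the draw is
    rejection-sampled until x_A < x_N, i.e. until the ancestral
    normoxia-adapted phenotype keeps the higher geometric mean fitness under
    50/50 environments.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    if gamma <= 1:
        warnings.warn(
            f"gamma={gamma} <= 1: the mean multiplicative fitness effect "
            "E[exp(x)] = gamma/(gamma-1) is infinite", stacklevel=2,
        )
    x_a, x_n = _draw_effects(gamma, 1, rng, enforce_ancestral_advantage)
    return PhenotypeFitness(float(x_a[0]), float(x_n[0]))


def offspring_anoxia_fraction(strategy: Strategy, maternal_env: Env) -> float:
    """Fraction of a brood carrying the anoxia-adapted phenotype.

    NONE mothers produce none; DME mothers produce an all-anoxia-adapted
    brood exactly when they themselves hatched in normoxia; RME mothers
    produce the fixed fraction q regardless of their environment.
    """
    if strategy.kind is StrategyKind.NONE:
        return 0.0
    if strategy.kind is StrategyKind.DME:
        return 1.0 if Env(maternal_env) is Env.NORMOXIA else 0.0
    return float(strategy.q)  # RME


def transition_fitness(
    strategy: Strategy,
    maternal_env: Env,
    offspring_env: Env,
    pf: PhenotypeFitness,
) -> float:
    """Reproductive output w_k(i, j) of a brood on one environment transition.

    The brood is an arithmetic phenotype mixture: a fraction ``f`` (set by
    the strategy and the maternal environment) has the anoxia-adapted
    phenotype with fitness ``pf.phenotype_fitness(offspring_env)``, the rest
    the reference fitness 1.
    """
    f = offspring_anoxia_fraction(strategy, maternal_env)
    return f * pf.phenotype_fitness(Env(offspring_env)) + (1.0 - f)


def geometric_mean_fitness(
    strategy: Strategy,
    p: TransitionFrequencies,
    pf: PhenotypeFitness,
) -> float:
    """Geometric mean fitness G_k = exp(sum p(i,j) log w_k(i,j)).

    A transition with zero reproductive output and positive weight makes
    the long-run growth rate zero; G = 0 is returned rather than raising.
    """
    acc = 0.0
    for i in Env:
        for j in Env:
            weight = p.p(i, j)
            if weight == 0.0:
                continue
            w = transition_fitness(strategy, i, j, pf)
            if w == 0.0:
                return 0.0
            acc += weight * math.log(w)
    return math.exp(acc)


def optimal_q(p: TransitionFrequencies, pf: PhenotypeFitness) -> float:
    """The bet-hedging fraction q* maximizing RME geometric mean fitness.

    RME broods do not depend on the maternal environment, so G_RME(q)
    depends on p only through the marginal offspring-environment
    frequencies (pi_A, pi_N):

        log G(q) = pi_A log(1 + q a) + pi_N log(1 + q b),

    with a = w_in_anoxia - 1 >= 0 and b = w_in_normoxia - 1 <= 0.  log G is
    concave; its derivative pi_A a/(1+qa) + pi_N b/(1+qb) is linear in q
    after clearing denominators, giving the interior optimum
    q* = -(pi_A a + pi_N b)/(a b), clipped by the boundary conditions
    (q*=0 when the arithmetic mean effect pi_A a + pi_N b <= 0; q*=1 when
    the derivative at 1 is still nonnegative).  Degenerate effects
    (a = b = 0) tie-break to q* = 0, the ancestral phenotype.
    """
    pi_a = p.marginal_offspring_anoxia
    pi_n = 1.0 - pi_a
    a = pf.w_in_anoxia - 1.0
    b = pf.w_in_normoxia - 1.0
    d0 = pi_a * a + pi_n * b  # derivative of log G at q=0
    if d0 <= 0.0:
        return 0.0
    # derivative at q=1 (denominators 1+a, 1+b are positive here since
    # d0 > 0 requires a > 0, and w_in_normoxia > 0 gives 1+b > 0)
    d1 = pi_a * a / (1.0 + a) + pi_n * b / (1.0 + b)
    if d1 >= 0.0:
        return 1.0
    return float(-d0 / (a * b))
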