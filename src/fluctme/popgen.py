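"""Fixation-probability theory and Wright-Fisher invasion simulations.

The invasion of a maternal-effect allele into a population fixed for the
no-maternal-effect ancestor is modelled two ways:

* analytically, through Kimura's diffusion approximation of the
  Wright-Fisher sampling process, with the effective selection coefficient
  taken as the excess geometric mean fitness of the invader; and
* by direct stochastic simulation: each generation, genotype frequencies
  are multiplied by the genotype's reproductive output on the current
  environment transition and the next generation of N individuals is drawn
  from the resulting multinomial distribution.

The maternal environment is global -- every mother of generation t hatched
in env_{t-1} -- so an environment sequence of length n_gen + 1 drives an
n_gen-generation run, the founding mothers hatching in env_0.

Also included: the parameter sweep over environmental switching rates that
compares deterministic and randomizing maternal-effect alleles over random
fitness-effect draws, and two closed-form diversity summaries (Fis and the
effective number of haplotypes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .envseq import Env, EnvSequence, make_markov, stationary_transition_frequencies
from .fitness import (
    PhenotypeFitness,
    Strategy,
    _draw_effects,
    geometric_mean_fitness,
    optimal_q,
    transition_fitness,
)

__all__ = [
    "PopGenParams",
    "Trajectory",
    "ExtinctionError",
    "selection_coefficient",
    "kimura_fixation_probability",
    "establishment_probability",
    "wf_step",
    "wf_simulate",
    "fixation_generation",
    "fixation_summary",
    "fixation_probability_sweep",
    "fis",
    "effective_number",
]


class ExtinctionError(RuntimeError):
    """Total reproductive output of the population hit zero."""


@dataclass(frozen=True)
class PopGenParams:
    """Population parameters for simulations and diffusion formulas.

    ``n`` is the census size used by the multinomial simulation, ``ne`` the
    effective size used in the diffusion formula, ``p0`` the invader's
    initial frequency and ``selection_scaling`` the constant c in
    Kimura's formula (2 for an effectively haploid transmission, as in a
    selfing hermaphrodite population; 4 for the diploid-genic convention).
    """

    n: int = 1000
    ne: float = 1000.0
    p0: float = 0.01
    n_gen: int = 60
    seed: int | None = None
    selection_scaling: float = 2.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"census size must be >= 2, got {self.n}")
        if self.ne <= 0:
            raise ValueError(f"effective size must be positive, got {self.ne}")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError(f"initial frequency must be in (0, 1), got {self.p0}")
        if round(self.n * self.p0) < 1:
            raise ValueError(
                f"n*p0 = {self.n * self.p0} rounds to zero founder copies"
            )
        if self.selection_scaling not in (2.0, 4.0, 2, 4):
            raise ValueError("selection_scaling must be 2 or 4")


@dataclass(frozen=True)
class Trajectory:
    """One Wright-Fisher run: per-generation environments, frequencies, output.

    ``freqs`` has shape (n_gen + 1, n_genotypes); row t are the genotype
    frequencies at generation t (row 0 the founders).  ``mean_fitness[t]``
    is the population mean reproductive output producing generation t
    (undefined, NaN, at t = 0).
    """

    envs: np.ndarray
    freqs: np.ndarray
    mean_fitness: np.ndarray
    strategies: tuple[Strategy, ...] = field(default=())
    params: PopGenParams | None = None

    @property
    def n_gen(self) -> int:
        return self.freqs.shape[0] - 1

    def final_frequency(self, genotype: int) -> float:
        return float(self.freqs[-1, genotype])


def selection_coefficient(g_mut: float, g_res: float = 1.0) -> float:
    """Effective selection coefficient s = G_mut / G_res - 1.

    The geometric mean fitness of each genotype summarizes its long-run
    growth; the invader's selection coefficient is its multiplicative excess
    over the resident (the resident ancestor has G = 1 by construction).
    """
    if g_res <= 0:
        raise ValueError(f"resident geometric mean fitness must be > 0, got {g_res}")
    return g_mut / g_res - 1.0


def kimura_fixation_probability(
    s,
    ne: float,
    p0: float,
    selection_scaling: float = 2.0,
):
    """Kimura's diffusion fixation probability, vectorized over ``s``.

    U = (1 - exp(-c Ne s p0)) / (1 - exp(-c Ne s)) with c the selection
    scaling.  The neutral limit U -> p0 is taken analytically, and both
    tails are overflow-safe: strongly beneficial alleles approach
    1 - exp(-c Ne s p0), strongly deleterious ones exp(c Ne s (1 - p0)) ~ 0.
    """
    if ne <= 0:
        raise ValueError(f"effective size must be positive, got {ne}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"initial frequency must be in (0, 1), got {p0}")
    s = np.asarray(s, dtype=float)
    a = selection_scaling * ne * s
    with np.errstate(over="ignore", invalid="ignore"):
        u = np.where(
            np.abs(a) < 1e-9,
            p0,
            np.where(
                a < -700.0,
                np.exp(a * (1.0 - p0)),
                np.expm1(-a * p0) / np.expm1(-np.where(np.abs(a) < 1e-9, 1.0, a)),
            ),
        )
    return float(u) if u.ndim == 0 else u


def establishment_probability(
    u_dme: float, u_rme: float, g_dme: float, g_rme: float
) -> float:
    """Probability that the deterministic maternal-effect allele prevails.

    With both invaders present at low frequency, whichever establishes with
    the higher geometric mean fitness wins: U_DME when G_DME >= G_RME,
    otherwise U_DME (1 - U_RME).
    """
    for name, u in (("u_dme", u_dme), ("u_rme", u_rme)):
        if not 0.0 <= u <= 1.0:
            raise ValueError(f"{name} must be a probability, got {u}")
    if g_dme >= g_rme:
        return u_dme
    return u_dme * (1.0 - u_rme)


def wf_step(
    freqs: np.ndarray,
    fitnesses: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Wright-Fisher generation: weighted multinomial resampling.

    Sampling probabilities are freq_i w_i / sum_j freq_j w_j; the next
    generation's counts are a size-``n`` multinomial draw.  Raises
    :class:`ExtinctionError` when the total reproductive output is zero.
    """
    freqs = np.asarray(freqs, dtype=float)
    fitnesses = np.asarray(fitnesses, dtype=float)
    if (fitnesses < 0).any():
        raise ValueError("fitness values must be nonnegative")
    output = freqs * fitnesses
    total = output.sum()
    if total <= 0.0:
        raise ExtinctionError("total reproductive output is zero; population extinct")
    counts = rng.multinomial(n, output / total)
    return counts / n


def wf_simulate(
    strategies: Sequence[Strategy],
    initial_freqs: Sequence[float],
    env: EnvSequence | float,
    pf: PhenotypeFitness,
    params: PopGenParams,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Simulate maternal-effect genotype frequencies through a fluctuating regime.

    ``env`` is either an explicit :class:`EnvSequence` of length
    ``params.n_gen + 1`` (or longer; generation t's mothers hatched in
    env_{t-1}) or a Markov switching probability, in which case a fresh
    sequence is drawn for the run.  Each generation applies one
    multinomial Wright-Fisher step with the genotypes' transition fitness
    values, and the population mean reproductive output is recorded.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    freqs0 = np.asarray(initial_freqs, dtype=float)
    if len(strategies) != freqs0.size:
        raise ValueError("one initial frequency per strategy is required")
    if abs(freqs0.sum() - 1.0) > 1e-9 or (freqs0 < 0).any():
        raise ValueError("initial frequencies must be nonnegative and sum to 1")
    n_env = params.n_gen + 1
    if isinstance(env, EnvSequence):
        if len(env) < n_env:
            raise ValueError(
                f"environment sequence of length >= {n_env} required for "
                f"{params.n_gen} generations, got {len(env)}"
            )
        seq = env
    else:
        seq = make_markov(n_env, float(env), init_env="random", rng=rng)

    # 2x2 transition-fitness lookup per strategy
    w = np.empty((len(strategies), 2, 2))
    for k, st in enumerate(strategies):
        for i in Env:
            for j in Env:
                w[k, int(i), int(j)] = transition_fitness(st, i, j, pf)

    labels = seq.labels
    freqs = np.empty((n_env, len(strategies)))
    mean_fitness = np.empty(n_env)
    mean_fitness[0] = np.nan
    freqs[0] = freqs0
    cur = freqs0
    for t in range(1, n_env):
        fit = w[:, labels[t - 1], labels[t]]
        mean_fitness[t] = float(np.dot(cur, fit))
        cur = wf_step(cur, fit, params.n, rng)
        freqs[t] = cur
    return Trajectory(
        envs=labels[:n_env].copy(),
        freqs=freqs,
        mean_fitness=mean_fitness,
        strategies=tuple(strategies),
        params=params,
    )


def fixation_generation(traj: Trajectory, genotype: int) -> int | None:
    """First generation at which the genotype's frequency is exactly 1 (or None)."""
    fixed = np.flatnonzero(traj.freqs[:, genotype] == 1.0)
    return int(fixed[0]) if fixed.size else None


def fixation_summary(traj: Trajectory, genotype: int) -> dict:
    """Fixation generation, final frequency and realized geometric mean output."""
    gen = fixation_generation(traj, genotype)
    logs = np.log(traj.mean_fitness[1:])
    return {
        "fixation_generation": gen,
        "final_frequency": traj.final_frequency(genotype),
        "realized_geometric_mean_fitness": float(np.exp(logs.mean())),
    }


def fixation_probability_sweep(
    n_draws: int,
    gamma: float,
    params: PopGenParams,
    switch_probs: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, float]:
    """Compare DME and RME fixation probabilities across switching rates.

    For ``n_draws`` random fitness-effect pairs (rejection-filtered so the
    ancestor keeps the higher 50/50 geometric mean) and each environmental
    switching probability sigma: compute each strategy's geometric mean
    fitness under the stationary transition frequencies (the RME allele at
    its optimal bet-hedging fraction), convert to an effective selection
    coefficient, and evaluate Kimura's fixation probability.

    Returns a table with one row per sigma -- the mean U_DME and U_RME over
    draws, their ratio, and the mean adjusted establishment probability of
    the DME allele (U_DME, or U_DME (1 - U_RME) where RME has the higher
    geometric mean) -- plus the overall ratio mean(U_RME) / mean(U_DME)
    pooled over draws x switching rates.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if switch_probs is None:
        switch_probs = np.round(np.arange(0.05, 0.951, 0.05), 10)
    switch_probs = np.asarray(switch_probs, dtype=float)
    if ((switch_probs <= 0) | (switch_probs >= 1)).any():
        raise ValueError("switching probabilities must lie strictly in (0, 1)")

    x_a, x_n = _draw_effects(gamma, n_draws, rng, enforce_ancestral_advantage=True)
    w_aa = np.exp(x_a)      # anoxia phenotype hatching in anoxia
    w_an = np.exp(-x_n)     # anoxia phenotype hatching in normoxia

    # RME: the stationary chain is symmetric, so the marginal environment
    # frequencies are 0.5/0.5 for every sigma and q*, G_RME do not depend
    # on the switching rate.
    a = w_aa - 1.0
    b = w_an - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        q_interior = -(0.5 * a + 0.5 * b) / (a * b)
    d0 = 0.5 * a + 0.5 * b
    d1 = 0.5 * a / w_aa + 0.5 * b / w_an
    q = np.where(d0 <= 0.0, 0.0, np.where(d1 >= 0.0, 1.0, q_interior))
    g_rme = np.sqrt((1.0 + q * a) * (1.0 + q * b))
    u_rme = kimura_fixation_probability(
        g_rme - 1.0, params.ne, params.p0, params.selection_scaling
    )

    rows = []
    sum_u_dme = 0.0
    sum_u_rme = float(np.sum(u_rme)) * len(switch_probs)
    for sigma in switch_probs:
        log_g_dme = 0.5 * sigma * x_a - 0.5 * (1.0 - sigma) * x_n
        g_dme = np.exp(log_g_dme)
        u_dme = kimura_fixation_probability(
            g_dme - 1.0, params.ne, params.p0, params.selection_scaling
        )
        established = np.where(g_dme >= g_rme, u_dme, u_dme * (1.0 - u_rme))
        sum_u_dme += float(np.sum(u_dme))
        rows.append(
            {
                "switch_prob": float(sigma),
                "mean_u_dme": float(u_dme.mean()),
                "mean_u_rme": float(u_rme.mean()),
                "ratio_rme_dme": float(u_rme.mean() / u_dme.mean()),
                "mean_u_dme_established": float(established.mean()),
            }
        )
    overall_ratio = sum_u_rme / sum_u_dme
    return pd.DataFrame(rows), float(overall_ratio)


# ---------------------------------------------------------------------------
# closed-form diversity summaries
# ---------------------------------------------------------------------------

def fis(ho: float, he: float) -> float:
    """Within-population fixation index Fis = 1 - Ho/He.

    Near 1 under predominant self-fertilization (heterozygote deficit).
    """
    if he <= 0:
        raise ValueError(f"expected heterozygosity must be > 0, got {he}")
    if ho < 0:
        raise ValueError(f"observed heterozygosity must be >= 0, got {ho}")
    return 1.0 - ho / he


def effective_number(proportions: Sequence[float]) -> float:
    """Effective number of types 1 / sum(p_i^2) (e.g. of haplotypes)."""
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
    return float(1.0 / np.sum(p**2))
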