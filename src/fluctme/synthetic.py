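"""Synthetic assay tables with the statistical structure the pipeline assumes.

The generator emulates the two-generation factorial growth-rate assay: an
ancestor population measured in every thawing block alongside evolved
populations from one or more regimes, with multiplicative (log-normal)
thawing-block effects, replicate-population effects and residual noise, and
optional Poisson L1 counts as the raw observable behind growth rates.

It exists so that the full analysis pipeline -- growth rates, ln relative
fitness against per-block ancestral means, per-transition estimates,
geometric mean fitness -- can be exercised and validated for parameter
recovery without any external data.  The default configuration mirrors the
real assay design: 18 thawing blocks, 4 replicate populations per regime,
3 measurements per population and hatching treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .envseq import Env, EnvSequence
from .fitness import PhenotypeFitness, Strategy, transition_fitness

__all__ = [
    "TruthParams",
    "SynthConfig",
    "default_truth",
    "generate_assay_table",
    "generate_l1_counts",
    "generate_evolution_trace",
]

_TRANSITIONS = [(i, j) for i in Env for j in Env]


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth parameters of a simulated assay experiment.

    ``ancestor_mean`` maps each (maternal env, offspring env) treatment to
    the ancestor's true mean growth rate; ``effects`` maps each regime to
    its true ln relative fitness per treatment.  The sigmas are standard
    deviations of the multiplicative (log-scale) block, replicate-population
    and residual effects.
    """

    ancestor_mean: Mapping[tuple[Env, Env], float]
    effects: Mapping[str, Mapping[tuple[Env, Env], float]]
    sigma_block: float = 0.1
    sigma_pop: float = 0.1
    sigma_res: float = 0.2

    def __post_init__(self) -> None:
        for key, v in self.ancestor_mean.items():
            if v <= 0:
                raise ValueError(f"ancestor mean for {key} must be positive, got {v}")
        for name, s in (("sigma_block", self.sigma_block),
                        ("sigma_pop", self.sigma_pop),
                        ("sigma_res", self.sigma_res)):
            if s < 0:
                raise ValueError(f"{name} must be >= 0, got {s}")


@dataclass(frozen=True)
class SynthConfig:
    """Assay design: blocks, populations per regime, replicates per cell."""

    n_blocks: int = 18
    n_populations: int = 4
    n_replicates: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        for name, v in (("n_blocks", self.n_blocks),
                        ("n_populations", self.n_populations),
                        ("n_replicates", self.n_replicates)):
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")


def default_truth(
    sigma_block: float = 0.1, sigma_pop: float = 0.1, sigma_res: float = 0.2
) -> TruthParams:
    """Default truth: anoxia roughly halves growth; the evolved regime gains
    fitness out of maternal normoxia and loses it under repeated anoxia."""
    N, A = Env.NORMOXIA, Env.ANOXIA
    return TruthParams(
        ancestor_mean={(N, N): 1.5, (N, A): 0.45, (A, N): 1.4, (A, A): 0.55},
        effects={
            "predictable": {(N, N): 0.20, (N, A): 0.25, (A, N): 0.0, (A, A): -0.30},
        },
        sigma_block=sigma_block,
        sigma_pop=sigma_pop,
        sigma_res=sigma_res,
    )


def _rows_for(
    regime: str,
    populations: Sequence[str],
    truth: TruthParams,
    cfg: SynthConfig,
    block_eff: np.ndarray,
    pop_eff: Mapping[str, float],
    rng: np.random.Generator,
    trait: str = "growth_rate",
) -> list[dict]:
    effects = truth.effects.get(regime, {})
    rows = []
    for pop in populations:
        for block in range(cfg.n_blocks):
            for (i, j) in _TRANSITIONS:
                base = truth.ancestor_mean[(i, j)]
                eff = 0.0 if regime == "ancestor" else effects.get((i, j), 0.0)
                for rep in range(cfg.n_replicates):
                    resid = rng.normal(0.0, truth.sigma_res)
                    value = base * np.exp(
                        eff + block_eff[block] + pop_eff[pop] + resid
                    )
                    rows.append(
                        {
                            "regime": regime,
                            "population": pop,
                            "block": f"B{block + 1:02d}",
                            "replicate": rep + 1,
                            "maternal_env": i.letter,
                            "offspring_env": j.letter,
                            "trait": trait,
                            "value": value,
                        }
                    )
    return rows


def generate_assay_table(truth: TruthParams, cfg: SynthConfig) -> pd.DataFrame:
    """Simulate a long-format assay table (deterministic given cfg.seed).

    value = ancestor_mean(i,j) * exp(effect + block + population + residual),
    all effects Normal(0, sigma) on the log scale; the regime effect is zero
    for ancestor rows, which appear in every block.  The ancestor is a
    single population (no population effect), matching the real design.
    """
    rng = np.random.default_rng(cfg.seed)
    block_eff = rng.normal(0.0, truth.sigma_block, size=cfg.n_blocks)
    rows = _rows_for("ancestor", ["ANC"], truth, cfg, block_eff, {"ANC": 0.0}, rng)
    for regime in truth.effects:
        pops = [f"{regime[:1].upper()}{k + 1}" for k in range(cfg.n_populations)]
        pop_eff = {p: rng.normal(0.0, truth.sigma_pop) for p in pops}
        rows += _rows_for(regime, pops, truth, cfg, block_eff, pop_eff, rng)
    return pd.DataFrame(rows)


def generate_l1_counts(
    truth: TruthParams, cfg: SynthConfig, seeded: int = 5000
) -> pd.DataFrame:
    """Simulate raw offspring L1 counts: count ~ Poisson(seeded * true rate).

    Dividing the counts by ``seeded`` (see ``growth_rate_from_counts``)
    recovers a noisy growth rate whose extra dispersion is Poisson counting
    noise on top of the multiplicative effect structure.
    """
    table = generate_assay_table(truth, cfg)
    rng = np.random.default_rng(
        None if cfg.seed is None else cfg.seed + 1_000_003
    )
    counts = rng.poisson(seeded * table["value"].to_numpy())
    out = table.drop(columns="value")
    out["l1_count"] = counts
    out["seeded"] = seeded
    return out


def generate_evolution_trace(
    seq: EnvSequence,
    pf: PhenotypeFitness,
    strategies: Sequence[Strategy],
    freqs: Sequence[float] | None = None,
    baseline: float = 1.0,
) -> pd.DataFrame:
    """Deterministic expected mean reproductive output along a regime sequence.

    For a fixed strategy composition (frequencies ``freqs``, defaulting to a
    single fixed strategy), generation t's expected population output is the
    frequency-weighted mean transition fitness on (env_{t-1}, env_t), scaled
    by ``baseline``.  Intended for fixture plots and smoke tests, not as a
    model of real trajectories.
    """
    if freqs is None:
        if len(strategies) != 1:
            raise ValueError("freqs is required with more than one strategy")
        freqs = [1.0]
    f = np.asarray(freqs, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9 or (f < 0).any():
        raise ValueError("strategy frequencies must be nonnegative and sum to 1")
    labels = seq.labels
    rows = []
    for t in range(1, len(labels)):
        w = sum(
            fk * transition_fitness(st, Env(int(labels[t - 1])), Env(int(labels[t])), pf)
            for fk, st in zip(f, strategies)
        )
        rows.append(
            {
                "generation": t,
                "maternal_env": Env(int(labels[t - 1])).letter,
                "offspring_env": Env(int(labels[t])).letter,
                "expected_growth_rate": baseline * w,
            }
        )
    return pd.DataFrame(rows)
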