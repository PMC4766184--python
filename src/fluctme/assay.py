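"""Fitness-assay analysis for two-generation factorial hatching experiments.

The experimental fitness assay seeds 5,000 maternal L1 larvae, runs one full
life cycle through a factorial pair of maternal and offspring hatching
environments (normoxia/anoxia), and counts the surviving offspring L1s.
The count divided by 5,000 is the growth rate, whose natural logarithm
estimates absolute fitness.  Assays are organized in thawing blocks, with
the ancestor population measured in every block, so evolved measurements
are expressed as ln(evolved / ancestral block mean) -- the ln relative
fitness, an estimate of selection strength.

This module implements that pipeline on long-format assay tables (one row
per measurement), plus the two downstream summaries:

* geometric mean fitness over the environment transitions a population
  actually experienced (equal weight on the two alternating transitions for
  the predictable regime; a population's empirical transition frequencies
  for the unpredictable regime); and
* "expected adaptation" A_s, the per-generation relative-fitness advantage
  of an evolved genotype along an arbitrary 12-generation environmental
  sequence s: the 12th root of the product of per-transition relative
  fitness values, enumerated over all 2^12 sequences to map which futures
  the evolved maternal effect prepares a population for.

Inferential machinery (mixed models, post-hoc contrasts) is intentionally
replaced by cell means with seeded bootstrap standard errors.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .envseq import Env, EnvSequence, TransitionFrequencies

__all__ = [
    "ASSAY_COLUMNS",
    "growth_rate_from_counts",
    "exclude_zero_growth",
    "ancestral_block_means",
    "ln_relative",
    "population_transition_estimates",
    "regime_transition_estimates",
    "geometric_mean_fitness_assay",
    "expected_adaptation",
    "enumerate_adaptation",
]

logger = logging.getLogger(__name__)

#: Long-format assay schema: one row per measurement.
ASSAY_COLUMNS = (
    "regime", "population", "block", "replicate",
    "maternal_env", "offspring_env", "trait", "value",
)

_CELL = ["block", "maternal_env", "offspring_env", "trait"]


def _check_schema(df: pd.DataFrame, context: str) -> None:
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{context}: assay table is missing columns {missing}")


def growth_rate_from_counts(l1_count, seeded: int = 5000):
    """Growth rate = offspring L1 count / number of seeded maternal L1s."""
    if seeded <= 0:
        raise ValueError(f"seeded count must be positive, got {seeded}")
    counts = np.asarray(l1_count)
    if (counts < 0).any():
        raise ValueError("L1 counts must be nonnegative")
    out = counts / seeded
    return float(out) if out.ndim == 0 else out


def exclude_zero_growth(df: pd.DataFrame) -> pd.DataFrame:
    """Drop records with value 0 (undefined on the log scale), logging the count."""
    _check_schema(df, "exclude_zero_growth")
    zero = df["value"] == 0
    if zero.any():
        logger.info("excluding %d zero-valued assay records from ln-ratio analysis",
                    int(zero.sum()))
    return df.loc[~zero].copy()


def ancestral_block_means(records: pd.DataFrame) -> pd.DataFrame:
    """Mean ancestor value per block x maternal env x offspring env x trait."""
    _check_schema(records, "ancestral_block_means")
    anc = records[records["regime"] == "ancestor"]
    if anc.empty:
        raise ValueError("no ancestor records (regime == 'ancestor') found")
    out = (
        anc.groupby(_CELL, as_index=False)["value"]
        .mean()
        .rename(columns={"value": "ancestral_mean"})
    )
    return out


def ln_relative(evolved: pd.DataFrame, anc_means: pd.DataFrame) -> pd.DataFrame:
    """ln(evolved value / ancestral block mean), carrying all record keys.

    Every evolved record must find its matching ancestor cell
    (block x treatment x trait); a missing cell raises, naming it.  Values
    must be positive on both sides (zero growth rates are excluded upstream
    with :func:`exclude_zero_growth`).
    """
    _check_schema(evolved, "ln_relative")
    evolved = evolved[evolved["regime"] != "ancestor"]
    merged = evolved.merge(anc_means, on=_CELL, how="left")
    missing = merged["ancestral_mean"].isna()
    if missing.any():
        cell = merged.loc[missing, _CELL].iloc[0].to_dict()
        raise ValueError(f"no ancestral mean for assay cell {cell}")
    if (merged["value"] <= 0).any():
        raise ValueError(
            "nonpositive evolved values: ln relative fitness is undefined "
            "(exclude zero growth rates upstream)"
        )
    if (merged["ancestral_mean"] <= 0).any():
        raise ValueError("nonpositive ancestral block means: ln ratio undefined")
    merged["ln_rel_fitness"] = np.log(merged["value"] / merged["ancestral_mean"])
    return merged


def _bootstrap_se(values: np.ndarray, n_boot: int, rng: np.random.Generator) -> float:
    idx = rng.integers(values.size, size=(n_boot, values.size))
    return float(values[idx].mean(axis=1).std(ddof=1))


def population_transition_estimates(
    lnrel: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean ln relative fitness per population x environment transition.

    Standard errors are nonparametric bootstrap over records (``n_boot``
    resamples, seeded); cells with a single record get ``se = NaN``.
    """
    if "ln_rel_fitness" not in lnrel.columns:
        raise ValueError("input must come from ln_relative()")
    rng = np.random.default_rng(seed)
    rows = []
    keys = ["population", "maternal_env", "offspring_env"]
    for key, grp in lnrel.groupby(keys, sort=True):
        vals = grp["ln_rel_fitness"].to_numpy()
        rows.append(
            dict(
                zip(keys, key),
                mean_ln_rel_fitness=float(vals.mean()),
                se=_bootstrap_se(vals, n_boot, rng) if vals.size > 1 else np.nan,
                n=int(vals.size),
            )
        )
    return pd.DataFrame(rows)


def regime_transition_estimates(
    lnrel: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Regime-level per-transition estimates with cluster-bootstrap intervals.

    The regime estimate is the mean of replicate-population means.  Two
    cluster structures contribute to its error: populations carry their own
    drift history, and thawing-block noise -- including the noise of the
    per-block ancestral means every ln ratio is measured against -- is
    shared across populations within a block.  The interval therefore comes
    from a two-way cluster bootstrap that resamples populations and blocks
    jointly; with few clusters a percentile interval undercovers, so the
    interval is mean +/- t(n_pops - 1) x bootstrap s.e.
    """
    if "ln_rel_fitness" not in lnrel.columns:
        raise ValueError("input must come from ln_relative()")
    rng = np.random.default_rng(seed)
    rows = []
    for key, grp in lnrel.groupby(["maternal_env", "offspring_env"], sort=True):
        cells = (
            grp.groupby(["population", "block"])["ln_rel_fitness"]
            .mean()
            .unstack("block")
            .to_numpy()
        )
        k, n_blocks = cells.shape
        pop_means = np.nanmean(cells, axis=1)
        est = float(pop_means.mean())
        if k > 1:
            boots = np.empty(n_boot)
            for r in range(n_boot):
                sub = cells[rng.integers(k, size=k)][:, rng.integers(n_blocks, size=n_blocks)]
                boots[r] = np.nanmean(np.nanmean(sub, axis=1))
            se = float(boots.std(ddof=1))
            tcrit = float(stats.t.ppf(0.5 + level / 2, df=k - 1))
            lo, hi = est - tcrit * se, est + tcrit * se
        else:
            se, lo, hi = np.nan, np.nan, np.nan
        rows.append(
            {
                "maternal_env": key[0],
                "offspring_env": key[1],
                "mean_ln_rel_fitness": est,
                "se": se,
                "ci_low": lo,
                "ci_high": hi,
                "n_populations": k,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geometric mean fitness and expected adaptation
# ---------------------------------------------------------------------------

def _as_weight(weights, i: Env, j: Env) -> float:
    if isinstance(weights, TransitionFrequencies):
        return weights.p(i, j)
    return float(weights.get((i, j), 0.0))


def geometric_mean_fitness_assay(
    fitness_by_transition: Mapping[tuple[Env, Env], float],
    weights: TransitionFrequencies | Mapping[tuple[Env, Env], float],
) -> float:
    """exp of the weighted mean log per-transition absolute fitness.

    For the predictable regime the weights put 0.5 on each of the two
    alternating transitions; for an unpredictable population they are the
    empirical transition frequencies of the sequence it experienced.
    """
    acc = 0.0
    total = 0.0
    for i in Env:
        for j in Env:
            wt = _as_weight(weights, i, j)
            if wt == 0.0:
                continue
            if (i, j) not in fitness_by_transition:
                raise ValueError(f"missing fitness for weighted transition ({i.letter},{j.letter})")
            w = fitness_by_transition[(i, j)]
            if w <= 0:
                raise ValueError(f"fitness must be positive where weighted, got {w}")
            acc += wt * np.log(w)
            total += wt
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"transition weights must sum to 1, got {total}")
    return float(np.exp(acc))


def expected_adaptation(
    rel_fitness: Mapping[tuple[Env, Env], float],
    seq: EnvSequence,
    boundary: str = "cyclic",
) -> float:
    """Per-generation fitness advantage A_s along an environmental sequence.

    A_s = (prod_t rel_w(env_{t-1}, env_t))^(1/L) over the L generations of
    ``seq``.  The first generation's maternal environment is set by the
    boundary rule: ``"cyclic"`` (default) wraps the sequence (env_0 :=
    env_L), ``"prepend"`` duplicates the first environment.
    """
    labels = list(seq.labels)
    if boundary == "cyclic":
        prev = [labels[-1]] + labels[:-1]
    elif boundary == "prepend":
        prev = [labels[0]] + labels[:-1]
    else:
        raise ValueError(f"boundary must be 'cyclic' or 'prepend', got {boundary!r}")
    log_sum = 0.0
    for i, j in zip(prev, labels):
        w = rel_fitness[(Env(i), Env(j))]
        if w <= 0:
            raise ValueError(f"relative fitness must be positive, got {w}")
        log_sum += np.log(w)
    return float(np.exp(log_sum / len(labels)))


def enumerate_adaptation(
    rel_fitness: Mapping[tuple[Env, Env], float],
    length: int = 12,
    boundary: str = "cyclic",
) -> pd.DataFrame:
    """Score every binary environmental sequence of the given length.

    Returns one row per sequence (2^length total, guarded at length <= 20)
    with the sequence as an N/A string, its per-generation advantage
    ``a_s``, the raw fitness product, and the normoxia frequency used for
    coloring adaptation maps.
    """
    if not 1 <= length <= 20:
        raise ValueError(f"enumeration limited to lengths 1..20, got {length}")
    logw = np.empty((2, 2))
    for i in Env:
        for j in Env:
            w = rel_fitness[(i, j)]
            if w <= 0:
                raise ValueError(f"relative fitness must be positive, got {w}")
            logw[int(i), int(j)] = np.log(w)
    codes = np.arange(2 ** length, dtype=np.int64)
    bits = (codes[:, None] >> np.arange(length - 1, -1, -1)) & 1
    if boundary == "cyclic":
        prev = np.roll(bits, 1, axis=1)
    elif boundary == "prepend":
        prev = np.concatenate([bits[:, :1], bits[:, :-1]], axis=1)
    else:
        raise ValueError(f"boundary must be 'cyclic' or 'prepend', got {boundary!r}")
    log_total = logw[prev, bits].sum(axis=1)
    letters = np.array(["N", "A"])
    seqs = ["".join(row) for row in letters[bits]]
    return pd.DataFrame(
        {
            "sequence": seqs,
            "a_s": np.exp(log_total / length),
            "fitness_product": np.exp(log_total),
            "normoxia_freq": 1.0 - bits.mean(axis=1),
        }
    )
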