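"""Normoxia-anoxia environmental sequences: design and diagnostics.

Experimental evolution in a fluctuating hatching environment exposes every
generation of embryos to either normal oxygen (normoxia, ``N``) or oxygen
deprivation (anoxia, ``A``).  The selective regime is therefore an ordered
binary sequence of hatching environments, one label per generation.  This
module constructs the three regime families used both in the wet experiment
and in the invasion simulations --

* *predictable*: a balanced sequence with a prescribed, small number of
  adjacent repeats, so that mothers almost never share their offspring's
  environment (near-strict alternation);
* *unpredictable*: a balanced sequence whose adjacent (mother-offspring) and
  optionally distance-2 (grandmother-offspring) repeat counts are tuned to
  prescribed targets by a seeded swap search, so that the maternal
  environment carries essentially no information about the offspring's;
* *constant*: a block of anoxia generations followed by a block of normoxia;
* *Markov*: a two-state chain with a given per-generation switching
  probability, the stationary idealization used by the fixation-probability
  theory --

and the diagnostics used to characterize them: lagged repeat probabilities,
empirical mother-offspring transition frequencies, the autocorrelation
function, and the cumulative periodogram.

Encoding
--------
Throughout the package NORMOXIA = 0 and ANOXIA = 1.  This is the canonical
integer encoding; sequence files use the single letters ``N`` and ``A``.

A note on lag conventions: repeat probabilities are indexed by *distance* in
generations, so ``lag=1`` compares mothers with their offspring (what the
experimental literature sometimes calls "lag two", counting both
generations) and ``lag=2`` compares grandmothers with offspring ("lag
three").
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Env",
    "EnvSequence",
    "TransitionFrequencies",
    "make_predictable",
    "make_unpredictable",
    "make_constant",
    "make_markov",
    "count_repeats",
    "repeat_probability",
    "transition_frequencies",
    "stationary_transition_frequencies",
    "autocorrelation",
    "cumulative_periodogram",
]


class Env(enum.IntEnum):
    """A hatching environment. NORMOXIA = 0, ANOXIA = 1 (fixed encoding)."""

    NORMOXIA = 0
    ANOXIA = 1

    @property
    def letter(self) -> str:
        return "N" if self is Env.NORMOXIA else "A"

    @classmethod
    def from_letter(cls, s: str) -> "Env":
        s = s.strip().upper()
        if s in ("N", "NORMOXIA", "0"):
            return cls.NORMOXIA
        if s in ("A", "ANOXIA", "1"):
            return cls.ANOXIA
        raise ValueError(f"unrecognized environment label {s!r}")


@dataclass(frozen=True)
class EnvSequence:
    """An ordered sequence of hatching environments, one per generation.

    Parameters
    ----------
    labels : array-like of {0, 1}
        Environment per generation, in the canonical 0/1 encoding.
    name : str
        Free-text identifier (e.g. ``"predictable"``).
    seed : int or None
        Seed used by the generator that produced the sequence, if any.
    """

    labels: np.ndarray
    name: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels, dtype=np.int8)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("an environment sequence needs at least 2 generations")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("labels must be 0 (normoxia) or 1 (anoxia)")
        object.__setattr__(self, "labels", arr)
        self.labels.setflags(write=False)

    def __len__(self) -> int:
        return int(self.labels.size)

    def __getitem__(self, t: int) -> Env:
        return Env(int(self.labels[t]))

    def __iter__(self) -> Iterator[Env]:
        return (Env(int(v)) for v in self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnvSequence):
            return NotImplemented
        return np.array_equal(self.labels, other.labels)

    def __str__(self) -> str:
        return "".join(Env(int(v)).letter for v in self.labels)

    # --- counts ---------------------------------------------------------

    @property
    def n_anoxia(self) -> int:
        return int(self.labels.sum())

    @property
    def n_normoxia(self) -> int:
        return len(self) - self.n_anoxia

    @property
    def is_balanced(self) -> bool:
        return self.n_anoxia == self.n_normoxia

    # --- serialization --------------------------------------------------

    @classmethod
    def from_letters(cls, letters: str | Iterable[str], **kw) -> "EnvSequence":
        labels = [int(Env.from_letter(c)) for c in letters]
        return cls(np.array(labels, dtype=np.int8), **kw)

    def to_file(self, path: str | Path) -> None:
        """Write one ``N``/``A`` label per line, with a ``#`` header."""
        path = Path(path)
        lines = [f"# environment sequence {self.name or '(unnamed)'}; "
                 f"length {len(self)}; seed {self.seed}"]
        lines += [Env(int(v)).letter for v in self.labels]
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path, name: str = "") -> "EnvSequence":
        tokens = [
            ln.strip() for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        return cls.from_letters(tokens, name=name or Path(path).stem)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"generation": np.arange(len(self)),
             "env": [Env(int(v)).letter for v in self.labels]}
        )


@dataclass(frozen=True)
class TransitionFrequencies:
    """Frequencies p(i, j) of maternal environment i followed by offspring j.

    Stored as a 2x2 matrix indexed by the canonical encoding
    (row = maternal env, column = offspring env).  Entries are nonnegative
    and sum to 1.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.full((2, 2), 0.25))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 2):
            raise ValueError("transition frequencies must form a 2x2 matrix")
        if (m < -1e-12).any():
            raise ValueError("transition frequencies must be nonnegative")
        if abs(m.sum() - 1.0) > 1e-12:
            raise ValueError(f"transition frequencies must sum to 1, got {m.sum()!r}")
        object.__setattr__(self, "matrix", m)
        self.matrix.setflags(write=False)

    def p(self, maternal: Env, offspring: Env) -> float:
        return float(self.matrix[int(maternal), int(offspring)])

    @property
    def marginal_offspring_anoxia(self) -> float:
        """Marginal frequency of the offspring generation hatching in anoxia."""
        return float(self.matrix[:, int(Env.ANOXIA)].sum())

    @classmethod
    def iid(cls, anoxia_freq: float = 0.5) -> "TransitionFrequencies":
        """Independent environments with a given anoxia frequency."""
        pa = float(anoxia_freq)
        pn = 1.0 - pa
        return cls(np.array([[pn * pn, pn * pa], [pa * pn, pa * pa]]))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _compose(total: int, parts: int, rng: np.random.Generator) -> np.ndarray:
    """A uniformly random composition of ``total`` into ``parts`` parts >= 1."""
    if parts == 1:
        return np.array([total])
    cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
    return np.diff(np.concatenate(([0], cuts, [total])))


def make_predictable(n_gen: int, n_repeats: int, seed: int | None = None) -> EnvSequence:
    """A balanced sequence with an exact number of adjacent repeats.

    The sequence has ``n_gen/2`` generations of each environment and exactly
    ``n_repeats`` adjacent pairs with equal labels, so its mother-offspring
    repeat probability is ``n_repeats / (n_gen - 1)``.  The near-alternating
    regime of the evolution experiment is ``make_predictable(60, 3)``, whose
    repeat probability is 3/59 ~ 0.05.

    The construction draws a uniformly random run-length decomposition: a
    sequence with r runs has exactly ``n_gen - r`` equal adjacent pairs, so
    the label counts are split into ``n_gen - n_repeats`` alternating runs.
    """
    if n_gen % 2 != 0 or n_gen < 2:
        raise ValueError(f"n_gen must be even and >= 2, got {n_gen}")
    if not 0 <= n_repeats <= n_gen - 2:
        raise ValueError(
            f"a balanced sequence of length {n_gen} has between 0 and {n_gen - 2} "
            f"equal adjacent pairs; requested {n_repeats}"
        )
    rng = np.random.default_rng(seed)
    half = n_gen // 2
    n_runs = n_gen - n_repeats
    k_first = (n_runs + 1) // 2  # runs of the starting label
    k_second = n_runs // 2
    start = Env(int(rng.integers(2)))
    runs_first = _compose(half, k_first, rng)
    runs_second = _compose(half, k_second, rng)
    labels = np.empty(n_gen, dtype=np.int8)
    pos = 0
    for i in range(n_runs):
        run = runs_first[i // 2] if i % 2 == 0 else runs_second[i // 2]
        lab = int(start) if i % 2 == 0 else 1 - int(start)
        labels[pos:pos + run] = lab
        pos += run
    return EnvSequence(labels, name="predictable", seed=seed)


def make_unpredictable(
    n_gen: int,
    n_repeats: int,
    n_repeats_lag2: int | None = None,
    seed: int | None = None,
    budget: int = 100_000,
) -> EnvSequence:
    """A balanced sequence with tuned repeat counts, by seeded swap search.

    ``n_repeats`` is the exact target number of adjacent (mother-offspring)
    equal pairs; ``n_repeats_lag2``, when given, is the exact target number
    of distance-2 (grandmother-offspring) equal pairs.  The uncorrelated
    regime of the evolution experiment is ``make_unpredictable(60, 27)``
    (repeat probability 27/59 ~ 0.46); its archived variants additionally
    fixed the distance-2 count (e.g. 30/58 ~ 0.52).

    The search starts from a random balanced shuffle and hill-climbs over
    swaps of oppositely labelled positions (which preserve balance),
    accepting any proposal that does not increase the distance to the
    targets; sideways moves let it escape plateaus.  It raises if the budget
    is exhausted, reporting the best counts achieved.
    """
    if n_gen % 2 != 0 or n_gen < 2:
        raise ValueError(f"n_gen must be even and >= 2, got {n_gen}")
    if not 0 <= n_repeats <= n_gen - 2:
        raise ValueError(
            f"a balanced length-{n_gen} sequence has at most {n_gen - 2} equal "
            f"adjacent pairs (and at least 0); requested {n_repeats}"
        )
    rng = np.random.default_rng(seed)
    half = n_gen // 2
    labels = np.array([0] * half + [1] * half, dtype=np.int8)
    rng.shuffle(labels)

    def objective(x: np.ndarray) -> int:
        err = abs(int((x[1:] == x[:-1]).sum()) - n_repeats)
        if n_repeats_lag2 is not None:
            err += abs(int((x[2:] == x[:-2]).sum()) - n_repeats_lag2)
        return err

    def counts(x: np.ndarray) -> tuple[int, int | None]:
        return (
            int((x[1:] == x[:-1]).sum()),
            None if n_repeats_lag2 is None else int((x[2:] == x[:-2]).sum()),
        )

    best = cur = objective(labels)
    best_counts = counts(labels)
    for _ in range(budget):
        if cur == 0:
            return EnvSequence(labels, name="unpredictable", seed=seed)
        i, j = rng.integers(n_gen, size=2)
        if labels[i] == labels[j]:
            continue
        labels[i], labels[j] = labels[j], labels[i]
        new = objective(labels)
        if new <= cur:
            cur = new
        else:
            labels[i], labels[j] = labels[j], labels[i]
        if cur < best:
            best = cur
            best_counts = counts(labels)
    if cur == 0:
        return EnvSequence(labels, name="unpredictable", seed=seed)
    raise RuntimeError(
        f"swap search exhausted its {budget}-proposal budget without reaching "
        f"targets (adjacent={n_repeats}, distance-2={n_repeats_lag2}); best "
        f"achieved counts: {best_counts}"
    )


def make_constant(n_gen: int) -> EnvSequence:
    """Anoxia for the first half of the generations, then normoxia.

    Mirrors the constant regime of the evolution experiment: 30 consecutive
    anoxia generations followed by 30 of normoxia for ``n_gen=60``.
    """
    if n_gen % 2 != 0 or n_gen < 2:
        raise ValueError(f"n_gen must be even and >= 2, got {n_gen}")
    half = n_gen // 2
    labels = np.array([1] * half + [0] * half, dtype=np.int8)
    return EnvSequence(labels, name="constant")


def make_markov(
    n_gen: int,
    p_switch: float,
    init_env: Env | str = "random",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EnvSequence:
    """A two-state Markov sequence with per-generation switching probability.

    Each environment differs from the previous one with probability
    ``p_switch``; ``p_switch=1`` is strict alternation, ``p_switch=0`` a
    constant environment.  ``init_env`` may be an :class:`Env` or
    ``"random"`` (uniform draw).
    """
    if not 0.0 <= p_switch <= 1.0:
        raise ValueError(f"p_switch must be a probability, got {p_switch}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if init_env == "random":
        first = int(rng.integers(2))
    else:
        first = int(Env(init_env))
    switches = rng.random(n_gen - 1) < p_switch
    labels = np.empty(n_gen, dtype=np.int8)
    labels[0] = first
    labels[1:] = (first + np.cumsum(switches)) % 2
    return EnvSequence(labels, name=f"markov(p_switch={p_switch})", seed=seed)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def count_repeats(seq: EnvSequence, lag: int = 1) -> int:
    """Number of positions t >= lag with the same label as position t - lag."""
    if not 1 <= lag < len(seq):
        raise ValueError(f"lag must be in [1, {len(seq) - 1}], got {lag}")
    x = seq.labels
    return int((x[lag:] == x[:-lag]).sum())


def repeat_probability(seq: EnvSequence, lag: int = 1) -> float:
    """Fraction of distance-``lag`` pairs sharing the same environment.

    ``lag=1`` is the probability that mothers and offspring hatch in the
    same environment (``n - 1`` comparisons); ``lag=2`` compares
    grandmothers with offspring.
    """
    return count_repeats(seq, lag) / (len(seq) - lag)


def transition_frequencies(seq: EnvSequence) -> TransitionFrequencies:
    """Empirical frequencies of the n-1 adjacent environment transitions."""
    x = seq.labels
    m = np.zeros((2, 2))
    np.add.at(m, (x[:-1], x[1:]), 1.0)
    return TransitionFrequencies(m / (len(seq) - 1))


def stationary_transition_frequencies(p_switch: float) -> TransitionFrequencies:
    """Long-run transition frequencies of the symmetric two-state chain.

    The chain's stationary distribution is uniform, so
    p(i, j) = p_switch / 2 for i != j and (1 - p_switch) / 2 for i == j.
    """
    if not 0.0 <= p_switch <= 1.0:
        raise ValueError(f"p_switch must be a probability, got {p_switch}")
    stay = 0.5 * (1.0 - p_switch)
    move = 0.5 * p_switch
    return TransitionFrequencies(np.array([[stay, move], [move, stay]]))


def autocorrelation(seq: EnvSequence, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation of the 0/1 sequence up to ``max_lag``.

    The standard time-series estimator: mean-centered, normalized by the
    lag-0 sum of squares, so r_0 = 1 and the denominator is the same at
    every lag.  A constant sequence has zero variance and raises.
    """
    if not 0 <= max_lag < len(seq):
        raise ValueError(f"max_lag must be in [0, {len(seq) - 1}], got {max_lag}")
    x = seq.labels.astype(float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("autocorrelation is undefined for a constant sequence")
    r = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        r[k] = np.dot(x[: len(x) - k], x[k:]) / denom
    return r


def cumulative_periodogram(seq: EnvSequence) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative normalized periodogram of the 0/1 sequence.

    The raw (untapered, mean-removed) periodogram is evaluated at the
    Fourier frequencies j/n for j = 1..floor(n/2), cumulatively summed and
    normalized to end at 1.  For a white-noise sequence the curve tracks the
    diagonal; concentration at low (high) frequencies indicates a red
    (blue) spectrum.  Returns ``(frequencies, cumulative_power)``.
    """
    n = len(seq)
    if n < 4:
        raise ValueError("periodogram needs at least 4 observations")
    x = seq.labels.astype(float)
    x = x - x.mean()
    spectrum = np.abs(np.fft.rfft(x)) ** 2 / n
    power = spectrum[1: n // 2 + 1]
    total = power.sum()
    if total == 0.0:
        raise ValueError("periodogram is undefined for a constant sequence")
    freqs = np.arange(1, n // 2 + 1) / n
    return freqs, np.cumsum(power) / total
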