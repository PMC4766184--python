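"""Assay pipeline: growth rates, ln relative fitness, geometric means, A_s."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fluctme.envseq import Env, EnvSequence, TransitionFrequencies
from fluctme.assay import (
    ancestral_block_means,
    enumerate_adaptation,
    exclude_zero_growth,
    expected_adaptation,
    geometric_mean_fitness_assay,
    growth_rate_from_counts,
    ln_relative,
    population_transition_estimates,
)

N, A = Env.NORMOXIA, Env.ANOXIA


def record(regime="predictable", population="P1", block="B01", replicate=1,
           maternal_env="N", offspring_env="A", trait="growth_rate", value=1.0):
    return dict(regime=regime, population=population, block=block,
                replicate=replicate, maternal_env=maternal_env,
                offspring_env=offspring_env, trait=trait, value=value)


@pytest.fixture
def small_table():
    rows = [
        record(regime="ancestor", population="ANC", value=1.0),
        record(regime="ancestor", population="ANC", replicate=2, value=3.0),
        record(value=2.0),
        record(replicate=2, value=2.0),
    ]
    return pd.DataFrame(rows)


class TestGrowthRate:
    @pytest.mark.parametrize("count,expected", [(5000, 1.0), (10000, 2.0), (0, 0.0)])
    def test_counts_over_seeded(self, count, expected):
        assert growth_rate_from_counts(count) == expected

    def test_vectorized_and_validated(self):
        np.testing.assert_allclose(
            growth_rate_from_counts(np.array([2500, 7500])), [0.5, 1.5]
        )
        with pytest.raises(ValueError):
            growth_rate_from_counts(-1)
        with pytest.raises(ValueError):
            growth_rate_from_counts(100, seeded=0)


class TestLnRelative:
    def test_ancestral_block_means(self, small_table):
        means = ancestral_block_means(small_table)
        assert len(means) == 1
        assert means["ancestral_mean"].iloc[0] == pytest.approx(2.0)

    def test_missing_ancestor_cell_raises(self, small_table):
        means = ancestral_block_means(small_table)
        orphan = pd.DataFrame([record(block="B99", value=1.5)])
        with pytest.raises(ValueError, match="B99"):
            ln_relative(orphan, means)

    def test_ln_ratio_values(self, small_table):
        means = ancestral_block_means(small_table)
        lnrel = ln_relative(small_table, means)
        assert np.allclose(lnrel["ln_rel_fitness"], math.log(2.0 / 2.0) + math.log(1.0))
        evolved = pd.DataFrame([record(value=2.0 * math.e)])
        assert ln_relative(evolved, means)["ln_rel_fitness"].iloc[0] == pytest.approx(1.0)

    def test_nonpositive_values_raise_and_zeros_are_excluded_upstream(self, small_table, caplog):
        means = ancestral_block_means(small_table)
        bad = pd.DataFrame([record(value=0.0)])
        with pytest.raises(ValueError, match="undefined"):
            ln_relative(bad, means)
        with caplog.at_level("INFO", logger="fluctme.assay"):
            kept = exclude_zero_growth(pd.concat([small_table, bad], ignore_index=True))
        assert len(kept) == len(small_table)
        assert "excluding 1" in caplog.text


class TestTransitionEstimates:
    def test_mean_se_and_single_record_contract(self):
        rows = [record(value=math.e ** 0.1), record(replicate=2, value=math.e ** 0.3),
                record(maternal_env="A", value=2.0)]
        rows.append(record(regime="ancestor", population="ANC", value=1.0))
        rows.append(record(regime="ancestor", population="ANC", maternal_env="A", value=1.0))
        df = pd.DataFrame(rows)
        lnrel = ln_relative(df, ancestral_block_means(df))
        est = population_transition_estimates(lnrel, n_boot=200, seed=0)
        cell = est[est["maternal_env"] == "N"].iloc[0]
        assert cell["mean_ln_rel_fitness"] == pytest.approx(0.2)
        assert cell["n"] == 2 and cell["se"] > 0
        single = est[est["maternal_env"] == "A"].iloc[0]
        assert single["n"] == 1 and np.isnan(single["se"])

    def test_identical_records_have_zero_se(self):
        rows = [record(replicate=r, value=2.0) for r in range(1, 4)]
        rows.append(record(regime="ancestor", population="ANC", value=1.0))
        df = pd.DataFrame(rows)
        lnrel = ln_relative(df, ancestral_block_means(df))
        est = population_transition_estimates(lnrel, n_boot=200, seed=0)
        assert est["se"].iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestGeometricMeanAssay:
    def test_reciprocal_transitions_cancel(self):
        g = geometric_mean_fitness_assay(
            {(N, A): 2.0, (A, N): 0.5}, {(N, A): 0.5, (A, N): 0.5}
        )
        assert g == pytest.approx(1.0)

    def test_matches_model_closed_form_for_alternation(self):
        g = geometric_mean_fitness_assay(
            {(N, A): 2.63, (A, N): 1.0}, {(N, A): 0.5, (A, N): 0.5}
        )
        assert g == pytest.approx(math.sqrt(2.63), rel=1e-12)

    def test_unit_fitness_everywhere(self):
        w = {(i, j): 1.0 for i in Env for j in Env}
        assert geometric_mean_fitness_assay(w, TransitionFrequencies.iid(0.5)) == 1.0

    def test_ancestor_against_itself_recovers_unity(self):
        # ln-ratio pipeline on ancestor-vs-itself data: all ratios 1, G = 1
        rows = [record(regime="ancestor", population="ANC", maternal_env=m,
                       offspring_env=o, value=v)
                for (m, o), v in {("N", "A"): 0.5, ("A", "N"): 1.3}.items()]
        df = pd.DataFrame(rows)
        evolved = df.assign(regime="evolved", population="P1")
        lnrel = ln_relative(pd.concat([df, evolved]), ancestral_block_means(df))
        w = {
            (Env.from_letter(r.maternal_env), Env.from_letter(r.offspring_env)):
            math.exp(r.ln_rel_fitness)
            for r in lnrel.itertuples()
        }
        g = geometric_mean_fitness_assay(w, {(N, A): 0.5, (A, N): 0.5})
        assert g == pytest.approx(1.0) and math.log(g) == pytest.approx(0.0)

    def test_missing_weighted_transition_raises(self):
        with pytest.raises(ValueError, match="missing fitness"):
            geometric_mean_fitness_assay({(N, A): 2.0}, {(N, A): 0.5, (A, N): 0.5})


class TestExpectedAdaptation:
    def test_unit_relative_fitness(self):
        w = {(i, j): 1.0 for i in Env for j in Env}
        assert expected_adaptation(w, EnvSequence.from_letters("NA" * 6)) == 1.0

    def test_cyclic_alternation_hand_value(self):
        w = {(N, A): 1.2, (A, N): 1.0, (N, N): 9.9, (A, A): 9.9}
        a = expected_adaptation(w, EnvSequence.from_letters("NA" * 6))
        assert a == pytest.approx(1.2 ** 0.5, rel=1e-12)

    def test_constant_sequence_is_single_transition(self):
        w = {(N, N): 1.1, (N, A): 9.9, (A, N): 9.9, (A, A): 9.9}
        assert expected_adaptation(w, EnvSequence.from_letters("N" * 12)) == pytest.approx(1.1)

    def test_cyclic_rotation_invariance(self, rng):
        w = {(i, j): float(f) for (i, j), f in
             zip([(N, N), (N, A), (A, N), (A, A)], rng.uniform(0.5, 2.0, 4))}
        labels = rng.integers(2, size=12)
        base = expected_adaptation(w, EnvSequence(labels))
        for shift in range(1, 12):
            rolled = EnvSequence(np.roll(labels, shift))
            assert expected_adaptation(w, rolled) == pytest.approx(base, rel=1e-12)

    def test_prepend_boundary_duplicates_first_environment(self):
        w = {(N, N): 1.5, (N, A): 2.0, (A, N): 0.5, (A, A): 1.0}
        a = expected_adaptation(w, EnvSequence.from_letters("NAN"), boundary="prepend")
        assert a == pytest.approx((1.5 * 2.0 * 0.5) ** (1 / 3), rel=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(
        labels=st.lists(st.integers(0, 1), min_size=2, max_size=12),
        bump=st.floats(1.0, 3.0),
    )
    def test_raising_a_transition_weakly_increases_adaptation(self, labels, bump):
        w = {(i, j): 1.0 for i in Env for j in Env}
        seq = EnvSequence(np.array(labels, dtype=np.int8))
        base = expected_adaptation(w, seq)
        for key in w:
            w2 = dict(w)
            w2[key] = w[key] * bump
            assert expected_adaptation(w2, seq) >= base - 1e-12


class TestEnumeration:
    def test_full_enumeration_size_and_consistency(self):
        w = {(N, N): 1.1, (N, A): 1.3, (A, N): 0.9, (A, A): 0.7}
        table = enumerate_adaptation(w, length=12)
        assert len(table) == 4096
        assert table["sequence"].is_unique
        # spot-check rows against the single-sequence evaluator
        for idx in (0, 1, 1000, 4095):
            row = table.iloc[idx]
            seq = EnvSequence.from_letters(row["sequence"])
            assert row["a_s"] == pytest.approx(expected_adaptation(w, seq), rel=1e-12)
            assert row["normoxia_freq"] == pytest.approx(
                row["sequence"].count("N") / 12
            )

    def test_minimal_and_unit_cases(self):
        w = {(i, j): 1.0 for i in Env for j in Env}
        assert len(enumerate_adaptation(w, length=1)) == 2
        assert (enumerate_adaptation(w, length=5)["a_s"] == 1.0).all()

    def test_enumeration_guard(self):
        w = {(i, j): 1.0 for i in Env for j in Env}
        with pytest.raises(ValueError):
            enumerate_adaptation(w, length=21)
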