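"""Tree category probabilities, constraints and the multinomial likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mptsource import (
    ConstraintSet,
    FrequencyTable,
    ItemType,
    ParameterVector,
    ResponseCategory,
    apply_constraints,
    category_probabilities,
    log_likelihood,
)
from mptsource.model import (
    N_PARAMS,
    PARAM_NAMES,
    category_probability_matrix,
)
from mptsource.paths import evaluate_paths

from conftest import params_with, random_parameter_vectors

# Brute-force path enumeration at all parameters = 0.5, target TI (frozen
# from the path oracle; see tests/test_paths.py for the oracle itself).
ALL_HALF_TI = np.array([0.25, 0.453125, 0.109375, 0.109375, 0.078125])


class TestCategoryProbabilities:
    def test_certain_detection_and_joint_retrieval(self):
        p = category_probabilities(
            params_with({"D_TI": 1.0, "d_TI": 1.0}), ItemType.TARGET_TI
        )
        assert p[ResponseCategory.OLD_TI.index] == 1.0
        assert p[ResponseCategory.NEW.index] == 0.0

    def test_undetected_without_old_guessing_always_new(self):
        p = category_probabilities(
            params_with({"D_TU": 0.0, "b": 0.0}), ItemType.TARGET_TU
        )
        assert p[ResponseCategory.NEW.index] == 1.0
        assert np.all(p[1:] == 0.0)

    def test_all_half_matches_path_enumeration_oracle(self):
        p = category_probabilities(params_with({}), ItemType.TARGET_TI)
        np.testing.assert_allclose(p, ALL_HALF_TI, atol=1e-15)

    @pytest.mark.parametrize("item_type", list(ItemType))
    def test_rows_sum_to_one(self, item_type):
        values = random_parameter_vectors(200, seed=3)
        probs = category_probability_matrix(values)
        np.testing.assert_allclose(
            probs[:, item_type.index].sum(axis=1), 1.0, atol=1e-12
        )

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_correct_joint_response_monotone_in_d_and_D(self, lo, hi):
        lo, hi = min(lo, hi), max(lo, hi)
        for name in ("d_TI", "D_TI"):
            p_lo = category_probabilities(params_with({name: lo}), ItemType.TARGET_TI)
            p_hi = category_probabilities(params_with({name: hi}), ItemType.TARGET_TI)
            assert (
                p_hi[ResponseCategory.OLD_TI.index]
                >= p_lo[ResponseCategory.OLD_TI.index] - 1e-12
            )

    def test_out_of_range_parameter_rejected(self):
        values = np.full(N_PARAMS, 0.5)
        values[0] = 1.2
        with pytest.raises(ValueError):
            ParameterVector(values)


class TestConstraints:
    def test_paper_set_has_14_free_parameters(self, paper_cs):
        assert paper_cs.n_free == 14

    def test_distractor_detection_equated_with_target_TI(self, paper_cs):
        free = {n: 0.5 for n in paper_cs.free_names}
        free["D_TI"] = 0.8
        full = apply_constraints(free, paper_cs)
        assert full["D_new"] == 0.8
        assert full["D_TI"] == 0.8

    def test_empty_constraint_set_is_identity(self):
        cs = ConstraintSet()
        assert cs.free_names == PARAM_NAMES
        free = {n: v for n, v in zip(PARAM_NAMES, np.linspace(0.01, 0.99, N_PARAMS))}
        full = apply_constraints(free, cs)
        for n in PARAM_NAMES:
            assert full[n] == free[n]

    def test_idempotence(self, paper_cs):
        rng = np.random.default_rng(5)
        free = {n: float(v) for n, v in zip(paper_cs.free_names, rng.random(14))}
        once = apply_constraints(free, paper_cs)
        twice = apply_constraints(paper_cs.reduce(once), paper_cs)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_missing_free_parameter_raises(self, paper_cs):
        free = {n: 0.5 for n in paper_cs.free_names if n != "b"}
        with pytest.raises(KeyError):
            apply_constraints(free, paper_cs)

    def test_out_of_range_free_value_raises(self, paper_cs):
        free = {n: 0.5 for n in paper_cs.free_names}
        free["b"] = -0.1
        with pytest.raises(ValueError):
            apply_constraints(free, paper_cs)

    def test_parameter_in_two_groups_rejected(self):
        with pytest.raises(ValueError):
            ConstraintSet(groups=(("x", ("b",)), ("y", ("b",))))


class TestLogLikelihood:
    def test_probability_one_outcomes_give_zero(self):
        params = params_with(
            {f"D_{k}": 0.0 for k in ("TI", "TU", "FI", "FU")}
            | {"b": 0.0, "D_new": 1.0}
        )
        items = np.array([9, 9, 9, 9, 18])
        counts = np.zeros((5, 5), dtype=int)
        counts[:, 0] = items
        table = FrequencyTable("p1", counts, items)
        assert log_likelihood(params, table) == 0.0

    def test_single_joint_retrieval_trial_matches_oracle_value(self):
        items = np.array([1, 0, 0, 0, 0])
        counts = np.zeros((5, 5), dtype=int)
        counts[0, ResponseCategory.OLD_TI.index] = 1
        table = FrequencyTable("p1", counts, items)
        assert log_likelihood(params_with({}), table) == pytest.approx(
            np.log(ALL_HALF_TI[1]), abs=1e-12
        )

    def test_matches_path_enumeration_likelihood(self):
        rng = np.random.default_rng(7)
        items = np.array([9, 9, 9, 9, 18])
        for _ in range(20):
            params = ParameterVector(rng.random(N_PARAMS))
            probs = np.stack(
                [evaluate_paths(it, params) for it in ItemType]
            )
            counts = np.stack(
                [rng.multinomial(n, p) for n, p in zip(items, probs)]
            )
            table = FrequencyTable("p1", counts, items)
            expected = np.sum(
                np.where(counts > 0, counts * np.log(probs), 0.0)
            )
            assert log_likelihood(params, table) == pytest.approx(expected, abs=1e-10)

    def test_impossible_observation_is_minus_inf(self):
        params = params_with({"D_new": 1.0})  # distractors always called new
        items = np.array([0, 0, 0, 0, 1])
        counts = np.zeros((5, 5), dtype=int)
        counts[4, 1] = 1
        table = FrequencyTable("p1", counts, items)
        assert log_likelihood(params, table) == -np.inf

    def test_row_sum_mismatch_rejected(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 0] = 3
        with pytest.raises(ValueError):
            FrequencyTable("p1", counts, np.array([9, 9, 9, 9, 18]))
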