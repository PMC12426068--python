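"""Synthetic-cohort generator: heterogeneity draws, frequencies, trials."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import ndtr, ndtri

from mptsource import (
    CodingRule,
    DesignSpec,
    GroupDistribution,
    build_frequency_tables,
    draw_participants,
    simulate_frequencies,
    simulate_trials,
)
from mptsource.model import category_probability_matrix

from conftest import params_with


class TestDrawParticipants:
    def test_zero_heterogeneity_gives_identical_participants(self, paper_cs):
        mu = ndtri(np.linspace(0.2, 0.8, paper_cs.n_free))
        group = GroupDistribution(mu=mu, sigma=np.zeros((14, 14)))
        params = draw_participants(group, paper_cs, 4, seed=1)
        for p in params:
            free = paper_cs.reduce(p)
            np.testing.assert_allclose(
                [free[n] for n in paper_cs.free_names], ndtr(mu), atol=1e-15
            )

    def test_zero_mean_gives_one_half(self, paper_cs):
        group = GroupDistribution(mu=np.zeros(14), sigma=np.zeros((14, 14)))
        params = draw_participants(group, paper_cs, 3, seed=2)
        assert all(np.allclose(p.values, 0.5) for p in params)

    def test_sample_mean_matches_quadrature(self, paper_cs):
        """Probability-scale mean of Phi(mu+delta) against 1-D quadrature."""
        mu = np.zeros(14)
        k = paper_cs.free_names.index("d_TI")
        mu[k] = ndtri(0.42)
        group = GroupDistribution(mu=mu, sigma=0.25 * np.eye(14))
        params = draw_participants(group, paper_cs, 5000, seed=3)
        sample_mean = np.mean([p["d_TI"] for p in params])
        expected, _ = integrate.quad(
            lambda x: ndtr(x) * stats.norm.pdf(x, loc=mu[k], scale=0.5), -10, 10
        )
        assert sample_mean == pytest.approx(expected, abs=0.02)

    def test_non_psd_sigma_rejected(self):
        sigma = np.eye(3)
        sigma[0, 0] = -1.0
        with pytest.raises(ValueError):
            GroupDistribution(mu=np.zeros(3), sigma=sigma)

    def test_dimension_mismatch_rejected(self, paper_cs):
        group = GroupDistribution(mu=np.zeros(3), sigma=np.eye(3))
        with pytest.raises(ValueError):
            draw_participants(group, paper_cs, 2, seed=0)

    def test_seed_determinism(self, paper_cs):
        group = GroupDistribution(mu=np.zeros(14), sigma=0.25 * np.eye(14))
        a = draw_participants(group, paper_cs, 5, seed=9)
        b = draw_participants(group, paper_cs, 5, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)


class TestSimulateFrequencies:
    def test_perfect_memory_concentrates_on_correct_category(self, design):
        params = params_with(
            {f"D_{k}": 1.0 for k in ("TI", "TU", "FI", "FU")}
            | {f"d_{k}": 1.0 for k in ("TI", "TU", "FI", "FU")}
        )
        tables = simulate_frequencies([params] * 3, design, seed=4)
        for t in tables:
            for i in range(4):
                assert t.counts[i, i + 1] == design.items_per_source

    def test_large_count_proportions_match_probabilities(self):
        design = DesignSpec(n_participants=1, items_per_source=100_000,
                            n_distractors=100_000)
        params = params_with({"d_TI": 0.42, "e_ver": 0.8})
        (table,) = simulate_frequencies([params], design, seed=5)
        probs = category_probability_matrix(params.values[None])[0]
        props = table.counts / table.items_per_type[:, None]
        np.testing.assert_allclose(props, probs, atol=0.005)

    def test_same_seed_identical_tables(self, design, paper_cs):
        group = GroupDistribution(mu=np.zeros(14), sigma=0.25 * np.eye(14))
        params = draw_participants(group, paper_cs, 6, seed=6)
        a = simulate_frequencies(params, design, seed=7)
        b = simulate_frequencies(params, design, seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.counts, y.counts)


class TestSimulateTrials:
    def test_default_design_yields_54_records_per_participant(self, design):
        trials = simulate_trials([params_with({})] * 2, design, 0.7, seed=8)
        assert (trials.groupby("participant").size() == 54).all()

    def test_remember_rate_one_makes_codings_agree(self, design):
        params = [params_with({})] * 3
        trials = simulate_trials(params, design, remember_rate=1.0, seed=9)
        a = build_frequency_tables(trials, CodingRule.REMEMBER_ONLY, design)
        b = build_frequency_tables(trials, CodingRule.REMEMBER_PLUS_KNOW, design)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.counts, y.counts)

    def test_remember_rate_zero_kills_old_counts_under_remember_only(self, design):
        trials = simulate_trials([params_with({})] * 2, design, 0.0, seed=10)
        tables = build_frequency_tables(trials, CodingRule.REMEMBER_ONLY, design)
        for t in tables:
            assert t.counts[:, 1:].sum() == 0
            assert t.counts[:, 0].sum() == design.n_test_items

    def test_trial_frequencies_distributionally_match_tree(self):
        """Goodness of fit of collapsed trials against the category probabilities."""
        design = DesignSpec(n_participants=1, items_per_source=20_000,
                            n_distractors=20_000)
        params = params_with({"d_TI": 0.42, "e_imp": 0.2})
        trials = simulate_trials([params], design, remember_rate=0.7, seed=11)
        (table,) = build_frequency_tables(
            trials, CodingRule.REMEMBER_PLUS_KNOW, design
        )
        probs = category_probability_matrix(params.values[None])[0]
        for t in range(5):
            res = stats.chisquare(
                table.counts[t], probs[t] * table.items_per_type[t]
            )
            assert res.pvalue > 1e-3

    def test_invalid_remember_rate_rejected(self, design):
        with pytest.raises(ValueError):
            simulate_trials([params_with({})], design, remember_rate=1.5, seed=0)
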