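"""Behavioral metrics and the classical statistics layer."""

import numpy as np
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from racas import (
    AgentSpec,
    DegenerateInputError,
    ValidationError,
    bias_fraction,
    cohens_d_one_sample,
    delta_rewards_norm,
    exploitation,
    group_compare,
    observed_expectancy,
    rank_correlation,
    rolling_mean,
    run_session,
    summarize_session,
    summarize_sessions,
)
from racas.schedule import MINUS, PLUS
from racas.session import SessionResult, TrialRecord


def session_from_pattern(n_plus_choices, rewards_plus, rewards_minus):
    """Hand-built complete session: choices and obtained rewards by count.

    Allocations are arranged to stay consistent (25 per side) while
    delivering the requested obtained-reward counts.
    """
    records = []
    plus_alloc = minus_alloc = 0
    for t in range(1, 101):
        choice = PLUS if t <= n_plus_choices else MINUS
        ap = choice == PLUS and rewards_plus > 0
        am = choice == MINUS and rewards_minus > 0
        if ap:
            rewards_plus -= 1
            plus_alloc += 1
        if am:
            rewards_minus -= 1
            minus_alloc += 1
        records.append(TrialRecord(t, choice, ap, am, ap or am))
    # dump the unallocated remainder onto unchosen sides (missed rewards)
    for r in records:
        if plus_alloc < 25 and r.choice == MINUS and not r.alloc_plus:
            r.alloc_plus = True
            plus_alloc += 1
        if minus_alloc < 25 and r.choice == PLUS and not r.alloc_minus:
            r.alloc_minus = True
            minus_alloc += 1
    result = SessionResult(records=records, agent="handmade", seed=0, session_id="hm")
    result.validate()
    return result


class TestSessionMetrics:
    def test_bias_fraction_counts_plus_choices(self, always_plus_session):
        assert bias_fraction(always_plus_session) == 1.0
        assert bias_fraction(session_from_pattern(70, 15, 5)) == pytest.approx(0.70)

    def test_bias_fraction_zero_for_pure_defector(self, always_minus_session):
        assert bias_fraction(always_minus_session) == 0.0

    def test_delta_rewards_extremes_and_midpoint(
        self, always_plus_session, always_minus_session
    ):
        assert delta_rewards_norm(always_plus_session) == 1.0
        assert delta_rewards_norm(always_minus_session) == -1.0
        assert delta_rewards_norm(session_from_pattern(70, 10, 10)) == 0.0
        assert delta_rewards_norm(session_from_pattern(70, 15, 5)) == pytest.approx(0.5)

    def test_delta_rewards_undefined_without_any_reward(self):
        session = session_from_pattern(70, 0, 0)
        assert delta_rewards_norm(session) is None

    def test_observed_expectancy(self, always_plus_session):
        assert observed_expectancy(always_plus_session, PLUS) == pytest.approx(0.25)
        assert observed_expectancy(always_plus_session, MINUS) is None
        session = session_from_pattern(40, 10, 0)
        assert observed_expectancy(session, PLUS) == pytest.approx(0.25)

    def test_exploitation(self, always_plus_session):
        assert exploitation(always_plus_session, PLUS) == 1.0
        assert exploitation(always_plus_session, MINUS) == 0.0
        assert exploitation(session_from_pattern(70, 20, 0), PLUS) == pytest.approx(0.8)

    def test_exploitation_requires_complete_session(self, always_plus_session):
        truncated = SessionResult(
            records=always_plus_session.records[:99],
            agent="x",
            seed=0,
            session_id="trunc",
        )
        with pytest.raises(ValidationError):
            exploitation(truncated, PLUS)

    def test_identities_hold_on_every_simulated_session(self, mixed_batch):
        for session in mixed_batch:
            s = summarize_session(session)
            choices_plus = round(s.bias_plus * 100)
            if s.expectancy_plus is not None:
                assert s.obtained_plus == pytest.approx(s.expectancy_plus * choices_plus)
            assert s.obtained_plus == pytest.approx(s.exploitation_plus * 25)
            if s.delta_rewards_norm is not None:
                assert -1.0 <= s.delta_rewards_norm <= 1.0
            assert 0.0 <= s.bias_plus <= 1.0
            assert 0.0 <= s.exploitation_plus <= 1.0
            assert 0.0 <= s.exploitation_minus <= 1.0

    def test_summary_frame_has_one_row_per_session(self, mixed_batch):
        frame = summarize_sessions(mixed_batch)
        assert len(frame) == len(mixed_batch)
        assert set(frame["agent"]) == {s.agent for s in mixed_batch}


class TestRollingMean:
    def test_constant_series_is_preserved(self):
        assert np.allclose(rolling_mean([1.0] * 20, 10), 1.0)

    def test_alternating_series_averages_out(self):
        out = rolling_mean([0, 1] * 10, window=2)
        assert np.allclose(out, 0.5)

    def test_window_one_is_identity(self):
        series = [3.0, 1.0, 4.0, 1.0, 5.0]
        assert np.allclose(rolling_mean(series, 1), series)

    def test_output_length_trims_warm_up(self):
        assert len(rolling_mean(list(range(100)), 10)) == 91

    @pytest.mark.parametrize("window", [0, 11])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(ValidationError):
            rolling_mean([1.0] * 10, window)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        series=st.lists(
            st.floats(min_value=-1e6, max_value=1e6), min_size=5, max_size=40
        ),
        a=st.floats(min_value=-100, max_value=100),
        b=st.floats(min_value=-100, max_value=100),
    )
    def test_commutes_with_affine_transforms(self, series, a, b):
        window = 5
        direct = rolling_mean([a * v + b for v in series], window)
        assert np.allclose(direct, a * rolling_mean(series, window) + b, atol=1e-6)


class TestEffectSizes:
    def test_two_point_sample(self):
        assert cohens_d_one_sample([0.6, 0.8], 0.5) == pytest.approx(1.41421, abs=1e-4)

    def test_null_effect(self):
        assert cohens_d_one_sample([0.4, 0.6], 0.5) == 0.0

    def test_constant_sample_rejected(self):
        with pytest.raises(DegenerateInputError):
            cohens_d_one_sample([0.5, 0.5, 0.5], 0.4)

    def test_is_scale_and_shift_equivariant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.7, 0.1, size=40)
        d = cohens_d_one_sample(x, 0.5)
        assert cohens_d_one_sample(3 * x + 1, 3 * 0.5 + 1) == pytest.approx(d)
        assert cohens_d_one_sample(-x, -0.5) == pytest.approx(-d)


class TestGroupCompare:
    def test_identical_samples_give_null_result(self):
        res = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert res.cohens_d == 0.0
        assert res.df == 4

    def test_one_sample_constant_at_null_rejected(self):
        with pytest.raises(DegenerateInputError):
            group_compare([0.5, 0.5, 0.5], mu0=0.5)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            group_compare([1.0, 1.0], [2.0, 2.0])

    def test_two_sample_matches_pingouin(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.70, 0.15, size=130)
        b = rng.normal(0.69, 0.15, size=132)
        res = group_compare(a, b)
        ref = pg.ttest(a, b, correction=False).iloc[0]
        assert res.t == pytest.approx(ref["T"], abs=1e-9)
        assert res.df == ref["dof"]
        assert res.p_value == pytest.approx(ref["p_val"], abs=1e-9)
        assert abs(res.cohens_d) == pytest.approx(ref["cohen_d"], abs=1e-9)
        lo, hi = ref["CI95"]  # pingouin rounds the interval to 2 decimals
        assert res.ci_low == pytest.approx(lo, abs=6e-3)
        assert res.ci_high == pytest.approx(hi, abs=6e-3)

    def test_one_sample_matches_pingouin(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.55, 0.2, size=60)
        res = group_compare(x, mu0=0.5)
        ref = pg.ttest(x, 0.5).iloc[0]
        assert res.t == pytest.approx(ref["T"], abs=1e-9)
        assert res.p_value == pytest.approx(ref["p_val"], abs=1e-9)
        assert abs(res.cohens_d) == pytest.approx(ref["cohen_d"], abs=1e-9)

    def test_requires_a_comparison(self):
        with pytest.raises(ValidationError):
            group_compare([1.0, 2.0])


class TestRankCorrelation:
    def test_perfect_monotone_relations(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert rank_correlation(x, x)[0] == pytest.approx(1.0)
        assert rank_correlation(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_partial_agreement(self):
        rho, _ = rank_correlation([1, 2, 3], [2, 1, 3])
        assert rho == pytest.approx(0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            rank_correlation([1, 2, 3], [1, 2])

    def test_memoryless_agents_earn_chance_level_regardless_of_bias(self):
        # a choice that cannot anticipate the trial's allocation wins each of
        # the 50 allocated rewards with its choice probability, so expected
        # totals stay at 25 at every bias level
        for p in (0.1, 0.5, 0.9):
            totals = np.array(
                [
                    run_session(
                        AgentSpec("bernoulli", {"p_plus": p}), seed=s
                    ).total_obtained()
                    for s in range(300)
                ],
                dtype=float,
            )
            se = totals.std(ddof=1) / np.sqrt(len(totals))
            assert abs(totals.mean() - 25.0) < 4 * se
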