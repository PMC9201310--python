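"""W likelihood-ratio test, restricted chi-square, Y profiles, split halves."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

import oracles
from conftest import make_session
from trialchain import (
    IndependenceFit,
    Outcome,
    ScheduleConfig,
    SessionMeta,
    chi2_critical,
    chi2_into_state,
    count_transitions,
    estimate_zeroth_order,
    independence_policy,
    premature_carryover_policy,
    simulate_session,
    split_half_homogeneity,
    w_statistic,
    y_deviation,
)
from trialchain.diagnostics import FULL_TABLE_DOF
from trialchain.estimation import TransitionCounts


def _counts(mat):
    mat = np.asarray(mat, dtype=np.int64)
    return TransitionCounts(
        counts=mat,
        n_transitions=int(mat.sum()),
        start_totals=mat.sum(axis=1),
        end_totals=mat.sum(axis=0),
        state_totals=mat.sum(axis=1),
    )


UNIFORM = _counts(np.full((5, 5), 4))  # margins 20 each, E = 20*20/100 = 4 everywhere


def _simulated_counts(n, policy=None, seed=7):
    policy = policy or premature_carryover_policy(excess=0.25)
    meta = SessionMeta("s", "x", 0.5, 5.0, 5.0, max_trials=n)
    sess = simulate_session(policy, meta, ScheduleConfig(0.5, n, seed=seed))
    return count_transitions(sess)


class TestCriticalValues:
    def test_decision_rule_constants(self):
        assert chi2_critical(0.05, 16) == pytest.approx(26.30, abs=0.005)
        assert chi2_critical(0.05, 5) == pytest.approx(11.07, abs=0.005)
        assert FULL_TABLE_DOF == 16

    def test_monotone_in_dof(self):
        assert chi2_critical(0.05, 17) > chi2_critical(0.05, 16)

    @pytest.mark.parametrize("alpha,dof", [(0.0, 5), (1.0, 5), (0.05, 0)])
    def test_invalid_arguments(self, alpha, dof):
        with pytest.raises(ValueError):
            chi2_critical(alpha, dof)


class TestWStatistic:
    def test_identity_table(self):
        res = w_statistic(UNIFORM, estimate_zeroth_order(UNIFORM))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert not res.reject
        assert res.dof == 16

    def test_matches_independent_oracles(self):
        c = _simulated_counts(2000)
        fit = estimate_zeroth_order(c)
        res = w_statistic(c, fit)
        # hand-coded G summation oracle
        oracle = oracles.g_statistic(c.counts.tolist(), fit.expected.tolist())
        assert res.statistic == pytest.approx(oracle, abs=1e-9)
        # scipy's log-likelihood-ratio contingency test as a second, library oracle
        g, p, dof, _ = chi2_contingency(c.counts, correction=False, lambda_="log-likelihood")
        assert res.statistic == pytest.approx(g, abs=1e-9)
        assert dof == res.dof == 16
        assert res.statistic > 26.30 and res.reject

    def test_reject_matches_critical_rule(self):
        c = _simulated_counts(2000)
        res = w_statistic(c, estimate_zeroth_order(c))
        assert res.reject == (res.statistic > res.critical_value)
        assert 0.0 <= res.p_value <= 1.0

    def test_degenerate_cell_errors(self):
        bad_fit = IndependenceFit(
            state_probs=np.array([0.5, 0.5, 0.0, 0.0, 0.0]),
            expected=np.outer(UNIFORM.start_totals, [0.5, 0.5, 0, 0, 0]),
        )
        with pytest.raises(ValueError, match="degenerate"):
            w_statistic(UNIFORM, bad_fit)

    @pytest.mark.parametrize("excess,seed", [(0.0, 7), (0.0, 11), (0.05, 7), (0.05, 11)])
    def test_approximates_pearson_on_dense_tables(self, excess, seed):
        """On dense tables (all E >= 5) W tracks Pearson's chi-square within 5%.

        The equivalence of the likelihood-ratio and Pearson statistics is an
        asymptotic property under the null / local alternatives, so it is
        exercised on null and weak-carry-over tables; under a strong fixed
        alternative the two statistics legitimately diverge.
        """
        policy = (
            independence_policy() if excess == 0.0 else premature_carryover_policy(excess=excess)
        )
        c = _simulated_counts(5000, policy=policy, seed=seed)
        fit = estimate_zeroth_order(c)
        assert fit.expected.min() >= 5
        w = w_statistic(c, fit).statistic
        pearson, *_ = chi2_contingency(c.counts, correction=False)
        assert abs(w - pearson) / pearson < 0.05


class TestRestrictedChi2:
    def test_identity_column(self):
        res = chi2_into_state(UNIFORM, estimate_zeroth_order(UNIFORM), Outcome.PREMATURE)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert not res.reject
        assert res.dof == 5
        assert res.critical_value == pytest.approx(11.07, abs=0.005)

    def test_single_cell_perturbation(self):
        # +2*sqrt(E) on one start state with all E = 4 -> statistic = 4
        mat = np.full((5, 5), 4)
        mat[0, 2] += 4
        fit = estimate_zeroth_order(UNIFORM)  # E = 4 everywhere
        res = chi2_into_state(_counts(mat), fit, Outcome.PREMATURE)
        assert res.statistic == pytest.approx(4.0)
        oracle = oracles.pearson_chi2_column(mat.tolist(), fit.expected.tolist(), 2)
        assert res.statistic == pytest.approx(oracle, abs=1e-12)

    def test_never_expected_target_errors(self):
        fit = IndependenceFit(
            state_probs=np.array([1.0, 0.0, 0.0, 0.0, 0.0]),
            expected=np.outer(UNIFORM.start_totals, [1.0, 0, 0, 0, 0]),
        )
        with pytest.raises(ValueError):
            chi2_into_state(_counts(np.diag([100, 0, 0, 0, 0])), fit, Outcome.PREMATURE)

    def test_dof_is_configurable(self):
        res = chi2_into_state(UNIFORM, estimate_zeroth_order(UNIFORM), Outcome.PREMATURE, dof=4)
        assert res.dof == 4


class TestYDeviation:
    def test_identity_gives_zero(self):
        prof = y_deviation(UNIFORM, estimate_zeroth_order(UNIFORM), Outcome.PREMATURE)
        np.testing.assert_allclose(prof.y, 0.0, atol=1e-12)
        assert prof.defined.all()

    def test_unit_residual(self):
        # O = E + sqrt(E) in one cell -> Y = 1 there
        mat = np.full((5, 5), 4)
        mat[1, 2] += 2  # sqrt(4)
        fit = estimate_zeroth_order(UNIFORM)
        prof = y_deviation(_counts(mat), fit, Outcome.PREMATURE)
        assert prof.y[1] == pytest.approx(1.0)

    def test_sign_matches_observed_minus_expected(self):
        c = _simulated_counts(1000)
        fit = estimate_zeroth_order(c)
        prof = y_deviation(c, fit, Outcome.PREMATURE)
        diff = c.counts[:, 2] - fit.expected[:, 2]
        for i in range(5):
            if prof.defined[i] and diff[i] != 0:
                assert np.sign(prof.y[i]) == np.sign(diff[i])

    def test_matches_oracle(self):
        c = _simulated_counts(500)
        fit = estimate_zeroth_order(c)
        prof = y_deviation(c, fit, Outcome.PREMATURE)
        oracle = oracles.y_column(c.counts.tolist(), fit.expected.tolist(), 2)
        for i, v in enumerate(oracle):
            if v is None:
                assert not prof.defined[i]
            else:
                assert prof.y[i] == pytest.approx(v, abs=1e-12)

    def test_null_profile_centred_near_zero(self):
        """Under the independence policy the mean Y per start state is ~0."""
        policy = independence_policy()
        meta = SessionMeta("s", "x", 0.5, 5.0, 5.0, max_trials=200)
        ys = []
        for i in range(500):
            sess = simulate_session(policy, meta, ScheduleConfig(0.5, 200, seed=300_000 + i))
            c = count_transitions(sess)
            ys.append(y_deviation(c, estimate_zeroth_order(c), Outcome.PREMATURE).y)
        means = np.nanmean(np.asarray(ys), axis=0)
        assert (means > -0.15).all() and (means < 0.15).all()


class TestSplitHalf:
    def test_repeated_block_is_homogeneous(self):
        block = ["R", "NR", "premature", "R", "omission", "incorrect"]
        rep = split_half_homogeneity(make_session(block * 2))
        assert rep.max_abs_diff_into_target == pytest.approx(0.0)
        assert not rep.degenerate

    def test_homogeneous_chain_small_difference(self):
        policy = premature_carryover_policy(excess=0.25)
        meta = SessionMeta("s", "x", 0.5, 5.0, 5.0, max_trials=5000)
        sess = simulate_session(policy, meta, ScheduleConfig(0.5, 5000, seed=11))
        rep = split_half_homogeneity(sess)
        assert rep.max_abs_diff_into_target < 0.1
        P1, t1 = rep.first_half
        P2, t2 = rep.second_half
        assert t1.dof == t2.dof == 16

    def test_degenerate_halves_flagged(self):
        sess = make_session(["R"] * 4 + ["premature"] * 4)
        with pytest.warns(UserWarning, match="no start state"):
            rep = split_half_homogeneity(sess)
        assert rep.degenerate
        assert rep.max_abs_diff_into_target == 0.0

    def test_short_sessions_excluded_with_warning(self):
        long = make_session(["R", "NR"] * 6)
        short = make_session(["R", "NR", "R"], session="b")
        with pytest.warns(UserWarning, match="excluded 1"):
            rep = split_half_homogeneity([long, short])
        assert not rep.degenerate

    def test_all_short_errors(self):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                split_half_homogeneity(make_session(["R", "NR", "R"]))
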