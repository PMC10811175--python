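"""Worth estimation: likelihood, MLE, uncertainty, bootstrap, covariates."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tricot import (
    DisconnectedError,
    PairwiseComparison,
    PlackettLuce,
    Ranking,
    ValidationError,
    break_ranking_to_pairs,
    fit_bradley_terry,
    fit_pl_item_covariates,
    fit_plackett_luce,
    loglik_ranking,
    risk_assessment,
    sample_ranking_from_worths,
    win_rate,
)

ITEMS3 = ["A", "B", "C"]


def reference_loglik(theta, rankings, items):
    """Independent likelihood oracle: plain-python sequential Luce choices."""
    idx = {it: i for i, it in enumerate(items)}
    total = 0.0
    for r in rankings:
        seq = list(r)
        for j in range(len(seq) - 1):
            remaining = seq[j:]
            num = np.exp(theta[idx[seq[j]]])
            den = sum(np.exp(theta[idx[it]]) for it in remaining)
            total += np.log(num / den)
    return total


class TestLoglikRanking:
    def test_uniform_triad(self):
        assert loglik_ranking(np.zeros(3), ("A", "B", "C"), ITEMS3) == pytest.approx(
            -np.log(6)
        )

    def test_two_item_even(self):
        assert loglik_ranking(np.zeros(2), ("A", "B"), ["A", "B"]) == pytest.approx(
            np.log(0.5)
        )

    def test_three_to_one_worth_ratio(self):
        assert loglik_ranking(
            np.array([np.log(3), 0.0]), ("A", "B"), ["A", "B"]
        ) == pytest.approx(np.log(0.75))

    def test_unknown_item(self):
        with pytest.raises(ValidationError):
            loglik_ranking(np.zeros(3), ("A", "Z"), ITEMS3)

    @given(st.floats(-3, 3), st.integers(0, 5))
    @settings(max_examples=25, deadline=None)
    def test_shift_invariance(self, shift, seed):
        """Adding a constant to every log-worth leaves likelihoods unchanged."""
        rng = np.random.default_rng(seed)
        theta = rng.normal(0, 1, 4)
        items = ["A", "B", "C", "D"]
        r = tuple(rng.permutation(items))
        assert loglik_ranking(theta, r, items) == pytest.approx(
            loglik_ranking(theta + shift, r, items)
        )


class TestFitPlackettLuce:
    def test_two_item_closed_form(self):
        """A beats B 3 times out of 4: P(A>B) = 3/4, theta gap = log 3."""
        res = fit_plackett_luce([("A", "B")] * 3 + [("B", "A")])
        assert res.prob_outperform("A", "B") == pytest.approx(0.75, abs=1e-6)
        assert res.params[0] - res.params[1] == pytest.approx(np.log(3), abs=1e-5)

    def test_symmetric_data_zero_theta(self, symmetric_rankings):
        res = fit_plackett_luce(symmetric_rankings)
        assert np.allclose(res.params, 0.0, atol=1e-8)

    def test_matches_grid_oracle(self):
        """MLE agrees with a coarse-to-fine grid search over the likelihood
        (independent reference implementation) within 1e-3."""
        rng = np.random.default_rng(99)
        theta_true = {"A": 0.7, "B": 0.0, "C": -0.7}
        rankings = [
            sample_ranking_from_worths(theta_true, ITEMS3, rng).ordered_items
            for _ in range(20)
        ]
        res = fit_plackett_luce(rankings)
        # grid over (theta_A, theta_B) with theta_C = -theta_A - theta_B
        center = np.zeros(2)
        width = 3.0
        for _ in range(6):
            grid = [
                np.array([a, b, -a - b])
                for a in np.linspace(center[0] - width, center[0] + width, 21)
                for b in np.linspace(center[1] - width, center[1] + width, 21)
            ]
            lls = [reference_loglik(th, rankings, ITEMS3) for th in grid]
            best = grid[int(np.argmax(lls))]
            center, width = best[:2], width / 5
        assert np.allclose(res.params, best, atol=1e-3)
        assert res.llf == pytest.approx(reference_loglik(res.params, rankings, ITEMS3))

    def test_loglik_nonpositive_and_gradient_small(self, five_item_trial):
        res = fit_plackett_luce(five_item_trial.rankings)
        assert res.llf < 0
        assert res.converged
        assert res.grad_norm < 1e-4
        assert res.params.sum() == pytest.approx(0.0, abs=1e-10)
        assert res.worth.sum() == pytest.approx(1.0, abs=1e-12)

    def test_disconnected_refused_with_components(self):
        with pytest.raises(DisconnectedError) as err:
            fit_plackett_luce([("A", "B", "C"), ("D", "E", "F")])
        assert len(err.value.components) == 2

    def test_vcov_symmetric_psd(self, five_item_trial):
        res = fit_plackett_luce(five_item_trial.rankings)
        assert np.allclose(res.vcov, res.vcov.T)
        assert np.all(np.linalg.eigvalsh(res.vcov) > -1e-10)


class TestBradleyTerry:
    def test_same_ordering_as_pl(self):
        pairs = [
            p for _ in range(10) for p in break_ranking_to_pairs(Ranking(("A", "B", "C")))
        ]
        bt = fit_bradley_terry(pairs)
        pl = fit_plackett_luce([("A", "B", "C")] * 10, regularize=True)
        assert list(bt.theta.sort_values(ascending=False).index) == list(
            pl.theta.sort_values(ascending=False).index
        )

    def test_single_pair_separation_flagged(self):
        res = fit_bradley_terry([PairwiseComparison("A", "B")])
        assert set(res.separated) == {"A", "B"}  # winner diverges, loser vanishes

    def test_balanced_pair_equal_theta(self):
        res = fit_bradley_terry([PairwiseComparison("A", "B"), PairwiseComparison("B", "A")])
        assert res.params == pytest.approx([0.0, 0.0], abs=1e-8)

    def test_rank_breaking_understates_uncertainty(self, five_item_trial):
        """Rank-breaking treats the m(m-1)/2 pairs from one ranking as
        independent, so the naive Bradley-Terry fit on broken pairs reports
        anti-conservative (smaller) nominal standard errors than the
        Plackett-Luce fit on the intact rankings, while both recover the
        same item ordering."""
        pl = fit_plackett_luce(five_item_trial.rankings)
        pairs = [
            p for r in five_item_trial.rankings for p in break_ranking_to_pairs(r)
        ]
        bt = fit_bradley_terry(pairs)
        assert (bt.bse.to_numpy() <= pl.bse.to_numpy() + 1e-12).all()
        assert list(bt.theta.sort_values().index) == list(pl.theta.sort_values().index)


class TestProbOutperform:
    def test_equal_worths(self, symmetric_rankings):
        res = fit_plackett_luce(symmetric_rankings)
        assert res.prob_outperform("A", "B") == pytest.approx(0.5, abs=1e-8)

    def test_ratio_and_complement(self):
        res = fit_plackett_luce([("A", "B")] * 3 + [("B", "A")])
        assert res.prob_outperform("A", "B") == pytest.approx(0.75, abs=1e-6)
        assert res.prob_outperform("B", "A") == pytest.approx(0.25, abs=1e-6)

    def test_same_item_rejected(self, symmetric_rankings):
        res = fit_plackett_luce(symmetric_rankings)
        with pytest.raises(ValidationError):
            res.prob_outperform("A", "A")


class TestQuasiVariances:
    def test_two_item_minimum_norm(self):
        res = fit_plackett_luce([("A", "B")] * 3 + [("B", "A")] * 2)
        qv = res.quasi_variances()
        v = res.contrast_variance("A", "B")
        assert qv.q.sum() == pytest.approx(v)
        assert qv.q[0] == pytest.approx(qv.q[1])
        assert qv.max_relative_error == 0.0

    def test_symmetric_design_equal_q(self, symmetric_rankings):
        qv = fit_plackett_luce(symmetric_rankings * 3).quasi_variances()
        assert np.allclose(qv.q, qv.q[0], rtol=1e-6)
        assert qv.max_relative_error < 1e-6

    def test_contrast_variances_within_10pct(self):
        """Simulated 6-item trial: q_i + q_j reproduces every pairwise
        contrast variance within 10% relative error."""
        from tricot import TrialTruth, simulate_trial

        truth = TrialTruth(
            tuple(f"V{i}" for i in range(6)), (0.6, 0.3, 0.1, -0.1, -0.3, -0.6)
        )
        trial = simulate_trial(truth, 200, seed=77)
        res = fit_plackett_luce(trial.rankings)
        qv = res.quasi_variances()
        assert qv.max_relative_error < 0.10


class TestBayesianBootstrap:
    def test_reproducible(self, five_item_trial):
        res = fit_plackett_luce(five_item_trial.rankings)
        d1 = res.bayesian_bootstrap(n_draws=25, seed=5)
        d2 = res.bayesian_bootstrap(n_draws=25, seed=5)
        assert np.array_equal(d1.theta, d2.theta)

    def test_equal_weights_reproduce_mle(self, five_item_trial):
        res = fit_plackett_luce(five_item_trial.rankings)
        forced = res.model.fit(weights=np.ones(res.n_rankings), check_connectivity=False)
        assert np.allclose(forced.params, res.params, atol=1e-6)

    def test_mean_near_mle(self, five_item_trial):
        res = fit_plackett_luce(five_item_trial.rankings)
        draws = res.bayesian_bootstrap(n_draws=200, seed=11)
        se = res.bse.to_numpy()
        mc_se = draws.theta.std(axis=0) / np.sqrt(draws.theta.shape[0])
        assert np.all(np.abs(draws.theta.mean(axis=0) - res.params) < 3 * (se + mc_se))

    def test_rows_mean_zero(self, five_item_trial):
        res = fit_plackett_luce(five_item_trial.rankings)
        draws = res.bayesian_bootstrap(n_draws=25, seed=5)
        assert np.allclose(draws.theta.mean(axis=1), 0.0, atol=1e-9)


class TestRiskAssessment:
    def test_dominant_item_high_reliability(self):
        from tricot import TrialTruth, simulate_trial

        truth = TrialTruth(("NEW", "CHK", "X1", "X2"), (1.0, -1.0, 0.0, 0.0))
        trial = simulate_trial(truth, 300, seed=13)
        res = fit_plackett_luce(trial.rankings)
        draws = res.bayesian_bootstrap(n_draws=200, seed=13)
        table = risk_assessment(draws, "CHK")
        assert table.loc["NEW", "reliability"] >= 0.95

    def test_check_vs_itself_zero(self, five_item_trial):
        res = fit_plackett_luce(five_item_trial.rankings)
        draws = res.bayesian_bootstrap(n_draws=50, seed=3)
        assert risk_assessment(draws, "V3").loc["V3", "reliability"] == 0.0

    def test_symmetric_items_near_half(self, symmetric_rankings):
        res = fit_plackett_luce(symmetric_rankings * 30)
        draws = res.bayesian_bootstrap(n_draws=400, seed=21)
        rel = risk_assessment(draws, "C").loc["A", "reliability"]
        assert 0.35 < rel < 0.65

    def test_missing_check(self, five_item_trial):
        res = fit_plackett_luce(five_item_trial.rankings)
        draws = res.bayesian_bootstrap(n_draws=10, seed=1)
        with pytest.raises(ValidationError):
            risk_assessment(draws, "NOPE")


def test_win_rate_observed_fraction():
    rankings = [("A", "B", "C"), ("B", "A", "C"), ("A", "C", "B"), ("C", "B", "A")]
    rankings = [Ranking(r) for r in rankings]
    assert win_rate(rankings, "A", "B") == pytest.approx(0.5)
    assert win_rate(rankings, "A", "C") == pytest.approx(0.75)


class TestItemCovariates:
    def test_saturated_dummies_match_unconstrained(self, five_item_trial):
        rankings = five_item_trial.rankings[:150]
        res = fit_plackett_luce(rankings)
        X = pd.DataFrame(np.eye(5), index=res.items, columns=res.items)
        cov_res = fit_pl_item_covariates(rankings, X)
        assert np.allclose(cov_res.implied.params, res.params, atol=1e-6)

    def test_binary_feature_two_worth_levels(self):
        rng = np.random.default_rng(5)
        items = ["A", "B", "C", "D"]
        theta = {"A": 0.6, "B": 0.6, "C": -0.6, "D": -0.6}
        rankings = [
            sample_ranking_from_worths(theta, items, rng).ordered_items
            for _ in range(400)
        ]
        X = pd.DataFrame({"grp": [1.0, 1.0, 0.0, 0.0]}, index=items)
        res = fit_pl_item_covariates(rankings, X)
        implied = res.implied.theta
        assert implied["A"] == pytest.approx(implied["B"], abs=1e-8)
        assert implied["C"] == pytest.approx(implied["D"], abs=1e-8)
        assert implied["A"] > implied["C"]

    def test_parameter_recovery_within_2se(self):
        rng = np.random.default_rng(123)
        items = [f"V{i}" for i in range(8)]
        X = pd.DataFrame(
            rng.normal(0, 1, (8, 2)), index=items, columns=["f1", "f2"]
        )
        beta_true = np.array([1.0, -0.5])
        theta = dict(zip(items, X.to_numpy() @ beta_true))
        triads = [list(rng.choice(items, 3, replace=False)) for _ in range(500)]
        rankings = [
            sample_ranking_from_worths(theta, tr, rng).ordered_items for tr in triads
        ]
        res = fit_pl_item_covariates(rankings, X)
        assert np.all(np.abs(res.beta.to_numpy() - beta_true) < 2 * res.beta_se.to_numpy())

    def test_rank_deficient_rejected(self, five_item_trial):
        X = pd.DataFrame(
            {"a": [1.0] * 5, "b": [2.0] * 5},
            index=["V1", "V2", "V3", "V4", "V5"],
        )
        with pytest.raises(ValidationError):
            fit_pl_item_covariates(five_item_trial.rankings[:50], X)


def test_parameter_recovery_improves_with_n():
    """Mean absolute error of theta decreases across n = 50, 200, 800."""
    from tricot import TrialTruth, simulate_trial

    truth = TrialTruth(
        tuple(f"V{i}" for i in range(6)), (0.8, 0.5, 0.2, -0.2, -0.5, -0.8)
    )
    maes = []
    for n in (50, 200, 800):
        errs = []
        for rep in range(3):
            trial = simulate_trial(truth, n, seed=1000 * n + rep)
            res = fit_plackett_luce(trial.rankings, regularize=True)
            errs.append(np.mean(np.abs(res.params - np.array(truth.theta))))
        maes.append(np.mean(errs))
    assert maes[0] > maes[1] > maes[2]
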