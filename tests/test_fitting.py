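"""Estimation: grid + closed-form least squares, BIC, model comparison."""

import math

import numpy as np
import pytest

from moodrpe.fitting import (
    DEFAULT_GAMMA_GRID,
    FitResult,
    MissingFitsError,
    UnderdeterminedError,
    compare_models,
    fit_mood_model,
    information_criterion,
)
from moodrpe.model import MODEL_SPECS, MoodParams, predict_happiness, term_series
from moodrpe.task import Gamble, Session, TrialRecord


class TestFit:
    def test_noise_free_recovery_is_exact(self, lab_session, grid_params):
        """Self-consistency: ratings generated by the model itself are
        recovered to 1e-6 (gamma exactly, since it lies on the grid)."""
        ratings = predict_happiness(grid_params, lab_session)
        fit = fit_mood_model(lab_session, ratings)
        assert fit.params.gamma == grid_params.gamma
        for attr in ("w0", "w_cr", "w_ev", "w_rpe"):
            assert getattr(fit.params, attr) == pytest.approx(
                getattr(grid_params, attr), abs=1e-6
            )
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_ratings_degenerate_convention(self, lab_session):
        ratings = np.full(lab_session.n_probes, 0.5)
        with pytest.warns(UserWarning, match="zero rating variance"):
            fit = fit_mood_model(lab_session, ratings)
        assert fit.params.w0 == 0.5
        assert fit.params.w_cr == fit.params.w_ev == fit.params.w_rpe == 0.0
        assert fit.r2 == 0.0
        assert fit.degenerate

    def test_underdetermined_raises(self, two_trial_session):
        with pytest.raises(UnderdeterminedError):
            fit_mood_model(two_trial_session, np.array([0.5]))

    def test_noisy_weight_recovery(self, grid_params):
        """Monte-Carlo recovery: at rating noise sd 0.05 on lab-length
        sessions, the median absolute error of each weight stays below
        25% of its generating value (100 replicates)."""
        from moodrpe.cohort import ChoiceParams, build_session_template, simulate_choices

        rng = np.random.default_rng(2024)
        errs = {"w_cr": [], "w_ev": [], "w_rpe": []}
        for _ in range(100):
            template = build_session_template("lab", int(rng.integers(2**31 - 1)))
            sess = simulate_choices(template, ChoiceParams(), int(rng.integers(2**31 - 1)))
            pred = predict_happiness(grid_params, sess)
            ratings = pred + rng.normal(0, 0.05, pred.size)
            fit = fit_mood_model(sess, ratings)
            for attr in errs:
                errs[attr].append(
                    abs(getattr(fit.params, attr) - getattr(grid_params, attr))
                )
        for attr, e in errs.items():
            assert np.median(e) < 0.25 * getattr(grid_params, attr), attr

    def test_grid_search_matches_brute_force_profiling(self, lab_session, grid_params):
        """The grid + closed-form estimator attains the same minimum as a
        dense 2-d scan over gamma × w_cr with the other weights profiled
        by least squares."""
        rng = np.random.default_rng(5)
        pred = predict_happiness(grid_params, lab_session)
        y = pred + rng.normal(0, 0.05, pred.size)
        fit = fit_mood_model(lab_session, y)

        idx = np.asarray(lab_session.probe_after) - 1
        best = np.inf
        best_gamma = None
        from scipy.signal import lfilter

        series = term_series(lab_session)
        for gamma in DEFAULT_GAMMA_GRID:
            cols = {
                k: lfilter([1.0], [1.0, -gamma], series[k])[idx]
                for k in ("cr", "ev", "rpe")
            }
            for w_cr in np.linspace(-1, 1, 401):
                resid_target = y - w_cr * cols["cr"]
                X = np.column_stack([np.ones(y.size), cols["ev"], cols["rpe"]])
                beta, *_ = np.linalg.lstsq(X, resid_target, rcond=None)
                sse = float(np.sum((resid_target - X @ beta) ** 2))
                if sse < best:
                    best, best_gamma = sse, gamma
        # agreement to the scan's resolution
        assert fit.sse <= best + 1e-9
        assert abs(fit.params.gamma - best_gamma) <= 0.01 + 1e-12

    def test_r2_invariant_to_money_rescaling(self, lab_session, grid_params):
        rng = np.random.default_rng(9)
        pred = predict_happiness(grid_params, lab_session)
        y = pred + rng.normal(0, 0.05, pred.size)
        fit1 = fit_mood_model(lab_session, y)

        c = 7.3
        scaled_trials = []
        for tr in lab_session.trials:
            g = tr.offered_gamble
            scaled_trials.append(
                TrialRecord(
                    index=tr.index,
                    choice=tr.choice,
                    cr=tr.cr * c,
                    ev=tr.ev * c,
                    outcome=None if tr.outcome is None else tr.outcome * c,
                    revealed=tr.revealed,
                    rpe=tr.rpe * c,
                    offered_certain=None if tr.offered_certain is None else tr.offered_certain * c,
                    offered_gamble=None if g is None else Gamble(g.outcome_hi * c, g.outcome_lo * c, g.p_hi),
                )
            )
        scaled = Session("lab", scaled_trials, list(lab_session.probe_after))
        fit2 = fit_mood_model(scaled, y)
        assert fit2.r2 == pytest.approx(fit1.r2, abs=1e-9)
        assert fit2.params.w_cr == pytest.approx(fit1.params.w_cr / c, rel=1e-6)


class TestInformationCriterion:
    def test_halving_sse_drops_ic_by_n_ln2(self):
        n, k = 66, 5
        assert information_criterion(0.1, n, k) - information_criterion(0.05, n, k) == pytest.approx(n * math.log(2))

    def test_extra_parameter_costs_ln_n(self):
        n = 66
        assert information_criterion(0.1, n, 5) - information_criterion(0.1, n, 4) == pytest.approx(math.log(n))

    def test_numeric_model_ranking(self):
        """A 5-parameter model at sse 0.165 beats a 4-parameter model at
        sse 0.25 for 66 probes."""
        full = information_criterion(0.165, 66, 5)
        reduced = information_criterion(0.25, 66, 4)
        assert full < reduced

    def test_preconditions(self):
        with pytest.raises(ValueError):
            information_criterion(0.1, 0, 2)
        with pytest.raises(ValueError):
            information_criterion(-0.1, 10, 2)


def _mk_fit(sse, n=66, k=4, sid="a"):
    return FitResult(
        params=MoodParams(w0=0.5, gamma=0.5),
        r2=0.5, sse=sse, n_probes=n, k_params=k,
        ic=information_criterion(sse, n, k), spec_id=sid,
    )


class TestCompareModels:
    def test_missing_fits_are_listed(self):
        fits = {"p1": {"a": _mk_fit(0.2)}, "p2": {"a": _mk_fit(0.2), "b": _mk_fit(0.3)}}
        with pytest.raises(MissingFitsError, match="p1"):
            compare_models(fits)

    def test_tie_is_reported_not_broken(self):
        fits = {"p1": {"a": _mk_fit(0.2, sid="a"), "b": _mk_fit(0.2, sid="b")}}
        cmp = compare_models(fits)
        assert cmp.winners == ["a", "b"]
        assert cmp.winning_spec is None
        assert cmp.tied_participants == 1

    def test_winner_minimizes_summed_ic(self):
        fits = {
            "p1": {"a": _mk_fit(0.2), "b": _mk_fit(0.4)},
            "p2": {"a": _mk_fit(0.3), "b": _mk_fit(0.25)},
        }
        cmp = compare_models(fits)
        assert cmp.winners == ["a"]
        assert cmp.best_counts == {"a": 1, "b": 1}
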