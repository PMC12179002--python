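"""Panel likelihood evaluation, maximization and RR reporting."""

import math

import numpy as np
import pandas as pd
import pytest

from oracles import grid_mle_two_state, two_state_panel_loglik

from cohortmsm import (
    FitResult,
    MultistateModelSpec,
    PanelDataset,
    ParameterVector,
    Term,
    fit_panel_mle,
    panel_log_likelihood,
    relative_risk_table,
    wald_rr,
)
from cohortmsm.likelihood import PanelLikelihood


def _round2(x):
    return math.floor(abs(x) * 100 + 0.5) / 100 * (1 if x >= 0 else -1)


def assert_printed(computed, printed):
    """Printed inputs carry 3-decimal rounding, so a recomputed 2-decimal
    cell may sit one unit of the last digit from the printed one."""
    assert abs(_round2(computed) - printed) <= 0.01 + 1e-9


class TestPanelLogLikelihood:
    def test_single_assessment_contributes_nothing(self, two_state_spec, two_state_params):
        data = PanelDataset(pd.DataFrame({"subject_id": [1], "time": [0.0], "state": [0]}))
        assert panel_log_likelihood(two_state_spec, two_state_params, data) == 0.0

    def test_two_state_closed_form(self, two_state_spec):
        lam = 0.3
        params = ParameterVector(log_baseline={"lam": [math.log(lam)]})
        data = PanelDataset(pd.DataFrame({"subject_id": [1, 1], "time": [0.0, 2.0], "state": [0, 1]}))
        ll = panel_log_likelihood(two_state_spec, params, data)
        assert ll == pytest.approx(math.log(1 - math.exp(-2 * lam)), abs=1e-10)

    def test_matches_direct_product_oracle(self, two_state_spec, simulate_two_state_panel):
        data = simulate_two_state_panel(0.25, 30, np.arange(0.0, 8.0), seed=3)
        for lam in (0.1, 0.25, 0.6):
            params = ParameterVector(log_baseline={"lam": [math.log(lam)]})
            ll = panel_log_likelihood(two_state_spec, params, data)
            assert ll == pytest.approx(two_state_panel_loglik(data.frame, lam), abs=1e-8)

    def test_additive_over_independent_subjects(self, two_state_spec, two_state_params, simulate_two_state_panel):
        a = simulate_two_state_panel(0.4, 10, np.arange(0.0, 5.0), seed=1)
        b_frame = simulate_two_state_panel(0.4, 10, np.arange(0.0, 5.0), seed=2).frame
        b_frame["subject_id"] += 1000
        b = PanelDataset(b_frame)
        ll_a = panel_log_likelihood(two_state_spec, two_state_params, a)
        ll_b = panel_log_likelihood(two_state_spec, two_state_params, b)
        ll_ab = panel_log_likelihood(two_state_spec, two_state_params, a.concat(b))
        assert ll_ab == pytest.approx(ll_a + ll_b, abs=1e-9)

    def test_disallowed_path_gives_minus_inf_with_diagnostic(self, two_state_spec, two_state_params):
        data = PanelDataset(
            pd.DataFrame({"subject_id": [9, 9, 9], "time": [0.0, 1.0, 2.0], "state": [0, 1, 0]})
        )
        with pytest.raises(ValueError, match="absorbing"):
            panel_log_likelihood(two_state_spec, two_state_params, data)
        # a recovery that is simply not in the transition set (non-absorbing source)
        spec = MultistateModelSpec(n_states=2, transitions=((0, 1),), baseline={(0, 1): "lam"})
        with pytest.warns(UserWarning, match="subject 9.*1->0"):
            ll = panel_log_likelihood(spec, two_state_params, data)
        assert ll == -np.inf

    def test_record_starting_in_absorbing_state_rejected(self, two_state_spec, two_state_params):
        data = PanelDataset(pd.DataFrame({"subject_id": [1, 1], "time": [0.0, 1.0], "state": [1, 1]}))
        with pytest.raises(ValueError, match="begins in an absorbing state"):
            panel_log_likelihood(two_state_spec, two_state_params, data)

    def test_exactly_observed_death_contributes_density(self):
        # illness-death with an exactly observed death time: the interval
        # contribution is sum_s P(t0,t)[k,s] * q_{s,dead}
        spec = MultistateModelSpec(
            n_states=3, transitions=((0, 1), (0, 2), (1, 2)), absorbing=frozenset({2})
        )
        lam01, lam02, lam12 = 0.3, 0.1, 0.5
        params = ParameterVector(
            log_baseline={
                "q01": [math.log(lam01)],
                "q02": [math.log(lam02)],
                "q12": [math.log(lam12)],
            }
        )
        data = PanelDataset(pd.DataFrame({"subject_id": [1, 1], "time": [0.0, 2.0], "state": [0, 2]}))
        ll_exact = panel_log_likelihood(spec, params, data, exact_death_states=(2,))
        from cohortmsm import transition_probability

        p = transition_probability(spec, params, {}, 0.0, 2.0)
        expected = p[0, 0] * lam02 + p[0, 1] * lam12
        assert ll_exact == pytest.approx(math.log(expected), abs=1e-10)
        # and differs from the interval-censored contribution
        assert ll_exact != pytest.approx(math.log(p[0, 2]), abs=1e-6)

    def test_grouped_and_generic_exponential_paths_agree(self, two_state_spec, simulate_two_state_panel):
        data = simulate_two_state_panel(0.3, 40, np.arange(0.0, 6.0, 0.7), seed=11)
        ev = PanelLikelihood(two_state_spec, data)
        assert ev.seg_groups is not None
        x = np.array([math.log(0.3)])
        grouped = ev.interval_probabilities(x)
        ev.seg_groups = None
        generic = ev.interval_probabilities(x)
        assert np.abs(grouped - generic).max() < 1e-12


class TestFit:
    def test_recovers_simulation_truth(self, two_state_spec, simulate_two_state_panel):
        lam = 0.10
        data = simulate_two_state_panel(lam, 2000, np.arange(0.0, 8.5), seed=42)
        fit = fit_panel_mle(two_state_spec, data, compute_se=True)
        lam_hat = math.exp(fit.x[0])
        # ~1100 expected events: 3 Monte-Carlo s.e. on the rate scale
        assert fit.converged
        assert abs(lam_hat - lam) < 3 * lam / math.sqrt(1000)
        assert fit.se["log_lam[0]"] == pytest.approx(1 / math.sqrt(1000), rel=0.4)

    def test_matches_grid_search_oracle(self, two_state_spec, simulate_two_state_panel):
        data = simulate_two_state_panel(0.3, 150, np.arange(0.0, 6.0), seed=5)
        fit = fit_panel_mle(two_state_spec, data, compute_se=False)
        oracle = grid_mle_two_state(data.frame)
        assert math.exp(fit.x[0]) == pytest.approx(oracle, abs=1e-4)

    def test_refit_from_optimum_is_fixed_point(self, two_state_spec, simulate_two_state_panel):
        data = simulate_two_state_panel(0.2, 100, np.arange(0.0, 6.0), seed=6)
        fit = fit_panel_mle(two_state_spec, data, compute_se=False)
        refit = fit_panel_mle(two_state_spec, data, init=fit.params, compute_se=False)
        assert abs(refit.loglik - fit.loglik) < 1e-6

    def test_unobserved_transition_warns(self, simulate_two_state_panel):
        spec = MultistateModelSpec(
            n_states=3, transitions=((0, 1), (0, 2)), absorbing=frozenset({1, 2})
        )
        data = simulate_two_state_panel(0.2, 20, np.arange(0.0, 4.0), seed=8)
        with pytest.warns(UserWarning, match="never observed"):
            fit_panel_mle(spec, data, compute_se=False, maxiter=30)

    def test_deterministic_given_inputs(self, two_state_spec, simulate_two_state_panel):
        data = simulate_two_state_panel(0.3, 60, np.arange(0.0, 5.0), seed=9)
        f1 = fit_panel_mle(two_state_spec, data, compute_se=True)
        f2 = fit_panel_mle(two_state_spec, data, compute_se=True)
        assert np.array_equal(f1.x, f2.x)
        assert np.array_equal(f1.covariance, f2.covariance)


class TestRelativeRiskTable:
    def _fit_from_printed(self, est, se):
        spec = MultistateModelSpec(
            n_states=2,
            transitions=((0, 1),),
            absorbing=frozenset({1}),
            design={(0, 1): tuple(Term(coef=k) for k in est)},
        )
        names = spec.parameter_names()
        x = np.array([0.0] + [est[k] for k in spec.coefficient_names])
        cov = np.diag([0.0] + [se[k] ** 2 for k in spec.coefficient_names])
        return FitResult(
            spec=spec, params=ParameterVector.from_array(spec, x), loglik=0.0,
            converged=True, n_iter=0, message="", x=x, covariance=cov,
            parameter_names=names,
        )

    def test_published_cells(self):
        # sex row of the onset table; biologics -> marker-normalization row
        fit = self._fit_from_printed({"theta2": 0.117, "eta01": 0.335}, {"theta2": 0.298, "eta01": 0.101})
        tab = relative_risk_table(fit)
        assert_printed(tab.loc["theta2", "rr"], 1.12)
        assert_printed(tab.loc["theta2", "lo"], 0.63)
        assert_printed(tab.loc["theta2", "hi"], 2.01)
        assert _round2(tab.loc["eta01", "rr"]) == 1.40
        assert _round2(tab.loc["eta01", "lo"]) == 1.15
        assert _round2(tab.loc["eta01", "hi"]) == 1.70

    def test_null_effect(self):
        assert wald_rr(0.0, 0.0) == (1.0, 1.0, 1.0)

    def test_linear_combination_uses_covariance(self):
        fit = self._fit_from_printed({"a": 1.0, "b": -0.5}, {"a": 0.2, "b": 0.1})
        tab = relative_risk_table(fit, combinations={"a+b": {"a": 1.0, "b": 1.0}})
        assert tab.loc["a+b", "rr"] == pytest.approx(math.exp(0.5))
        assert tab.loc["a+b", "se"] == pytest.approx(math.hypot(0.2, 0.1))

    def test_unknown_coefficient_raises(self):
        fit = self._fit_from_printed({"a": 1.0}, {"a": 0.2})
        with pytest.raises(KeyError):
            relative_risk_table(fit, coefficients=["nope"])


class TestPanelDatasetValidation:
    def test_duplicate_assessment_times_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PanelDataset(pd.DataFrame({"subject_id": [1, 1], "time": [1.0, 1.0], "state": [0, 0]}))

    def test_rows_sorted_within_subject(self):
        ds = PanelDataset(
            pd.DataFrame({"subject_id": [1, 1], "time": [2.0, 1.0], "state": [1, 0]})
        )
        assert list(ds.frame["time"]) == [1.0, 2.0]

    def test_state_outside_space_rejected(self, two_state_spec):
        ds = PanelDataset(pd.DataFrame({"subject_id": [1, 1], "time": [0.0, 1.0], "state": [0, 7]}))
        with pytest.raises(ValueError, match="state code 7"):
            ds.validate_for(two_state_spec)
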