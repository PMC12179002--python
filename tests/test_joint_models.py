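"""Joint-process builders, parameter sharing and registry models."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from test_likelihood import assert_printed, _round2

from cohortmsm import (
    FitResult,
    ParameterVector,
    RegistryRecord,
    build_fmt_model,
    build_generator,
    build_illness_death_enrolment_model,
    build_psa_onset_model,
    combined_effect_rr,
    fmt_state_code,
    fmt_state_decode,
    registry_enrolment_loglik,
    relative_risk_table,
    state_entry_risk,
)
from cohortmsm.joint import fit_registry_enrolment

TABLE2_EST = {
    "eta01": 0.335, "eta02_V1": 0.686, "eta02_V2": -0.074,
    "eta11": 0.120, "eta12_V1": 0.813, "eta12_V2": 0.157,
    "phi1": 0.618, "phi2_V1": 0.347, "phi2_V2": 1.004,
    "beta1": 0.554, "beta2": 1.081, "beta3": -1.657,
    "beta4_V1": 0.327, "beta4_V2": 1.334, "beta4_V3": 0.117,
}
TABLE2_SE = {
    "eta01": 0.101, "eta02_V1": 0.419, "eta02_V2": 0.273,
    "eta11": 0.101, "eta12_V1": 0.461, "eta12_V2": 0.333,
    "phi1": 0.197, "phi2_V1": 0.393, "phi2_V2": 0.282,
    "beta1": 0.399, "beta2": 0.297, "beta3": 0.732,
    "beta4_V1": 0.528, "beta4_V2": 0.360, "beta4_V3": 0.217,
}
TABLE2_PRINTED = {  # (RR, lo, hi)
    "eta01": (1.40, 1.15, 1.70), "eta02_V1": (1.99, 0.87, 4.51), "eta02_V2": (0.93, 0.54, 1.59),
    "eta11": (1.13, 0.93, 1.37), "eta12_V1": (2.25, 0.91, 5.57), "eta12_V2": (1.17, 0.61, 2.25),
    "phi1": (1.86, 1.26, 2.73), "phi2_V1": (1.42, 0.65, 3.06), "phi2_V2": (2.73, 1.57, 4.75),
    "beta1": (1.74, 0.80, 3.80), "beta2": (2.95, 1.65, 5.27), "beta3": (0.19, 0.05, 0.80),
    "beta4_V1": (1.39, 0.49, 3.91), "beta4_V2": (3.79, 1.87, 7.69), "beta4_V3": (1.12, 0.74, 1.72),
}


class TestPsaOnsetBuilder:
    def test_structure(self):
        spec = build_psa_onset_model()
        assert spec.transitions == ((0, 1),)
        assert spec.baseline_families == ("lambda12",)
        assert spec.coefficient_names == ("theta1", "theta2", "theta3")
        assert spec.n_pieces == 1

    def test_female_baseline_intensity(self, table1_params, female_cov):
        q = build_generator(build_psa_onset_model(), table1_params, female_cov, 0.0)
        assert q[0, 1] == pytest.approx(math.exp(-4.379), rel=1e-12)

    def test_death_extension_with_zero_mortality_preserves_risk(self, table1_params, male_cov):
        spec2 = build_psa_onset_model()
        spec3 = build_psa_onset_model(include_death=True)
        params3 = ParameterVector(
            log_baseline={**{k: v.copy() for k, v in table1_params.log_baseline.items()},
                          "lambda13": [-30.0], "lambda23": [-30.0]},
            coefficients=dict(table1_params.coefficients),
        )
        r2 = state_entry_risk(spec2, table1_params, male_cov, 0, 1, 20.0)
        r3 = state_entry_risk(spec3, params3, male_cov, 0, 1, 20.0)
        assert r3 == pytest.approx(r2, abs=1e-6)


class TestFmtBuilder:
    def test_state_coding_bijection(self):
        codes = {fmt_state_code(z, x, b) for z in (0, 1) for x in (0, 1) for b in (0, 1)}
        assert codes == set(range(8))
        for c in range(8):
            assert fmt_state_code(*fmt_state_decode(c)) == c

    def test_parameter_layout(self):
        spec = build_fmt_model()
        assert len(spec.transitions) == 10  # 4 marker flips, 2 initiations, 4 failures
        assert set(spec.baseline_families) == {"x01", "x10", "b01", "z01"}
        assert len(spec.coefficient_names) == 18
        assert len(spec.parameter_names()) == 4 * 3 + 18
        assert spec.cutpoints == (5.0, 10.0)

    def _params(self):
        coefs = dict(TABLE2_EST)
        coefs.update({"eta02_V3": 0.0, "eta12_V3": 0.0, "phi2_V3": 0.0})
        spec = build_fmt_model()
        return spec, ParameterVector(
            log_baseline={f: [0.0, 0.0, 0.0] for f in spec.baseline_families},
            coefficients=coefs,
        )

    def test_failure_intensity_combines_marker_treatment_interaction(self):
        spec, params = self._params()
        cov = {"V1": 0.0, "V2": 0.0, "V3": 0.0}
        q = build_generator(spec, params, cov, 1.0)
        ratio = q[fmt_state_code(0, 1, 1), fmt_state_code(1, 1, 1)] / q[
            fmt_state_code(0, 0, 0), fmt_state_code(1, 0, 0)
        ]
        assert ratio == pytest.approx(math.exp(0.554 + 1.081 - 1.657), rel=1e-12)

    def test_failure_states_are_absorbing(self):
        spec, params = self._params()
        q = build_generator(spec, params, {"V1": 0, "V2": 0, "V3": 0}, 7.0)
        for x in (0, 1):
            for b in (0, 1):
                assert np.all(q[fmt_state_code(1, x, b)] == 0.0)

    def test_treatment_and_failure_indicators_never_decrease(self):
        spec = build_fmt_model()
        for (src, dst) in spec.transitions:
            z0, x0, b0 = fmt_state_decode(src)
            z1, x1, b1 = fmt_state_decode(dst)
            assert b1 >= b0 and z1 >= z0

    def test_marker_flip_sharing_across_treatment_levels(self):
        # the two 0->1 flips (treated/untreated) share baseline and covariate
        # coefficients; they differ exactly by the treatment effect eta11
        spec, params = self._params()
        cov = {"V1": 1.0, "V2": 0.0, "V3": 1.0}
        q = build_generator(spec, params, cov, 1.0)
        untreated = q[fmt_state_code(0, 0, 0), fmt_state_code(0, 1, 0)]
        treated = q[fmt_state_code(0, 0, 1), fmt_state_code(0, 1, 1)]
        assert treated / untreated == pytest.approx(math.exp(TABLE2_EST["eta11"]), rel=1e-12)

    def test_reproduces_every_published_rr_cell(self):
        spec, params = self._params()
        names = spec.parameter_names()
        x = params.to_array(spec)
        cov = np.zeros((len(x), len(x)))
        for name, se in TABLE2_SE.items():
            i = names.index(name)
            cov[i, i] = se**2
        fit = FitResult(
            spec=spec, params=params, loglik=0.0, converged=True, n_iter=0,
            message="", x=x, covariance=cov, parameter_names=names,
        )
        tab = relative_risk_table(fit, coefficients=list(TABLE2_PRINTED))
        for name, (rr, lo, hi) in TABLE2_PRINTED.items():
            assert_printed(tab.loc[name, "rr"], rr)
            assert_printed(tab.loc[name, "lo"], lo)
            assert_printed(tab.loc[name, "hi"], hi)


class TestCombinedEffect:
    def test_published_biologics_under_elevated_marker(self):
        rr = combined_effect_rr({"beta2": 1.081, "beta3": -1.657}, ["beta2", "beta3"])
        assert _round2(rr) == 0.56

    def test_single_name_matches_rr_table(self):
        assert combined_effect_rr({"beta2": 1.081}, ["beta2"]) == pytest.approx(math.exp(1.081))

    def test_empty_combination_is_unity(self):
        assert combined_effect_rr({}, []) == 1.0

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            combined_effect_rr({"a": 1.0}, ["b"])


class TestIllnessDeathEnrolment:
    def test_family_counts(self):
        shared = build_illness_death_enrolment_model(pre_post_shared=True)
        split = build_illness_death_enrolment_model(pre_post_shared=False)
        assert len(shared.baseline_families) == 5  # 3 disease + 2 enrolment
        assert len(split.baseline_families) == 8

    def test_enrolment_indicator_never_decreases(self):
        spec = build_illness_death_enrolment_model()
        enrolled = {3, 4, 5}
        for (k, r) in spec.transitions:
            assert not (k in enrolled and r not in enrolled)

    def test_shared_families_equalize_pre_and_post_intensities(self):
        spec = build_illness_death_enrolment_model(pre_post_shared=True)
        rng = np.random.default_rng(3)
        params = ParameterVector(
            log_baseline={f: rng.normal(-1.5, 0.5, size=1) for f in spec.baseline_families}
        )
        q = build_generator(spec, params, {}, 1.0)
        assert q[0, 1] == q[3, 4]
        assert q[0, 2] == q[3, 5]
        assert q[1, 2] == q[4, 5]


class TestRegistryEnrolment:
    def _records(self):
        return [
            RegistryRecord(id=1, delta=1, time=2.0, covariates={"ill": 1.0}),
            RegistryRecord(id=2, delta=0, time=2.0, covariates={"ill": 0.0}),
            RegistryRecord(id=3, delta=1, time=2.0, covariates={"ill": 0.0}),
        ]

    def test_matches_hand_summed_bernoulli(self):
        coefs = {"intercept": -0.5, "ill": 1.2}
        expit = lambda v: 1 / (1 + math.exp(-v))
        pis = [expit(-0.5 + 1.2), expit(-0.5), expit(-0.5)]
        expected = math.log(pis[0]) + math.log(1 - pis[1]) + math.log(pis[2])
        assert registry_enrolment_loglik(self._records(), coefs) == pytest.approx(expected, abs=1e-12)

    def test_certain_enrolment_limit(self):
        records = [r for r in self._records() if r.delta == 1]
        assert registry_enrolment_loglik(records, {"intercept": 50.0, "ill": 0.0}) == pytest.approx(0.0, abs=1e-10)

    def test_permutation_invariance(self):
        coefs = {"intercept": 0.3, "ill": -0.7}
        recs = self._records()
        assert registry_enrolment_loglik(recs, coefs) == registry_enrolment_loglik(recs[::-1], coefs)

    def test_degenerate_probability_contradiction(self):
        recs = [RegistryRecord(id=1, delta=1, time=1.0, covariates={"ill": 0.0})]
        with pytest.warns(UserWarning, match="degenerate"):
            ll = registry_enrolment_loglik(recs, {"intercept": -math.inf, "ill": 0.0})
        assert ll == -math.inf

    def test_fit_matches_statsmodels_logit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        ill = rng.integers(0, 2, size=500).astype(float)
        lp = -1.0 + 1.0 * ill
        delta = (rng.uniform(size=500) < 1 / (1 + np.exp(-lp))).astype(int)
        records = [
            RegistryRecord(id=i, delta=int(d), time=1.0, covariates={"ill": float(v)})
            for i, (d, v) in enumerate(zip(delta, ill))
        ]
        ours = fit_registry_enrolment(records, ["ill"])
        X = sm.add_constant(pd.DataFrame({"ill": ill}))
        ref = sm.Logit(delta, X).fit(disp=0)
        assert ours["estimates"]["intercept"] == pytest.approx(ref.params["const"], abs=1e-4)
        assert ours["estimates"]["ill"] == pytest.approx(ref.params["ill"], abs=1e-4)
        assert ours["se"]["ill"] == pytest.approx(ref.bse["ill"], rel=1e-3)
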