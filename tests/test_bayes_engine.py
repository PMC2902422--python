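"""Unit and property tests for the Bayesian cause-assignment engine."""

import time

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vacompare.bayes_engine import (
    NO,
    UNKNOWN,
    YES,
    CauseAssignment,
    ConfigurationError,
    PrevalenceSettings,
    UninterpretableCaseError,
    adjust_priors,
    complement_likelihood,
    interpret_cohort,
    posterior_distribution,
    prevalence_for_causes,
    select_causes,
    uniform_prior,
)
from vacompare.synthetic_data import SimulationConfig, simulate_cohort

from conftest import make_case, random_engine_instance


class TestAdjustPriors:
    def test_all_high_multipliers_are_identity(self, prior3):
        settings_ = PrevalenceSettings(
            malaria="high", hiv="high", malaria_causes=("c1",), hiv_causes=("c2",)
        )
        out = adjust_priors(prior3, settings_)
        pd.testing.assert_series_equal(out, prior3)

    def test_hand_renormalization(self, prior3):
        # (0.5, 0.3, 0.2), cause 3 down-weighted x0.1 -> (0.5, 0.3, 0.02)/0.82
        settings_ = PrevalenceSettings(
            malaria="low", hiv="high", malaria_causes=("c3",), hiv_causes=()
        )
        out = adjust_priors(prior3, settings_)
        expected = np.array([0.5, 0.3, 0.02]) / 0.82
        np.testing.assert_allclose(out.to_numpy(), expected, atol=5e-5)
        np.testing.assert_allclose(out.to_numpy(), [0.6098, 0.3659, 0.0244], atol=5e-5)

    def test_study_configuration_downweights_malaria_only(self):
        prior = pd.Series({"hiv_aids": 0.3, "malaria": 0.2, "injuries": 0.5})
        settings_ = prevalence_for_causes(prior.index, malaria="low", hiv="high")
        out = adjust_priors(prior, settings_)
        # malaria relative weight falls tenfold; HIV untouched relative to others
        assert out["malaria"] / out["injuries"] == pytest.approx(0.1 * (0.2 / 0.5))
        assert out["hiv_aids"] / out["injuries"] == pytest.approx(0.3 / 0.5)
        assert out.sum() == pytest.approx(1.0)

    def test_unknown_affected_cause_is_named(self, prior3):
        settings_ = PrevalenceSettings(malaria_causes=("nonexistent",), hiv_causes=())
        with pytest.raises(ConfigurationError, match="nonexistent"):
            adjust_priors(prior3, settings_)


class TestComplementLikelihood:
    def test_two_cause_reduction(self):
        base = pd.DataFrame({"c1": [0.7], "c2": [0.25]}, index=["i1"])
        prior = pd.Series({"c1": 0.6, "c2": 0.4})
        assert complement_likelihood(base, prior, "i1", "c1") == pytest.approx(0.25)
        assert complement_likelihood(base, prior, "i1", "c2") == pytest.approx(0.7)

    def test_three_cause_direct_sum(self, base3, prior3):
        # (0.1*0.3 + 0.1*0.2) / (1 - 0.5) = 0.1
        assert complement_likelihood(base3, prior3, "i1", "c1") == pytest.approx(0.1)

    def test_constant_row_symmetry(self, base3, prior3):
        for cause in base3.columns:
            assert complement_likelihood(base3, prior3, "i2", cause) == pytest.approx(0.2)

    def test_degenerate_prior_rejected(self, base3):
        prior = pd.Series({"c1": 1.0, "c2": 1e-300, "c3": 1e-300})
        with pytest.raises(ConfigurationError):
            complement_likelihood(base3, prior, "i1", "c1")


class TestPosterior:
    def test_no_yes_responses_returns_prior(self, base3, prior3):
        case = make_case({"i1": NO, "i2": UNKNOWN, "i3": NO})
        out = posterior_distribution(case, base3, prior3)
        np.testing.assert_allclose(out.to_numpy(), prior3.to_numpy(), atol=1e-12)

    def test_uninformative_indicator_returns_prior(self, base3, prior3):
        case = make_case({"i1": NO, "i2": YES, "i3": UNKNOWN})
        out = posterior_distribution(case, base3, prior3)
        np.testing.assert_allclose(out.to_numpy(), prior3.to_numpy(), atol=1e-12)

    def test_worked_example(self, base3, prior3):
        # prior (0.5,0.3,0.2) x row (0.9,0.1,0.1) -> (0.45,0.03,0.02)/0.5
        case = make_case({"i1": YES, "i2": NO, "i3": NO})
        out = posterior_distribution(case, base3, prior3)
        np.testing.assert_allclose(out.to_numpy(), [0.9, 0.06, 0.04], atol=1e-12)

    def test_zero_probability_everywhere_flags_case(self, prior3):
        # i1 occurs only under c1; i2 only under c2/c3 — observing both
        # "yes" has probability zero under every cause.
        base = pd.DataFrame(
            {"c1": [0.9, 0.0], "c2": [0.0, 0.9], "c3": [0.0, 0.9]},
            index=["i1", "i2"],
        )
        case = make_case({"i1": YES, "i2": YES})
        with pytest.raises(UninterpretableCaseError):
            posterior_distribution(case, base, prior3)

    def test_update_order_invariance(self, base3, prior3):
        fwd = make_case({"i1": YES, "i2": YES, "i3": NO})
        rev = make_case({"i3": NO, "i2": YES, "i1": YES})
        a = posterior_distribution(fwd, base3, prior3)
        b = posterior_distribution(rev, base3, prior3)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_posterior_normalization_and_binary_formula(self, seed):
        """Single-indicator multi-cause update equals the two-hypothesis
        Bayes form through the complement likelihood, for every cause."""
        rng = np.random.default_rng(seed)
        base, prior, _ = random_engine_instance(rng)
        ind = base.index[int(rng.integers(len(base.index)))]
        responses = {j: (YES if j == ind else UNKNOWN) for j in base.index}
        post = posterior_distribution(make_case(responses), base, prior)
        assert post.sum() == pytest.approx(1.0, abs=1e-9)
        for cause in base.columns:
            p_i_c = float(base.loc[ind, cause])
            p_c = float(prior[cause])
            p_i_not_c = complement_likelihood(base, prior, ind, cause)
            two_hyp = p_i_c * p_c / (p_i_c * p_c + p_i_not_c * (1.0 - p_c))
            assert post[cause] == pytest.approx(two_hyp, abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_monotonicity_in_base_entry(self, seed):
        """Raising P(indicator|cause) for an observed yes indicator never
        decreases that cause's posterior."""
        rng = np.random.default_rng(seed)
        base, prior, case = random_engine_instance(rng)
        yes = case.yes_indicators()
        if not yes:
            return
        ind = yes[0]
        cause = base.columns[int(rng.integers(len(base.columns)))]
        before = posterior_distribution(case, base, prior)[cause]
        bumped = base.copy()
        bumped.loc[ind, cause] = min(1.0, float(bumped.loc[ind, cause]) * 1.5 + 0.01)
        after = posterior_distribution(case, bumped, prior)[cause]
        assert after >= before - 1e-12


class TestSelectCauses:
    def test_degenerate_posterior_single_cause(self):
        post = pd.Series({"a": 1.0, "b": 0.0, "c": 0.0})
        out = select_causes(post, case_id="x")
        assert out.causes == (("a", 100.0),)
        assert not out.indeterminate

    def test_relative_threshold_arithmetic(self):
        post = pd.Series({"a": 0.55, "b": 0.30, "c": 0.15})
        out = select_causes(post)
        assert [c for c, _ in out.causes] == ["a", "b"]  # 0.30 >= 0.275 > 0.15
        assert out.causes[0][1] == pytest.approx(55.0)
        assert out.causes[1][1] == pytest.approx(30.0)

    def test_below_top_threshold_is_indeterminate(self):
        post = pd.Series({"a": 0.35, "b": 0.33, "c": 0.32})
        assert select_causes(post).indeterminate

    def test_ties_broken_by_cause_order(self):
        post = pd.Series({"b": 0.4, "a": 0.4, "c": 0.2})
        out = select_causes(post)
        assert [c for c, _ in out.causes] == ["b", "a", "c"]

    def test_at_most_three_causes(self):
        post = pd.Series({c: 0.25 for c in "abcd"})
        out = select_causes(post, tau_top=0.2, tau_rel=0.1)
        assert len(out.causes) == 3


class TestInterpretCohort:
    def test_empty_cohort(self, base3, prior3):
        assert interpret_cohort([], base3, prior3) == []

    def test_determinism_on_duplicated_case(self, base3, prior3):
        case = make_case({"i1": YES, "i2": NO, "i3": UNKNOWN})
        out = interpret_cohort([case] * 10, base3, prior3)
        assert len(out) == 10
        assert all(a.causes == out[0].causes for a in out)

    def test_uninterpretable_case_becomes_indeterminate_not_abort(self, prior3):
        base = pd.DataFrame(
            {"c1": [0.9, 0.0], "c2": [0.0, 0.9], "c3": [0.0, 0.0]},
            index=["i1", "i2"],
        )
        base.loc["i2", "c3"] = 0.9
        bad = make_case({"i1": YES, "i2": YES}, case_id="bad")
        ok = make_case({"i1": YES, "i2": NO}, case_id="ok")
        out = interpret_cohort([bad, ok], base, prior3)
        assert out[0].indeterminate and out[0].case_id == "bad"
        assert not out[1].indeterminate

    def test_study_scale_cohort_interprets_quickly(self):
        cfg = SimulationConfig(n_cases=1823, seed=7)
        cases, _, base = simulate_cohort(cfg)
        prior = cfg.overall_csmf()
        start = time.perf_counter()
        out = interpret_cohort(cases, base, prior)
        elapsed = time.perf_counter() - start
        assert len(out) == 1823
        assert elapsed < 60.0

    def test_assignment_invariants(self):
        with pytest.raises(ConfigurationError):
            CauseAssignment(case_id="x", causes=(("a", 10.0), ("b", 20.0)))
        with pytest.raises(ConfigurationError):
            CauseAssignment(
                case_id="x",
                causes=(("a", 40.0), ("b", 30.0), ("c", 20.0), ("d", 10.0)),
            )

    def test_uniform_prior_and_oracle_consistency(self, base3):
        prior = uniform_prior(base3.columns)
        case = make_case({"i1": YES, "i2": UNKNOWN, "i3": UNKNOWN})
        post = posterior_distribution(case, base3, prior)
        # uniform prior: posterior proportional to the likelihood row
        row = base3.loc["i1"]
        np.testing.assert_allclose(post.to_numpy(), (row / row.sum()).to_numpy(), atol=1e-12)
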