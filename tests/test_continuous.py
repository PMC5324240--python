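"""Moment-ODE propagation, likelihood structure and continuous-time fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quadhaz import (CoefficientFunction, ContinuousParams, MomentState,
                     SimulationPlan, fit_continuous, fit_time_dependent,
                     marginal_hazard, propagate_moments, simulate_cohort,
                     subject_log_likelihood, total_log_likelihood)
from quadhaz.errors import EstimationError, UnsupportedConfigurationError

from conftest import make_records


def _p1(a=-0.05, f1=80.0, b=5.0, mu0=1e-5, f=80.0, Q=1e-6, theta=0.0, slopes=None):
    return ContinuousParams(a=[[a]], f1=[f1], b=[b], mu0=mu0, f=[f],
                            Q=[[Q]], theta=theta, slopes=slopes or {})


class TestMarginalHazard:
    def test_minimum_risk_state(self):
        p = _p1()
        st0 = MomentState([80.0], [[0.0]])
        assert marginal_hazard(p, st0, 0.0) == pytest.approx(1e-5)

    def test_substitution(self):
        p = _p1()
        st0 = MomentState([90.0], [[25.0]])
        assert marginal_hazard(p, st0, 0.0) == pytest.approx(1.35e-4, rel=1e-12)

    def test_null_sensitivity(self):
        p = _p1(Q=0.0)
        st0 = MomentState([123.0], [[999.0]])
        assert marginal_hazard(p, st0, 5.0) == pytest.approx(1e-5)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            marginal_hazard(_p1(), MomentState([1.0, 2.0], np.eye(2)), 0.0)


class TestPropagation:
    @pytest.mark.parametrize("a", [-0.02, -0.05, -0.2])
    @pytest.mark.parametrize("b", [1.0, 5.0])
    @pytest.mark.parametrize("f1", [60.0, 80.0])
    def test_closed_forms_q_zero(self, a, b, f1):
        """Q=0: m(t) = f1 + (m0-f1)e^{at}; gamma(t) = -b^2/(2a)(1-e^{2at})."""
        p = _p1(a=a, f1=f1, b=b, Q=0.0)
        span = 10.0
        out = propagate_moments(p, MomentState([90.0], [[0.0]]), 0.0, span)
        m_exact = f1 + (90.0 - f1) * np.exp(a * span)
        g_exact = -b ** 2 / (2 * a) * (1 - np.exp(2 * a * span))
        assert out.m[0] == pytest.approx(m_exact, rel=1e-6)
        assert out.gamma[0, 0] == pytest.approx(g_exact, rel=1e-6)

    def test_equilibrium_state_constant(self):
        p = _p1(b=0.0, Q=0.0)
        out = propagate_moments(p, MomentState([80.0], [[0.0]]), 0.0, 25.0)
        assert out.m[0] == pytest.approx(80.0, abs=1e-12)
        assert out.gamma[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_hazard_integral(self):
        p = _p1(Q=0.0, mu0=3e-4)
        out = propagate_moments(p, MomentState([80.0], [[4.0]]), 10.0, 17.0)
        assert out.H == pytest.approx(3e-4 * 7.0, abs=1e-10)

    def test_invalid_span(self):
        with pytest.raises(ValueError):
            propagate_moments(_p1(), MomentState([80.0], [[0.0]]), 5.0, 5.0)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 5000), k=st.sampled_from([1, 2]))
def test_gamma_stays_symmetric_psd(seed, k):
    """gamma remains symmetric PSD along integrations from PSD starts."""
    rng = np.random.default_rng(seed)
    A = rng.normal(0, 1, (k, k))
    p = ContinuousParams(
        a=-np.eye(k) * rng.uniform(0.02, 0.3) + rng.normal(0, 0.01, (k, k)),
        f1=rng.normal(80, 10, k), b=np.abs(rng.normal(3, 1, k)) + 0.1,
        mu0=1e-4, f=rng.normal(80, 10, k),
        Q=A @ A.T * 1e-6 + 1e-8 * np.eye(k), theta=rng.uniform(0, 0.1))
    G = rng.normal(0, 2, (k, k))
    state = MomentState(rng.normal(80, 10, k), G @ G.T)
    t = 30.0
    for span in (0.3, 1.0, 2.7):
        state = propagate_moments(p, state, t, t + span)
        t += span
        asym = np.max(np.abs(state.gamma - state.gamma.T))
        assert asym <= 1e-9
        assert np.linalg.eigvalsh(state.gamma).min() >= -1e-8
    assert state.H >= 0.0


class TestSubjectLikelihood:
    def test_gompertz_closed_form(self):
        """Single censored observation, Q=0: the integral is Gompertz."""
        p = _p1(Q=0.0, mu0=1e-5, theta=0.1)
        rec = make_records({1: ([30.0], 75.0, 0, [81.0])})
        law = (np.array([80.0]), np.array([[4.0]]))
        ll = subject_log_likelihood(p, rec, initial_law=law)
        dens = -0.5 * (np.log(2 * np.pi * 4.0) + (81.0 - 80.0) ** 2 / 4.0)
        integral = 1e-5 / 0.1 * (np.exp(0.1 * 75) - np.exp(0.1 * 30))
        assert ll == pytest.approx(dens - integral, abs=1e-8)

    def test_event_term_is_log_marginal_hazard(self):
        p = _p1(mu0=1e-3, Q=1e-5)
        times, tau, vals = [30.0, 31.0, 32.0], 33.5, [80.0, 82.0, 79.0]
        rec_c = make_records({1: (times, tau, 0, vals)})
        rec_d = make_records({1: (times, tau, 1, vals)})
        ll_c = subject_log_likelihood(p, rec_c)
        ll_d = subject_log_likelihood(p, rec_d)
        st_end = propagate_moments(p, MomentState([79.0], [[0.0]]), 32.0, 33.5)
        assert ll_d - ll_c == pytest.approx(
            np.log(marginal_hazard(p, st_end, 33.5)), abs=1e-10)

    def test_matches_manual_composition(self):
        """Likelihood equals the hand-assembled density/survival terms."""
        p = _p1(mu0=1e-3, Q=1e-5, b=3.0)
        times, tau, vals = [30.0, 32.0], 34.0, [80.0, 86.0]
        rec = make_records({1: (times, tau, 1, vals)})
        ll = subject_log_likelihood(p, rec)
        st1 = propagate_moments(p, MomentState([80.0], [[0.0]]), 30.0, 32.0)
        dens = -0.5 * (np.log(2 * np.pi * st1.gamma[0, 0])
                       + (86.0 - st1.m[0]) ** 2 / st1.gamma[0, 0])
        st2 = propagate_moments(p, MomentState([86.0], [[0.0]]), 32.0, 34.0)
        expect = (dens + np.log(marginal_hazard(p, st2, 34.0))
                  - st1.H - st2.H)
        assert ll == pytest.approx(expect, rel=1e-12)

    def test_zero_mahalanobis_observation(self):
        """Observing exactly the propagated mean leaves only the log-det term."""
        p = _p1(mu0=0.0, Q=0.0, b=2.0)
        st1 = propagate_moments(p, MomentState([85.0], [[0.0]]), 30.0, 31.0)
        rec = make_records({1: ([30.0, 31.0], 31.5, 0, [85.0, float(st1.m[0])])})
        ll = subject_log_likelihood(p, rec)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi * st1.gamma[0, 0]),
                                   abs=1e-10)


@pytest.fixture(scope="module")
def cohort(table4_truth):
    plan = SimulationPlan(n_subjects=100, t_start=30, seed=17, mode="jittered")
    return simulate_cohort(table4_truth, plan)


class TestTotalLikelihood:
    def test_fast_path_matches_per_subject_reference(self, cohort, table4_truth):
        """Vectorized row likelihood == sum of per-subject ODE evaluations."""
        total = total_log_likelihood(table4_truth, cohort)
        by_subject = 0.0
        for _, g in cohort.frame.groupby("id", sort=False):
            by_subject += subject_log_likelihood(
                table4_truth,
                type(cohort)(frame=g, covariate_names=cohort.covariate_names))
        assert total == pytest.approx(by_subject, rel=1e-10)

    def test_permutation_invariance(self, cohort, table4_truth):
        df = cohort.frame
        rng = np.random.default_rng(1)
        ids = df["id"].unique()
        order = {sid: i for i, sid in enumerate(rng.permutation(ids))}
        shuffled = df.sort_values(by="id", key=lambda s: s.map(order),
                                  kind="mergesort")
        shuffled = type(cohort)(frame=shuffled,
                                covariate_names=cohort.covariate_names)
        assert total_log_likelihood(table4_truth, shuffled) == pytest.approx(
            total_log_likelihood(table4_truth, cohort), rel=1e-12)

    def test_substep_halving_stability(self, cohort, table4_truth):
        l1 = total_log_likelihood(table4_truth, cohort, h_max=0.05)
        l2 = total_log_likelihood(table4_truth, cohort, h_max=0.025)
        assert abs(l1 - l2) <= 1e-6

    def test_likelihood_dominance_at_truth(self, table4_truth):
        plan = SimulationPlan(n_subjects=2000, t_start=30, seed=23)
        cohort = simulate_cohort(table4_truth, plan)
        worse = ContinuousParams.from_dict(table4_truth.to_dict())
        worse.Q = worse.Q * 1.5
        assert total_log_likelihood(table4_truth, cohort) > \
            total_log_likelihood(worse, cohort)


class TestFits:
    def test_self_consistency_small(self):
        """Parameters re-estimated from their own simulation stay close."""
        truth = _p1(a=-0.1, f1=80.0, b=2.0, mu0=0.05, f=80.0, Q=1e-4)
        plan = SimulationPlan(n_subjects=500, t_start=30, seed=31,
                              mode="jittered")
        rec = simulate_cohort(truth, plan)
        fit = fit_continuous(rec, start=truth, on_fail="warn")
        p = fit.params
        assert p.a[0, 0] == pytest.approx(-0.1, abs=0.05)
        assert p.f1[0] == pytest.approx(80.0, abs=2.0)
        assert p.b[0] == pytest.approx(2.0, rel=0.1)
        assert p.mu0 == pytest.approx(0.05, rel=0.5)
        assert np.isfinite(fit.loglik)

    def test_time_dependent_with_no_slopes_matches_constant_fit(self):
        truth = _p1(a=-0.1, f1=80.0, b=2.0, mu0=0.05, f=80.0, Q=1e-4)
        rec = simulate_cohort(truth, SimulationPlan(n_subjects=200, t_start=30,
                                                    t_max=60, seed=37))
        f_const = fit_continuous(rec, start=truth, on_fail="warn")
        f_td = fit_time_dependent(rec, {}, start=truth, on_fail="warn")
        assert f_td.loglik == pytest.approx(f_const.loglik, abs=1e-4)
        assert f_td.params.a[0, 0] == pytest.approx(f_const.params.a[0, 0],
                                                    abs=1e-6)

    def test_no_events_unidentifiable(self):
        rec = make_records({1: ([30.0, 31.0, 32.0], 33.0, 0, [80.0, 81.0, 79.0]),
                            2: ([30.0, 31.0, 32.0], 33.0, 0, [78.0, 80.0, 81.0])})
        with pytest.raises(EstimationError, match="events"):
            fit_continuous(rec)

    def test_multidimensional_time_dependence_rejected(self, twod_truth):
        from quadhaz import continuous_to_discrete
        rec = simulate_cohort(continuous_to_discrete(twod_truth),
                              SimulationPlan(n_subjects=50, t_max=45, seed=41))
        with pytest.raises(UnsupportedConfigurationError):
            fit_time_dependent(rec, {"f1": CoefficientFunction()})

    def test_unknown_coefficient_rejected(self):
        rec = make_records({1: ([30.0, 31.0], 33.0, 1, [80.0, 81.0]),
                            2: ([30.0, 31.0], 33.0, 0, [78.0, 80.0])})
        with pytest.raises(UnsupportedConfigurationError, match="sigma"):
            fit_time_dependent(rec, {"sigma": CoefficientFunction()})
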