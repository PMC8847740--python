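"""Structural-model closed forms, decomposition ODEs and derived quantities."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

import cartpk as ck
from cartpk.kinetics import ComedicationSchedule, auc_trapezoid


def valid_params():
    """Hypothesis strategy for admissible structural parameters."""
    return st.builds(
        lambda c, t, fx, fb, a, r: ck.IndividualParams(
            c_max=c, t_max=t, foldx=fx, fb=fb, alpha=a, beta=a * r
        ),
        st.floats(1e2, 1e6),
        st.floats(3.0, 20.0),
        st.floats(10.0, 1e4),
        st.floats(0.01, 0.9),
        st.floats(0.02, 0.5),
        st.floats(0.01, 0.9),
    )


class TestExpansionRate:
    @pytest.mark.parametrize(
        "foldx,tmax,expected",
        [
            (math.e, 1.0, 1.0),
            (1.0, 10.0, 0.0),
            (5460.0, 8.657, math.log(5460.0) / 8.657),
        ],
    )
    def test_examples(self, foldx, tmax, expected):
        assert ck.expansion_rate(foldx, tmax) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ck.expansion_rate(-1.0, 5.0)
        with pytest.raises(ValueError):
            ck.expansion_rate(10.0, 0.0)


class TestConcentration:
    def test_baseline_and_peak(self, ref_params):
        p = ref_params
        assert ck.concentration(0.0, p) == pytest.approx(p.c_max / p.foldx, rel=1e-12)
        assert ck.concentration(p.t_max, p) == pytest.approx(p.c_max, rel=1e-12)

    def test_contraction_value_matches_scalar_formula(self, ref_params):
        # independent scalar evaluation of the biexponential branch
        p = ref_params
        tau = 30.0 - p.t_max
        expected = p.c_max * (
            (1 - p.fb) * math.exp(-p.alpha * tau) + p.fb * math.exp(-p.beta * tau)
        )
        assert ck.concentration(30.0, p) == pytest.approx(expected, rel=1e-12)

    def test_expansion_value_matches_scalar_formula(self, ref_params):
        p = ref_params
        rho = math.log(p.foldx) / p.t_max
        expected = p.c_max / p.foldx * math.exp(rho * 5.0)
        assert ck.concentration(5.0, p) == pytest.approx(expected, rel=1e-12)

    def test_negative_time_rejected(self, ref_params):
        with pytest.raises(ValueError):
            ck.concentration(-1.0, ref_params)

    @given(valid_params())
    def test_continuity_at_peak(self, p):
        eps = 1e-9 * p.t_max
        left = ck.concentration(p.t_max - eps, p)
        right = ck.concentration(p.t_max, p)
        assert left == pytest.approx(right, rel=1e-6)
        assert right == pytest.approx(p.c_max, rel=1e-12)

    @given(valid_params())
    def test_monotone_up_then_down(self, p):
        up = np.linspace(0, p.t_max * (1 - 1e-9), 25)
        down = np.linspace(p.t_max, p.t_max + 300, 25)
        cu = ck.concentration(up, p)
        cd = ck.concentration(down, p)
        assert np.all(np.diff(cu) > 0)
        assert np.all(np.diff(cd) < 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ck.IndividualParams(1e4, 9.0, 0.5, 0.1, 0.1, 0.01)  # foldx <= 1
        with pytest.raises(ValueError):
            ck.IndividualParams(1e4, 9.0, 100.0, 1.2, 0.1, 0.01)  # fb > 1
        with pytest.raises(ValueError):
            ck.IndividualParams(1e4, 9.0, 100.0, 0.1, 0.01, 0.1)  # beta >= alpha


class TestCovariateVariant:
    def test_off_equals_base(self, ref_params):
        t = np.array([0.0, 5.0, 30.0, 100.0])
        assert np.allclose(
            ck.concentration_with_covariate(t, ref_params, False, 0.468),
            ck.concentration(t, ref_params),
        )

    def test_identity_multiplier(self, ref_params):
        assert ck.concentration_with_covariate(
            12.0, ref_params, True, 1.0
        ) == pytest.approx(ck.concentration(12.0, ref_params))

    def test_peak_scaled_by_multiplier(self, ref_params):
        p = ref_params
        out = ck.concentration_with_covariate(p.t_max, p, True, 0.468)
        assert out == pytest.approx(0.468 * p.c_max, rel=1e-12)

    def test_nonpositive_multiplier_rejected(self, ref_params):
        with pytest.raises(ValueError):
            ck.concentration_with_covariate(1.0, ref_params, True, 0.0)


class TestComedicationVariant:
    def test_neutral_multipliers_match_base(self, ref_params):
        sched = ComedicationSchedule(t_toci=3.0, t_ster=5.0, f1=1.0, f2=1.0)
        t = np.linspace(0, 60, 121)
        a = ck.concentration_with_comedication(t, ref_params, sched)
        b = ck.concentration(t, ref_params)
        assert np.array_equal(a, b)

    def test_before_first_dose_unaffected(self, ref_params):
        sched = ComedicationSchedule(t_toci=3.0, t_ster=5.0, f1=0.5, f2=0.7)
        p = ref_params
        rho = math.log(p.foldx) / p.t_max
        for t in (0.0, 1.0, 2.9):
            assert ck.concentration_with_comedication(
                t, p, sched
            ) == pytest.approx(p.c_max / p.foldx * math.exp(rho * t), rel=1e-12)

    def test_piecewise_value_matches_independent_evaluation(self, ref_params):
        # independent evaluation of the three-segment expansion formula
        p = ref_params
        f1, f2, t_toci, t_ster, t = 0.966, 0.944, 3.0, 5.0, 7.0
        rho = math.log(p.foldx) / p.t_max
        expected = (
            p.c_max
            / p.foldx
            * math.exp(rho * t_toci)
            * math.exp(f1 * rho * (t_ster - t_toci))
            * math.exp(f1 * f2 * rho * (t - t_ster))
        )
        sched = ComedicationSchedule(t_toci=t_toci, t_ster=t_ster, f1=f1, f2=f2)
        assert ck.concentration_with_comedication(t, p, sched) == pytest.approx(
            expected, rel=1e-12
        )

    def test_steroid_first_applies_chronologically(self, ref_params):
        p = ref_params
        rho = math.log(p.foldx) / p.t_max
        sched = ComedicationSchedule(t_toci=6.0, t_ster=2.0, f1=0.9, f2=0.8)
        t = 4.0  # after steroid, before tocilizumab: rate f2*rho
        expected = p.c_max / p.foldx * math.exp(rho * 2.0 + 0.8 * rho * 2.0)
        assert ck.concentration_with_comedication(t, p, sched) == pytest.approx(
            expected, rel=1e-12
        )

    def test_published_form_jumps_but_continuous_mode_does_not(self, ref_params):
        p = ref_params
        sched = ComedicationSchedule(t_toci=2.0, t_ster=4.0, f1=0.8, f2=0.8)
        eps = 1e-7
        left = ck.concentration_with_comedication(p.t_max - eps, p, sched)
        right = ck.concentration_with_comedication(p.t_max, p, sched)
        assert right == pytest.approx(p.c_max)  # anchored at the typical peak
        assert left < right * 0.99  # the printed form leaves a jump
        left_c = ck.concentration_with_comedication(
            p.t_max - eps, p, sched, mode="continuous"
        )
        right_c = ck.concentration_with_comedication(
            p.t_max, p, sched, mode="continuous"
        )
        assert left_c == pytest.approx(right_c, rel=1e-5)

    def test_late_schedule_warns_or_raises(self, ref_params):
        sched = ComedicationSchedule(t_toci=20.0, f1=0.9)
        with pytest.warns(UserWarning):
            ck.concentration_with_comedication(5.0, ref_params, sched)
        with pytest.raises(ValueError):
            ck.concentration_with_comedication(
                5.0, ref_params, sched, on_late_schedule="error"
            )


class TestEffectorMemory:
    def test_memory_zero_through_peak(self, ref_params):
        grid = np.linspace(0, ref_params.t_max, 40)
        traj = ck.effector_memory_decompose(ref_params, grid)
        assert np.all(traj.y_beta == 0)

    def test_effector_reaches_peak(self, ref_params):
        traj = ck.effector_memory_decompose(ref_params, np.array([ref_params.t_max]))
        assert traj.y_alpha[0] == pytest.approx(ref_params.c_max, rel=1e-6)

    def test_sum_matches_closed_form_over_one_year(self, ref_params):
        grid = np.linspace(0, 365, 400)
        traj = ck.effector_memory_decompose(ref_params, grid)
        closed = ck.concentration(grid, ref_params)
        assert np.max(np.abs(traj.total - closed)) < 1e-6 * ref_params.c_max

    def test_analytic_solution_agrees_with_integration(self, ref_params):
        grid = np.linspace(0, 365, 200)
        ode = ck.effector_memory_decompose(ref_params, grid)
        ana = ck.effector_memory_closed_form(ref_params, grid)
        assert np.allclose(ode.y_alpha, ana.y_alpha, rtol=1e-6, atol=1e-6 * ref_params.c_max)
        assert np.allclose(ode.y_beta, ana.y_beta, rtol=1e-6, atol=1e-6 * ref_params.c_max)

    def test_unsorted_grid_rejected(self, ref_params):
        with pytest.raises(ValueError):
            ck.effector_memory_decompose(ref_params, np.array([3.0, 1.0]))


class TestAuc:
    def test_closed_form_matches_quadrature(self, ref_params):
        q, _ = integrate.quad(
            lambda t: ck.concentration(t, ref_params), 0, 28, limit=200
        )
        assert ck.auc(ref_params, 0, 28) == pytest.approx(q, rel=1e-6)

    @given(valid_params())
    def test_closed_form_matches_quadrature_random_params(self, p):
        q, _ = integrate.quad(lambda t: ck.concentration(t, p), 0, 28, limit=300)
        assert ck.auc(p, 0, 28) == pytest.approx(q, rel=1e-6)

    def test_contraction_only_window(self, ref_params):
        q, _ = integrate.quad(
            lambda t: ck.concentration(t, ref_params), 30, 120, limit=200
        )
        assert ck.auc(ref_params, 30, 120) == pytest.approx(q, rel=1e-8)

    def test_trapezoid_constant_series(self):
        t = np.linspace(0, 28, 15)
        assert auc_trapezoid(t, np.full_like(t, 5.0), 0, 28) == pytest.approx(140.0)

    def test_trapezoid_requires_coverage(self):
        with pytest.raises(ValueError):
            auc_trapezoid([0, 10], [1, 1], 0, 28)

    def test_invalid_window_rejected(self, ref_params):
        with pytest.raises(ValueError):
            ck.auc(ref_params, 28, 28)


class TestDerivedConstants:
    def test_half_life_of_ln2_rate_is_one_day(self, ref_params):
        import dataclasses

        p = dataclasses.replace(ref_params, alpha=math.log(2.0))
        assert ck.derived_constants(p)["half_life_alpha"] == pytest.approx(1.0)

    def test_terminal_half_life_value(self, ref_params):
        out = ck.derived_constants(ref_params)
        assert out["half_life_beta"] == pytest.approx(math.log(2) / 0.006122, rel=1e-12)

    def test_doubling_time_of_fourfold_in_two_days(self):
        p = ck.IndividualParams(1e4, 2.0, 4.0, 0.1, 0.2, 0.01)
        assert ck.derived_constants(p)["doubling_time"] == pytest.approx(1.0)
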