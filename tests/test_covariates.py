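"""Covariate thresholds, effect application and descriptive screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cartpk as ck
from cartpk.covariates import ScmTrace, chi2_threshold, scm, subject_auc28
from cartpk.model import CovariateTerm


class TestChi2Threshold:
    @pytest.mark.parametrize(
        "p,df,expected",
        [(0.05, 1, 3.84), (0.01, 1, 6.63), (0.5, 1, 0.4549)],
    )
    def test_quantiles(self, p, df, expected):
        assert chi2_threshold(p, df) == pytest.approx(expected, abs=5e-3)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            chi2_threshold(0.0, 1)
        with pytest.raises(ValueError):
            chi2_threshold(0.05, 0)

    @given(
        st.floats(0.001, 0.5),
        st.floats(0.001, 0.5),
        st.integers(1, 10),
    )
    def test_monotone_in_significance_and_df(self, p1, p2, df):
        lo, hi = sorted((p1, p2))
        if lo != hi:
            assert chi2_threshold(lo, df) > chi2_threshold(hi, df)
        assert chi2_threshold(lo, df + 1) > chi2_threshold(lo, df)


class TestApplyCovariate:
    def test_neutral_multiplier_leaves_predictions_unchanged(self, ref_pop):
        term = CovariateTerm("c_max", "EMM", "categorical", 1.0)
        ext = ck.apply_covariate(ref_pop, term)
        subjects = pd.DataFrame({"ID": [1, 2], "EMM": [0, 1]})
        mult = ext.covariate_multipliers(subjects)
        base = ref_pop.covariate_multipliers(subjects)
        # original EMM term (0.468) is still there; the added neutral term is a no-op
        assert np.allclose(mult, base)

    def test_flagged_subjects_scaled(self):
        pop = ck.PopulationModel(theta=ck.reference_population_model().theta)
        ext = ck.apply_covariate(pop, CovariateTerm("c_max", "EMM", "categorical", 0.468))
        subjects = pd.DataFrame({"ID": [1, 2], "EMM": [1, 0]})
        mult = ext.covariate_multipliers(subjects)
        assert mult[0, 0] == pytest.approx(0.468)
        assert mult[1, 0] == pytest.approx(1.0)

    def test_power_form_neutral_at_reference(self):
        pop = ck.PopulationModel(theta=ck.reference_population_model().theta)
        ext = ck.apply_covariate(pop, CovariateTerm("c_max", "WT", "power", 0.75))
        subjects = pd.DataFrame({"ID": [1, 2, 3], "WT": [50.0, 62.0, 80.0]})
        mult = ext.covariate_multipliers(subjects)
        assert mult[1, 0] == pytest.approx(1.0)  # at the cohort median
        assert mult[0, 0] < 1.0 < mult[2, 0]

    def test_zero_exponent_is_neutral(self):
        pop = ck.PopulationModel(theta=ck.reference_population_model().theta)
        ext = ck.apply_covariate(pop, CovariateTerm("c_max", "WT", "power", 0.0))
        subjects = pd.DataFrame({"ID": [1, 2], "WT": [40.0, 90.0]})
        assert np.allclose(ext.covariate_multipliers(subjects), 1.0)

    def test_unknown_covariate_is_schema_error(self, ref_pop):
        with pytest.raises(KeyError):
            ref_pop.with_covariate(
                CovariateTerm("c_max", "NOPE", "categorical", 0.5)
            ).covariate_multipliers(pd.DataFrame({"ID": [1]}))


def _fake_fit(ebe: pd.DataFrame, data) -> ck.FitResult:
    return ck.FitResult(
        pop=ck.reference_population_model(emm_effect=False),
        ofv=0.0,
        ebe=ebe,
        shrinkage={},
        rse=None,
        se=None,
        convergence={},
        spec=ck.ModelSpec(),
        data=data,
    )


class TestEbeScreen:
    def _dataset(self, n, emm):
        subjects = pd.DataFrame(
            {
                "ID": np.arange(1, n + 1),
                "EMM": emm,
                "AGE": 50.0,
                "SEX": 0,
                "WT": 60.0,
                "DOSE": 1.0,
                "PRIOR_CART": 0,
                "PRIOR_HSCT": 0,
                "CRS_GRADE": 1,
                "TTOCI": np.nan,
                "TSTER": np.nan,
                "RESPONSE": 1,
            }
        )
        obs = pd.DataFrame(
            {"ID": np.arange(1, n + 1), "TIME": 1.0, "DV": 100.0, "BLQ": 0, "LOQ": 20.0}
        )
        return ck.KineticDataset(obs=obs, subjects=subjects)

    def test_identical_groups_p_one(self):
        n = 10
        data = self._dataset(n, [0] * 5 + [1] * 5)
        ebe = pd.DataFrame({"ID": np.arange(1, n + 1)})
        for k in ck.PARAM_NAMES:
            ebe[f"eta_{k}"] = 0.0
        out = ck.ebe_covariate_screen(_fake_fit(ebe, data), "EMM")
        assert (out["p_value"] == 1.0).all()

    def test_separated_groups_tiny_p(self):
        n = 20
        emm = [0] * 10 + [1] * 10
        data = self._dataset(n, emm)
        rng = np.random.default_rng(0)
        ebe = pd.DataFrame({"ID": np.arange(1, n + 1)})
        for k in ck.PARAM_NAMES:
            ebe[f"eta_{k}"] = rng.normal(0, 0.1, n)
        ebe.loc[np.array(emm) == 1, "eta_c_max"] += 10.0
        out = ck.ebe_covariate_screen(_fake_fit(ebe, data), "EMM")
        p_cmax = out.loc[out.parameter == "c_max", "p_value"].iloc[0]
        assert p_cmax < 1e-3

    def test_simulated_emm_effect_flags_cmax_eta(self, ref_pop):
        # fit-free screen: EBEs under the no-covariate model show the imprint
        ds = ck.generate_cohort(ck.CohortConfig(n_subjects=80, seed=3), ref_pop)
        base_pop = ck.reference_population_model(emm_effect=False)
        ebe = ck.empirical_bayes(ds, base_pop)
        out = ck.ebe_covariate_screen(_fake_fit(ebe, ds), "EMM")
        p_cmax = out.loc[out.parameter == "c_max", "p_value"].iloc[0]
        p_alpha = out.loc[out.parameter == "alpha", "p_value"].iloc[0]
        assert p_cmax < 0.05 and p_cmax < p_alpha


class TestAuc28Screen:
    def test_scaling_halves_auc(self, small_cohort):
        auc = subject_auc28(small_cohort)
        halved = ck.KineticDataset(
            obs=small_cohort.obs.assign(
                DV=small_cohort.obs.DV * 0.5, LOQ=small_cohort.obs.LOQ * 0.5
            ),
            subjects=small_cohort.subjects,
        )
        auc2 = subject_auc28(halved)
        assert np.allclose(auc2.to_numpy(), 0.5 * auc.to_numpy())

    def test_subjects_without_enough_window_points_dropped(self, small_cohort):
        trimmed = ck.KineticDataset(
            obs=pd.concat(
                [
                    small_cohort.obs[small_cohort.obs.ID != 1],
                    small_cohort.obs[(small_cohort.obs.ID == 1)].iloc[:1],
                ]
            ).reset_index(drop=True),
            subjects=small_cohort.subjects,
        )
        auc = subject_auc28(trimmed)
        assert 1 not in auc.index

    def test_emm_group_has_lower_exposure(self, ref_pop):
        ds = ck.generate_cohort(ck.CohortConfig(n_subjects=80, seed=13), ref_pop)
        out = ck.auc28_screen(ds, "EMM")
        assert out["median_pos"] < out["median_neg"]


class TestScm:
    def test_empty_candidate_set_returns_base(self, ref_pop, small_cohort):
        base = _fake_fit(
            pd.DataFrame({"ID": small_cohort.subject_ids}), small_cohort
        )
        final, trace = scm(small_cohort, base, [])
        assert final is base
        assert trace.steps == []
        assert trace.selected == []

    def test_trace_selected_tracks_accepts(self):
        from cartpk.covariates import ScmStep

        steps = [
            ScmStep("forward", "EMM->c_max", 100.0, 90.0, 10.0, True),
            ScmStep("forward", "WT->c_max", 90.0, 89.0, 1.0, False),
            ScmStep("backward", "EMM->c_max", 90.0, 91.0, 1.0, True),
        ]
        assert ScmTrace(steps).selected == []
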