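"""Laplace NLME engine: likelihood oracles, invariances and recovery."""

import math

import numpy as np
import pandas as pd
import pytest

import cartpk as ck
from cartpk.model import omega_to_cv
from cartpk.nlme import eta_shrinkage, individual_conditional_neg2ll


def _subject_rows(n):
    return pd.DataFrame(
        [
            dict(
                ID=i + 1,
                AGE=50.0,
                SEX=0,
                WT=60.0,
                DOSE=1.0,
                EMM=0,
                PRIOR_CART=0,
                PRIOR_HSCT=0,
                CRS_GRADE=1,
                TTOCI=np.nan,
                TSTER=np.nan,
                RESPONSE=1,
            )
            for i in range(n)
        ]
    )


@pytest.fixture(scope="module")
def conjugate_toy():
    """Log-linear single-eta model whose marginal likelihood is Gaussian.

    A random effect on c_max alone shifts log-concentration additively at
    every time point, so with log-scale residual error the marginal of the
    log-observations is exactly multivariate normal.
    """
    rng = np.random.default_rng(3)
    theta = dict(c_max=1000.0, t_max=9.0, foldx=100.0, fb=0.1172, alpha=0.11, beta=0.006)
    omega, sp = 0.4, 0.3
    times = np.array([12.0, 16.0, 21.0, 28.0, 35.0])
    f_typ = ck.concentration(times, ck.IndividualParams(**theta))
    rows, exact = [], 0.0
    n = 12
    for i in range(n):
        eta = rng.normal(0, omega)
        lny = np.log(f_typ) + eta + rng.normal(0, sp, times.size)
        r = lny - np.log(f_typ)
        S = sp**2 * np.eye(times.size) + omega**2 * np.ones((times.size, times.size))
        exact += (
            times.size * np.log(2 * np.pi)
            + np.linalg.slogdet(S)[1]
            + r @ np.linalg.solve(S, r)
        )
        rows += [
            dict(ID=i + 1, TIME=t, DV=y, BLQ=0, LOQ=1e-6)
            for t, y in zip(times, np.exp(lny))
        ]
    data = ck.KineticDataset(obs=pd.DataFrame(rows), subjects=_subject_rows(n))
    pop = ck.PopulationModel(
        theta=theta,
        omega_cv={"c_max": omega_to_cv(omega)},
        sigma_prop=sp * 100,
        sigma_add=1e-4,
    )
    spec = ck.ModelSpec(random_effects=("c_max",), error_scale="log")
    return data, pop, spec, exact


class TestLaplaceOracle:
    def test_matches_exact_gaussian_marginal(self, conjugate_toy):
        data, pop, spec, exact = conjugate_toy
        assert abs(ck.laplace_ofv(data, pop, spec) - exact) < 1e-8

    def test_vanishing_bsv_approaches_pooled_neg2ll(self, conjugate_toy):
        data, pop, spec, _ = conjugate_toy
        import dataclasses

        tiny = dataclasses.replace(pop, omega_cv={"c_max": omega_to_cv(1e-3)})
        ofv = ck.laplace_ofv(data, tiny, spec)
        pooled = 0.0
        sp = pop.sigma_prop / 100.0
        f_typ = ck.concentration(
            np.array([12.0, 16.0, 21.0, 28.0, 35.0]), ck.IndividualParams(**pop.theta)
        )
        for _, g in data.obs.groupby("ID"):
            r = np.log(g["DV"].to_numpy()) - np.log(f_typ)
            v = sp**2 + (pop.sigma_add / f_typ) ** 2
            pooled += float(np.sum(np.log(2 * np.pi * v) + r * r / v))
        assert ofv == pytest.approx(pooled, abs=0.05)

    def test_duplicating_subjects_doubles_ofv(self, conjugate_toy):
        data, pop, spec, _ = conjugate_toy
        obs2 = pd.concat(
            [data.obs, data.obs.assign(ID=data.obs.ID + 100)], ignore_index=True
        )
        sub2 = pd.concat(
            [data.subjects, data.subjects.assign(ID=data.subjects.ID + 100)],
            ignore_index=True,
        )
        double = ck.KineticDataset(obs=obs2, subjects=sub2)
        assert ck.laplace_ofv(double, pop, spec) == pytest.approx(
            2 * ck.laplace_ofv(data, pop, spec), rel=1e-9
        )

    def test_subject_relabelling_invariance(self, conjugate_toy):
        data, pop, spec, _ = conjugate_toy
        perm = {i + 1: v for i, v in enumerate(np.random.default_rng(0).permutation(12) + 1)}
        shuffled = ck.KineticDataset(
            obs=data.obs.assign(ID=data.obs.ID.map(perm))
            .sort_values(["ID", "TIME"])
            .reset_index(drop=True),
            subjects=data.subjects.assign(ID=data.subjects.ID.map(perm))
            .sort_values("ID")
            .reset_index(drop=True),
        )
        assert ck.laplace_ofv(shuffled, pop, spec) == pytest.approx(
            ck.laplace_ofv(data, pop, spec), rel=1e-9
        )

    def test_m3_equals_discard_without_blq(self, conjugate_toy):
        data, pop, spec, _ = conjugate_toy
        import dataclasses

        a = ck.laplace_ofv(data, pop, dataclasses.replace(spec, blq="m3"))
        b = ck.laplace_ofv(data, pop, dataclasses.replace(spec, blq="discard"))
        assert a == pytest.approx(b, rel=1e-12)


class TestConditionalKernel:
    def test_single_observation_gaussian_density(self, ref_params):
        # additive-only error, eta = 0: -2 log N(y; f, sa^2) plus no prior
        y = ck.concentration(30.0, ref_params) + 50.0
        sa = 200.0
        out = individual_conditional_neg2ll(
            ref_params,
            eta=np.zeros(6),
            times=[30.0],
            dv=[y],
            blq=[False],
            loq=20.0,
            sigma_prop=0.0,
            sigma_add=sa,
            omega_sd=np.zeros(6),
        )
        f = ck.concentration(30.0, ref_params)
        expected = math.log(2 * math.pi * sa**2) + (y - f) ** 2 / sa**2
        assert out == pytest.approx(expected, rel=1e-10)

    def test_blq_with_high_prediction_is_huge(self, ref_params):
        # model predicts ~67,000 copies at the peak; claiming BLQ (<20) there
        out = individual_conditional_neg2ll(
            ref_params,
            eta=np.zeros(6),
            times=[ref_params.t_max],
            dv=[np.nan],
            blq=[True],
            loq=20.0,
            sigma_prop=1.0,
            sigma_add=1.0,
            omega_sd=np.zeros(6),
        )
        assert out > 1e3

    def test_prior_term_added(self, ref_params):
        omega = np.full(6, 0.5)
        eta = np.full(6, 0.3)
        base = individual_conditional_neg2ll(
            ref_params, np.zeros(6), [30.0], [1e4], [False], 20.0, 30.0, 1.0, omega
        )
        # same data evaluated at eta=0 vs shifted prior-only difference
        shifted = individual_conditional_neg2ll(
            ref_params, eta, [30.0], [1e4], [False], 20.0, 30.0, 1.0, omega
        )
        assert shifted - base == pytest.approx(np.sum(eta**2 / omega**2), rel=1e-9)


class TestShrinkage:
    def test_sd_convention_examples(self):
        ebes = np.array([[0.5], [-0.5]])  # SD = sqrt(0.5)... use direct values
        omega = np.array([np.std(ebes[:, 0], ddof=1)])
        assert eta_shrinkage(ebes, omega)[0] == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_ebes_fully_shrunk(self):
        ebes = np.zeros((5, 2))
        out = eta_shrinkage(ebes, np.array([0.5, 1.0]))
        assert np.allclose(out, 100.0)

    def test_half_sd_is_50_or_75_percent(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal(4000)
        draws = (draws - draws.mean()) / draws.std(ddof=1)  # exact unit SD
        ebes = (0.5 * draws)[:, None]
        omega = np.array([1.0])
        assert eta_shrinkage(ebes, omega)[0] == pytest.approx(50.0, abs=1e-9)
        assert eta_shrinkage(ebes, omega, convention="variance")[0] == pytest.approx(
            75.0, abs=1e-9
        )

    def test_zero_omega_reported_missing(self):
        out = eta_shrinkage(np.zeros((3, 1)), np.array([0.0]))
        assert np.isnan(out[0])


class TestEmpiricalBayes:
    def test_typical_subject_has_zero_etas(self, ref_pop):
        # noise-free observations generated exactly at the typical curve
        p = ck.IndividualParams(**ref_pop.theta)
        times = np.array(ck.DEFAULT_SCHEDULE[1:])
        rows = [
            dict(ID=1, TIME=t, DV=ck.concentration(t, p), BLQ=0, LOQ=1e-6)
            for t in times
        ] + [
            dict(ID=2, TIME=t, DV=ck.concentration(t, p) * 1.3, BLQ=0, LOQ=1e-6)
            for t in times
        ]
        data = ck.KineticDataset(obs=pd.DataFrame(rows), subjects=_subject_rows(2))
        import dataclasses

        pop = dataclasses.replace(ck.reference_population_model(emm_effect=False), sigma_prop=5.0, sigma_add=0.1)
        ebe = ck.empirical_bayes(data, pop)
        etas1 = ebe[ebe.ID == 1][[f"eta_{k}" for k in ck.PARAM_NAMES]].to_numpy()
        assert np.max(np.abs(etas1)) < 0.05

    def test_ebes_track_true_etas(self, ref_pop):
        ds = ck.generate_cohort(ck.CohortConfig(n_subjects=60, seed=11), ref_pop)
        ebe = ck.empirical_bayes(ds, ref_pop)
        merged = ebe.merge(ds.ground_truth, on="ID")
        from scipy.stats import spearmanr

        for k in ("c_max", "foldx", "alpha"):
            rho = spearmanr(merged[f"eta_{k}_x"], merged[f"eta_{k}_y"]).statistic
            assert rho > 0.3, f"eta_{k} rank correlation {rho}"


class TestFitRecovery:
    def test_low_noise_two_eta_model_recovers_theta(self):
        """Small, nearly noise-free cohort: typical values come back cleanly."""
        theta = dict(
            c_max=50000.0, t_max=9.0, foldx=2000.0, fb=0.15, alpha=0.12, beta=0.007
        )
        pop = ck.PopulationModel(
            theta=theta,
            omega_cv={"c_max": 20.0, "beta": 20.0},
            sigma_prop=3.0,
            sigma_add=0.1,
        )
        cfg = ck.CohortConfig(
            n_subjects=12,
            seed=5,
            emm_prevalence=0.0,
            toci_prob=0.0,
            ster_prob=0.0,
        )
        ds = ck.generate_cohort(cfg, pop)
        spec = ck.ModelSpec(random_effects=("c_max", "beta"))
        fr = ck.fit(ds, spec, options={"maxiter": 150})
        for k, tv in theta.items():
            assert fr.pop.theta[k] == pytest.approx(tv, rel=0.10), k

    def test_fit_rejects_underpopulated_data(self, ref_pop):
        rows = [dict(ID=1, TIME=t, DV=100.0, BLQ=0, LOQ=20.0) for t in (1.0, 2.0)]
        data = ck.KineticDataset(obs=pd.DataFrame(rows), subjects=_subject_rows(1))
        with pytest.raises(ValueError):
            ck.fit(data)
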