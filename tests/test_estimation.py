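"""Tests for FIML likelihood evaluation, model fitting, and uncertainty."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import dietval as dv
from dietval.estimation import FitConfig, fit_model, load_cohort


def complete_scenario(seed, n, p0, **kw):
    return dv.SimulationScenario(
        seed=seed, n_participants=n, nutrients={"x": p0},
        missing_webq=(0, 0, 0), missing_recall=(0, 0, 0),
        missing_biomarker=(0, 0, 0), **kw)


def brute_force_fiml(params, values):
    """Oracle: per-participant marginal normal density by dropping the
    missing rows/columns of the implied moments."""
    mean, cov = dv.implied_moments(params)
    total = 0.0
    for row in values:
        o = np.isfinite(row)
        total += multivariate_normal.logpdf(row[o], mean[o], cov[np.ix_(o, o)])
    return total


class TestLogLikelihood:
    def test_equals_complete_data_density(self, p0):
        sim = dv.generate_cohort(complete_scenario(1, 50, p0))
        cohort = sim.cohorts["x"]
        mean, cov = dv.implied_moments(p0)
        direct = multivariate_normal.logpdf(cohort.values, mean, cov).sum()
        assert dv.log_likelihood(p0, cohort) == pytest.approx(direct, abs=1e-10)

    def test_toy_marginalization_oracle(self, p0):
        # two participants, one missing cell: FIML must equal the hand
        # marginalization that drops the corresponding row/column
        sim = dv.generate_cohort(complete_scenario(2, 2, p0))
        values = sim.cohorts["x"].values.copy()
        values[1, 4] = np.nan
        cohort = dv.CohortMeasurements(
            nutrient="x", ids=np.array(["a", "b"]), values=values,
            sex=np.zeros(2), age=np.full(2, 40.0), bmi=np.full(2, 24.0))
        assert dv.log_likelihood(p0, cohort) == pytest.approx(
            brute_force_fiml(p0, values), abs=1e-10)

    def test_matches_brute_force_with_general_missingness(self, p0):
        sim = dv.generate_cohort(dv.SimulationScenario(
            seed=3, n_participants=80, nutrients={"x": p0}))
        cohort = sim.cohorts["x"]
        assert dv.log_likelihood(p0, cohort) == pytest.approx(
            brute_force_fiml(p0, cohort.values), rel=1e-12)

    def test_truth_beats_perturbed_parameters(self, p0):
        cohort = dv.generate_cohort(complete_scenario(4, 5000, p0)).cohorts["x"]
        at_truth = dv.log_likelihood(p0, cohort)
        worse = p0.replace(beta_Q1=p0.beta_Q1 * 1.3, sigma2_T=p0.sigma2_T * 0.7)
        assert at_truth > dv.log_likelihood(worse, cohort)

    def test_invariant_to_participant_order(self, p0, small_sim):
        cohort = small_sim.cohorts["protein"]
        params = dv.default_nutrient_parameters()["protein"]
        base = dv.log_likelihood(params, cohort)
        rng = np.random.default_rng(0)
        perm = rng.permutation(cohort.n)
        shuffled = cohort.subset(perm)
        assert dv.log_likelihood(params, shuffled) == pytest.approx(base, rel=1e-12)

    def test_invariant_to_occasion_order_when_exchangeable(self, p0):
        # with zero drift the occasions are exchangeable, so permuting the
        # occasion columns within each instrument leaves the likelihood fixed
        cohort = dv.generate_cohort(dv.SimulationScenario(
            seed=5, n_participants=60, nutrients={"x": p0})).cohorts["x"]
        p = p0.replace(mu_Q=(0.0,) * 3, mu_F=(0.0,) * 3, mu_M=(0.0,) * 3)
        base = dv.log_likelihood(p, cohort)
        perm = [2, 0, 1]
        cols = np.r_[perm, [3 + j for j in perm], [6 + j for j in perm]]
        permuted = dv.CohortMeasurements(
            nutrient="x", ids=cohort.ids, values=cohort.values[:, cols],
            sex=cohort.sex, age=cohort.age, bmi=cohort.bmi)
        assert dv.log_likelihood(p, permuted) == pytest.approx(base, rel=1e-12)

    def test_infinite_values_rejected(self, p0):
        values = np.full((3, 9), 1.0)
        values[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            dv.CohortMeasurements(
                nutrient="x", ids=np.arange(3), values=values,
                sex=np.zeros(3), age=np.zeros(3), bmi=np.zeros(3))

    def test_empty_participants_excluded_with_warning(self, p0, caplog):
        sim = dv.generate_cohort(complete_scenario(6, 5, p0))
        values = sim.cohorts["x"].values.copy()
        values[2, :] = np.nan
        cohort = dv.CohortMeasurements(
            nutrient="x", ids=np.arange(5), values=values,
            sex=np.zeros(5), age=np.zeros(5), bmi=np.zeros(5))
        import logging
        with caplog.at_level(logging.WARNING, logger="dietval.estimation"):
            ll = dv.log_likelihood(p0, cohort)
        assert "no observed measurements" in caplog.text
        assert ll == pytest.approx(brute_force_fiml(p0, values[[0, 1, 3, 4]]), rel=1e-12)


class TestFitModel:
    def test_zero_noise_cohort_gives_perfect_validity(self, p0):
        perfect = dv.ModelParameters(mu_T=4.0, sigma2_T=0.1)
        cohort = dv.generate_cohort(
            complete_scenario(7, 200, perfect)).cohorts["x"]
        fit = fit_model(cohort, config=FitConfig(compute_vcov=False))
        assert fit.attenuation(1) == pytest.approx(1.0, abs=1e-3)
        assert fit.correlation(1) == pytest.approx(1.0, abs=1e-3)
        assert fit.boundary_params  # error variances pinned at the floor

    def test_parameter_recovery_within_3se(self, p0):
        cohort = dv.generate_cohort(dv.SimulationScenario(
            seed=8, n_participants=2000, nutrients={"x": p0})).cohorts["x"]
        fit = fit_model(cohort)
        assert fit.converged
        from dietval.estimation import _layout, _pack, _to_free
        lay = _layout(3)
        z_true = _to_free(_pack(p0), lay)
        se = np.sqrt(np.diag(fit.vcov))
        pulls = (fit._free - z_true) / np.maximum(se, 1e-12)
        assert np.all(np.abs(pulls) < 3.0), pulls

    def test_ml_matches_method_of_moments(self, p0):
        cohort = dv.generate_cohort(dv.SimulationScenario(
            seed=9, n_participants=20_000, nutrients={"x": p0})).cohorts["x"]
        fit = fit_model(cohort, config=FitConfig(compute_vcov=False))
        V = np.ma.masked_invalid(cohort.values)
        C = np.asarray(np.ma.cov(V, rowvar=False, allow_masked=True))
        # cov(Q, M) = beta_Q1 sigma2_T for every occasion pair; var(Q_j) is
        # the lambda_1 denominator, so cov(Q,M)/var(Q) estimates lambda_1
        lam_mom = C[0:3, 6:9].mean() / np.diag(C[0:3, 0:3]).mean()
        assert fit.attenuation(1) == pytest.approx(lam_mom, abs=0.01)

    def test_fit_is_deterministic(self, small_sim):
        cohort = small_sim.cohorts["potassium"]
        f1 = fit_model(cohort, config=FitConfig(compute_vcov=False))
        f2 = fit_model(cohort, config=FitConfig(compute_vcov=False))
        assert f1.params == f2.params
        assert f1.loglik == f2.loglik

    def test_fit_improves_on_initialization(self, small_sim):
        from dietval.estimation import _moment_start
        cohort = small_sim.cohorts["sugars"]
        fit = fit_model(cohort, config=FitConfig(compute_vcov=False))
        start = _moment_start(cohort.values, 3)
        assert fit.loglik >= dv.log_likelihood(start, cohort)

    def test_multistart_agrees_with_single_start(self, small_sim):
        cohort = small_sim.cohorts["protein"]
        f1 = fit_model(cohort, config=FitConfig(compute_vcov=False))
        f5 = fit_model(cohort, config=FitConfig(compute_vcov=False, n_starts=5, seed=3))
        assert f5.loglik >= f1.loglik - 1e-6
        assert f5.attenuation(1) == pytest.approx(f1.attenuation(1), abs=5e-3)

    def test_unidentified_cohort_rejected(self, p0):
        values = np.full((10, 9), np.nan)
        values[:, 0] = 1.0
        values[:, 6] = 2.0     # single biomarker occasion only
        cohort = dv.CohortMeasurements(
            nutrient="x", ids=np.arange(10), values=values,
            sex=np.zeros(10), age=np.zeros(10), bmi=np.zeros(10))
        with pytest.raises(ValueError, match="replicates"):
            fit_model(cohort)


class TestMetricUncertainty:
    def test_interval_brackets_estimate_and_methods_overlap(self, protein_fit):
        mi = dv.metric_uncertainty(protein_fit, "attenuation", k=1,
                                   n_boot=80, seed=2)
        assert mi.ci_low <= mi.estimate <= mi.ci_high
        assert mi.ci_low < mi.ci_high
        # bootstrap and delta intervals overlap on a well-conditioned fit
        assert mi.ci_low < mi.delta_high and mi.delta_low < mi.ci_high
        assert mi.n_boot_failed == 0

    def test_correlation_interval_within_unit_range(self, protein_fit):
        mi = dv.metric_uncertainty(protein_fit, "correlation", k=2,
                                   n_boot=40, seed=3)
        assert 0 < mi.estimate < 1
        assert mi.ci_low <= mi.estimate <= mi.ci_high

    def test_rejects_unknown_metric(self, protein_fit):
        with pytest.raises(ValueError, match="metric"):
            dv.metric_uncertainty(protein_fit, "slope")


class TestSubgroups:
    def test_homogeneous_cohort_strata_agree(self, p0):
        cohort = dv.generate_cohort(dv.SimulationScenario(
            seed=12, n_participants=2000, nutrients={"x": p0})).cohorts["x"]
        cfg = FitConfig(compute_vcov=False)
        fits = dv.fit_subgroups(cohort, "sex", config=cfg)
        assert set(fits) == {"men", "women"}
        lam = [f.attenuation(1) for f in fits.values()]
        assert abs(lam[0] - lam[1]) < 0.08   # sampling error only

    def test_extra_person_bias_lowers_attenuation(self, p0):
        # women simulated with tripled person-specific bias variance: their
        # stratum must show the lower fitted attenuation factor
        noisier = p0.replace(sigma2_r=3 * p0.sigma2_r)
        a = dv.generate_cohort(dv.SimulationScenario(
            seed=13, n_participants=1500, nutrients={"x": p0}))
        b = dv.generate_cohort(dv.SimulationScenario(
            seed=14, n_participants=1500, nutrients={"x": noisier}))
        ca, cb = a.cohorts["x"], b.cohorts["x"]
        merged = dv.CohortMeasurements(
            nutrient="x",
            ids=np.r_[ca.ids, np.char.add(cb.ids.astype(str), "_b")],
            values=np.vstack([ca.values, cb.values]),
            sex=np.r_[np.zeros(ca.n), np.ones(cb.n)],
            age=np.r_[ca.age, cb.age], bmi=np.r_[ca.bmi, cb.bmi])
        fits = dv.fit_subgroups(merged, "sex", config=FitConfig(compute_vcov=False))
        assert fits["women"].attenuation(1) < fits["men"].attenuation(1)

    def test_understrength_stratum_skipped_with_warning(self, small_sim):
        cohort = small_sim.cohorts["protein"].subset(np.arange(30))
        cohort.age = np.full(30, 30.0)     # empty >=40 stratum
        with pytest.warns(UserWarning, match="skipped"):
            fits = dv.fit_subgroups(cohort, "age",
                                    config=FitConfig(compute_vcov=False))
        assert list(fits) == ["age<40"]

    def test_unknown_stratifier_rejected(self, small_sim):
        with pytest.raises(ValueError, match="stratifier"):
            dv.fit_subgroups(small_sim.cohorts["protein"], "height")


class TestLongFormatIO:
    def test_roundtrip_through_file(self, tmp_path, small_sim):
        cohort = small_sim.cohorts["protein"]
        long = cohort.to_long()
        # write in natural units so the loader applies the log transform
        long["value"] = np.exp(long["value"])
        path = tmp_path / "cohort.tsv"
        long.to_csv(path, sep="\t", index=False)
        back = load_cohort(path, nutrient="protein", log_transform=True)
        assert back.n == cohort.n
        # align on ids and compare matrices (missing cells preserved)
        order = {pid: i for i, pid in enumerate(back.ids)}
        idx = [order[p] for p in cohort.ids]
        np.testing.assert_allclose(back.values[idx], cohort.values,
                                   rtol=0, atol=1e-12, equal_nan=True)

    def test_nonpositive_values_cannot_be_logged(self, tmp_path):
        import pandas as pd
        df = pd.DataFrame({
            "participant_id": ["a"], "occasion": [1],
            "instrument": ["webq"], "nutrient": ["x"], "value": [-1.0],
        })
        with pytest.raises(ValueError, match="nonpositive"):
            dv.CohortMeasurements.from_long(df, design=dv.DesignSpec(3))
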