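"""Unit and property tests for the measurement-error model algebra."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import dietval as dv
from dietval.model import ExtrapolationInput, InfeasibleRatioError


def params(**kw):
    base = dict(mu_T=0.0, sigma2_T=1.0)
    base.update(kw)
    return dv.ModelParameters(**base)


# ---------------------------------------------------------------------------
# implied moments
# ---------------------------------------------------------------------------

class TestImpliedMoments:
    def test_perfect_instruments_give_rank_one_covariance(self):
        # all error variances zero, slopes 1, intercepts 0: every measure
        # equals T exactly, so the 9x9 covariance is all ones
        mean, cov = dv.implied_moments(params(mu_T=2.0))
        assert np.allclose(cov, np.ones((9, 9)))
        assert np.allclose(mean, 2.0)

    def test_biomarker_cross_occasion_covariance_is_sigma2T(self, p0):
        _, cov = dv.implied_moments(p0)
        M = cov[6:, 6:]
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(M[off], p0.sigma2_T)

    def test_block_structure(self, p0):
        _, cov = dv.implied_moments(p0)
        # QM block is beta_Q1 * sigma2_T everywhere (errors independent of T)
        assert np.allclose(cov[0:3, 6:9], p0.beta_Q1 * p0.sigma2_T)
        # QF block includes the bias covariance
        expected = (p0.beta_Q1 * p0.beta_F1 * p0.sigma2_T
                    + p0.rho_rs * math.sqrt(p0.sigma2_r * p0.sigma2_s))
        assert np.allclose(cov[0:3, 3:6], expected)

    def test_moments_match_large_simulation(self, p0):
        n = 200_000
        sc = dv.SimulationScenario(
            seed=11, n_participants=n, nutrients={"x": p0},
            missing_webq=(0, 0, 0), missing_recall=(0, 0, 0),
            missing_biomarker=(0, 0, 0))
        values = dv.generate_cohort(sc).cohorts["x"].values
        mean, cov = dv.implied_moments(p0)
        emp_mean = values.mean(axis=0)
        emp_cov = np.cov(values, rowvar=False)
        se_mean = np.sqrt(np.diag(cov) / n)
        assert np.all(np.abs(emp_mean - mean) < 3 * se_mean)
        v = np.diag(cov)
        se_cov = np.sqrt((np.outer(v, v) + cov ** 2) / n)
        assert np.all(np.abs(emp_cov - cov) < 3 * se_cov)

    @given(st.floats(0.1, 2.0), st.floats(-1.5, 1.5), st.floats(0.0, 1.0),
           st.floats(0.0, 1.0), st.floats(-0.99, 0.99), st.floats(0.0, 1.0))
    def test_covariance_always_psd(self, s2T, bQ1, s2r, s2s, rho, s2e):
        p = params(sigma2_T=s2T, beta_Q1=bQ1, sigma2_r=s2r, sigma2_s=s2s,
                   rho_rs=rho, sigma2_eps=s2e, sigma2_u=0.3, sigma2_v=0.2)
        _, cov = dv.implied_moments(p)
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() >= -1e-10

    @pytest.mark.parametrize("bad, match", [
        (dict(sigma2_T=-1.0), "sigma2_T"),
        (dict(rho_rs=1.5), "rho_rs"),
        (dict(sigma2_eps=float("nan")), "sigma2_eps"),
        (dict(mu_Q=(0.1, 0.0, 0.0)), "anchor"),
        (dict(mu_F=(0.0, 0.0)), "occasion"),
        (dict(beta_Q1=float("inf")), "beta_Q1"),
    ])
    def test_invalid_parameters_rejected(self, bad, match):
        with pytest.raises(ValueError, match=match):
            dv.implied_moments(params(**bad))


# ---------------------------------------------------------------------------
# attenuation and correlation
# ---------------------------------------------------------------------------

class TestValidityMetrics:
    def test_known_variance_split(self):
        # beta=1, sigma2_T=1, person bias 1, within error 2:
        # lambda_1 = 1/(1+1+2) = 0.25, lambda_2 = 1/(1+1+1) = 1/3,
        # rho_1 = 1/sqrt(4) = 0.5, rho_2 = 1/sqrt(3)
        p = params(sigma2_r=1.0, sigma2_eps=2.0)
        assert dv.attenuation_factor(p, "webq", 1) == pytest.approx(0.25)
        assert dv.attenuation_factor(p, "webq", 2) == pytest.approx(1 / 3)
        assert dv.correlation_with_truth(p, "webq", 1) == pytest.approx(0.5)
        assert dv.correlation_with_truth(p, "webq", 2) == pytest.approx(1 / math.sqrt(3))

    def test_error_free_instrument_is_perfect(self):
        p = params()
        for k in (1, 2, 7):
            assert dv.attenuation_factor(p, "webq", k) == pytest.approx(1.0)
            assert dv.correlation_with_truth(p, "webq", k) == pytest.approx(1.0)

    def test_matches_regression_slope_in_simulation(self, p0):
        # independent oracle: lambda_k is the slope of regressing true intake
        # on the mean of k administrations; rho_k the plain correlation
        sc = dv.SimulationScenario(
            seed=7, n_participants=400_000, nutrients={"x": p0},
            missing_webq=(0, 0, 0), missing_recall=(0, 0, 0),
            missing_biomarker=(0, 0, 0))
        sim = dv.generate_cohort(sc)
        T = sim.true_intake["x"]
        Q = sim.cohorts["x"].values[:, :3]
        for k in (1, 2, 3):
            qbar = Q[:, :k].mean(axis=1)
            slope = np.cov(T, qbar)[0, 1] / np.var(qbar, ddof=1)
            corr = np.corrcoef(T, qbar)[0, 1]
            assert slope == pytest.approx(dv.attenuation_factor(p0, "webq", k), abs=5e-3)
            assert corr == pytest.approx(dv.correlation_with_truth(p0, "webq", k), abs=5e-3)

    def test_recall_uses_its_own_components(self, p0):
        lam = dv.attenuation_factor(p0, "recall", 1)
        expected = p0.beta_F1 * p0.sigma2_T / (
            p0.beta_F1 ** 2 * p0.sigma2_T + p0.sigma2_s + p0.sigma2_u)
        assert lam == pytest.approx(expected)

    def test_biomarker_and_bad_k_rejected(self, p0):
        with pytest.raises(ValueError, match="instrument"):
            dv.attenuation_factor(p0, "biomarker", 1)
        with pytest.raises(ValueError, match="k must be"):
            dv.attenuation_factor(p0, "webq", 0)
        with pytest.raises(ValueError, match="k must be"):
            dv.correlation_with_truth(p0, "webq", -3)

    def test_nonpositive_slope_warns(self):
        p = params(beta_Q1=-0.5, sigma2_eps=0.5)
        with pytest.warns(UserWarning, match="beta1"):
            dv.attenuation_factor(p, "webq", 1)


# ---------------------------------------------------------------------------
# closed-form extrapolation
# ---------------------------------------------------------------------------

PRINTED_CELLS = [
    # (lambda1, lambda2, rho1), k, expected lambda_k, expected rho_k (2 dp)
    ((0.27, 0.37, 0.40), 3, 0.42, 0.50),   # protein
    ((0.27, 0.37, 0.40), 4, 0.45, 0.52),
    ((0.27, 0.37, 0.40), 5, 0.48, 0.53),
    ((0.31, 0.42, 0.34), 3, 0.48, 0.42),   # potassium
    ((0.31, 0.45, 0.33), 3, 0.53, 0.43),   # total sugars
    ((0.31, 0.45, 0.33), 5, 0.62, 0.47),
    ((0.22, 0.31, 0.32), 2, 0.31, 0.38),   # total energy
]


class TestExtrapolation:
    @pytest.mark.parametrize("triple, k, lam2dp, rho2dp", PRINTED_CELLS)
    def test_reproduces_published_repeat_cells(self, triple, k, lam2dp, rho2dp):
        lam, rho = dv.extrapolate_from_pair(ExtrapolationInput(*triple), k)
        assert dv.round_half_up(lam) == pytest.approx(lam2dp)
        assert dv.round_half_up(rho) == pytest.approx(rho2dp)

    def test_no_within_person_error_is_constant(self):
        inp = ExtrapolationInput(0.5, 0.5, 0.5)
        for k in (1, 2, 99):
            assert dv.extrapolate_from_pair(inp, k) == pytest.approx((0.5, 0.5))

    @given(st.floats(0.05, 0.9), st.floats(1.0, 1.95), st.floats(0.05, 1.0))
    def test_identity_and_monotonicity(self, lam1, ratio, rho1):
        lam2 = lam1 * ratio
        inp = ExtrapolationInput(lam1, lam2, rho1)
        prev = (0.0, 0.0)
        for k in range(1, 8):
            lam, rho = dv.extrapolate_from_pair(inp, k)
            # correlation-attenuation identity holds to machine precision
            assert (rho / rho1) ** 2 == pytest.approx(lam / lam1, rel=1e-12)
            assert lam >= prev[0] and rho >= prev[1]
            prev = (lam, rho)
        # finite limits
        x = inp.variance_ratio
        assert prev[0] <= lam1 * (1 + x) + 1e-12

    def test_k1_k2_recover_inputs(self):
        inp = ExtrapolationInput(0.27, 0.37, 0.40)
        assert dv.extrapolate_from_pair(inp, 1) == pytest.approx((0.27, 0.40))
        assert dv.extrapolate_from_pair(inp, 2)[0] == pytest.approx(0.37)

    def test_roundtrip_with_model_parameters(self, p0):
        # extrapolating from the model's own (lambda1, lambda2, rho1) must
        # agree with the direct closed forms for every k
        inp = ExtrapolationInput(
            dv.attenuation_factor(p0, "webq", 1),
            dv.attenuation_factor(p0, "webq", 2),
            dv.correlation_with_truth(p0, "webq", 1))
        for k in range(1, 11):
            lam, rho = dv.extrapolate_from_pair(inp, k)
            assert lam == pytest.approx(dv.attenuation_factor(p0, "webq", k), abs=1e-12)
            assert rho == pytest.approx(dv.correlation_with_truth(p0, "webq", k), abs=1e-12)

    def test_infeasible_ratio_raises(self):
        with pytest.raises(InfeasibleRatioError):
            ExtrapolationInput(0.2, 0.4, 0.5)      # ratio exactly 2
        with pytest.raises(InfeasibleRatioError):
            ExtrapolationInput(0.2, 0.45, 0.5)     # ratio > 2
        with pytest.raises(InfeasibleRatioError):
            ExtrapolationInput(0.4, 0.3, 0.5)      # decreasing


# ---------------------------------------------------------------------------
# construction from printed metrics & serialization
# ---------------------------------------------------------------------------

class TestParameterConstruction:
    @pytest.mark.parametrize("triple", [t for t, *_ in PRINTED_CELLS[:1]] + [
        (0.31, 0.42, 0.34), (0.22, 0.31, 0.32)])
    def test_solved_parameters_reproduce_metrics(self, triple):
        lam1, lam2, rho1 = triple
        p = dv.parameters_from_validity(lam1, lam2, rho1, sigma2_T=0.1)
        assert dv.attenuation_factor(p, "webq", 1) == pytest.approx(lam1, abs=1e-12)
        assert dv.attenuation_factor(p, "webq", 2) == pytest.approx(lam2, abs=1e-12)
        assert dv.correlation_with_truth(p, "webq", 1) == pytest.approx(rho1, abs=1e-12)

    def test_incompatible_metrics_rejected(self):
        # a correlation this high is impossible given the small k=1 -> k=2
        # attenuation gain (it would need negative person-bias variance)
        with pytest.raises(ValueError, match="person-bias"):
            dv.parameters_from_validity(0.5, 0.65, 0.8, sigma2_T=0.1)

    def test_json_roundtrip_is_lossless(self, p0):
        restored = dv.ModelParameters.from_json(p0.to_json())
        assert restored == p0
        # field names are exactly the documented flat keys
        keys = set(json.loads(p0.to_json()))
        assert keys == {
            "mu_T", "sigma2_T", "mu_Q", "mu_F", "mu_M", "beta_Q0", "beta_F0",
            "beta_Q1", "beta_F1", "sigma2_r", "sigma2_s", "rho_rs",
            "sigma2_eps", "sigma2_u", "sigma2_v"}
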