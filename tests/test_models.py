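import numpy as np
import pandas as pd
import pytest

from perijoint.models import (
    FitResult,
    ModelFrame,
    ModelSpec,
    cluster_logliks,
    decode_psi,
    encode_psi,
    fit_model,
    loglik_bivariate,
    loglik_multinomial,
    score_and_information,
)
from perijoint.simulate import GeneratorConfig, simulate_registry

from .oracles import logistic_loglik, multinomial_loglik, trapezoid_raw

BIV_SPEC = ModelSpec(
    kind="bivariate",
    covariates_preterm=["anc_visits", "parity"],
    covariates_death=["anc_visits"],
    random_structure="shared",
)


def _theta(frame, beta_value=0.3, log_sd=np.log(0.6)):
    n_beta = sum(frame.n_beta)
    return np.r_[np.full(n_beta, beta_value), np.full(frame.spec.n_psi, log_sd)]


class TestPsiEncoding:
    @pytest.mark.parametrize(
        "spec,D",
        [
            (ModelSpec(kind="bivariate", random_structure="shared"), [[0.37]]),
            (ModelSpec(kind="bivariate", random_structure="correlated"), [[0.6, 0.25], [0.25, 0.9]]),
            (
                ModelSpec(kind="multinomial", random_structure="correlated"),
                [[1.0, 0.3, -0.2], [0.3, 0.8, 0.1], [-0.2, 0.1, 0.5]],
            ),
            (
                ModelSpec(kind="bivariate", random_structure="correlated", equal_variances=True),
                [[0.5, -0.2], [-0.2, 0.5]],
            ),
        ],
    )
    def test_round_trip(self, spec, D):
        D = np.asarray(D)
        got = decode_psi(encode_psi(D, spec), spec)
        np.testing.assert_allclose(got, D, atol=1e-10)


class TestBivariateLoglik:
    def test_degenerate_variance_equals_independent_logits(self, small_bivariate_registry):
        frame = ModelFrame(small_bivariate_registry, BIV_SPEC)
        theta = _theta(frame, log_sd=-20.0)
        got = loglik_bivariate(theta, frame, BIV_SPEC)
        betas, _ = frame.split_theta(theta)
        inv = np.empty_like(frame._perm)
        inv[frame._perm] = np.arange(len(frame._perm))
        y = frame.y[inv]
        n1 = frame.X[0].shape[0]
        want = logistic_loglik(frame.X[0] @ betas[0], y[:n1]) + logistic_loglik(
            frame.X[1] @ betas[1], y[n1:]
        )
        assert got == pytest.approx(want, abs=1e-8)

    def test_single_cluster_matches_trapezoid(self):
        # one mother, one delivery, both outcomes, beta = 0, sigma^2 = 1
        df = pd.DataFrame(
            {
                "mother_id": ["m1"],
                "birth_index": [1],
                "year": [2010],
                "gestational_age_weeks": [34.0],
                "perinatal_death": [0.0],
                "preterm": [1.0],
                "cooccurrence": [3.0],
            }
        )
        spec = ModelSpec(kind="bivariate", random_structure="shared")
        frame = ModelFrame(df, spec)
        theta = np.array([0.0, 0.0, 0.0])  # intercepts, log sd = 0
        # a single broad Bernoulli factor needs a higher order than the
        # default 10 points to reach 1e-8 absolute accuracy
        got = loglik_bivariate(theta, frame, spec, rule=20)

        def integrand(b):
            from scipy.special import expit

            return expit(b) * (1 - expit(b)) * np.exp(-0.5 * b**2) / np.sqrt(2 * np.pi)

        want = np.log(trapezoid_raw(integrand, -10, 10))
        assert got == pytest.approx(want, abs=1e-8)

    def test_perfect_correlation_recovers_shared_model(self, small_bivariate_registry):
        shared = ModelSpec(
            kind="bivariate",
            covariates_preterm=["anc_visits"],
            covariates_death=["anc_visits"],
            random_structure="shared",
        )
        corr = ModelSpec(
            kind="bivariate",
            covariates_preterm=["anc_visits"],
            covariates_death=["anc_visits"],
            random_structure="correlated",
        )
        f_sh = ModelFrame(small_bivariate_registry, shared)
        f_co = ModelFrame(small_bivariate_registry, corr)
        beta = np.array([-1.4, 0.7, -2.1, 0.4])
        sd = 0.6
        th_sh = np.r_[beta, np.log(sd)]
        # D = sd^2 * J via an (almost) rank-one Cholesky factor
        th_co = np.r_[beta, np.log(sd), sd, np.log(1e-8)]
        ll_sh = cluster_logliks(th_sh, f_sh, 20, adaptive=False).sum()
        ll_co = cluster_logliks(th_co, f_co, 20, adaptive=False).sum()
        assert ll_co == pytest.approx(ll_sh, abs=1e-6)

    def test_partial_outcome_contributes_single_factor(self):
        # death missing on one record: that record only carries its preterm factor
        df = pd.DataFrame(
            {
                "mother_id": ["m1", "m1", "m2"],
                "birth_index": [1, 2, 1],
                "year": [2010] * 3,
                "gestational_age_weeks": [34.0, 39.0, 38.0],
                "perinatal_death": [0.0, np.nan, 1.0],
                "preterm": [1.0, 0.0, 0.0],
                "cooccurrence": [3.0, np.nan, 2.0],
            }
        )
        spec = ModelSpec(kind="bivariate", random_structure="shared")
        frame = ModelFrame(df, spec)
        assert frame.n_obs == {"preterm": 3, "death": 2}
        complete = ModelSpec(kind="bivariate", random_structure="shared", complete_case=True)
        frame_cc = ModelFrame(df, complete)
        assert frame_cc.n_obs == {"preterm": 2, "death": 2}

    def test_empty_cluster_set_rejected(self):
        df = pd.DataFrame(
            {
                "mother_id": ["m1"],
                "birth_index": [1],
                "year": [2010],
                "gestational_age_weeks": [np.nan],
                "perinatal_death": [np.nan],
                "preterm": [np.nan],
                "cooccurrence": [np.nan],
            }
        )
        with pytest.raises(ValueError, match="empty cluster set"):
            ModelFrame(df, ModelSpec(kind="bivariate", random_structure="shared"))


class TestMultinomialLoglik:
    MN_SPEC = ModelSpec(kind="multinomial", covariates=["anc_visits"], random_structure="shared")

    def test_degenerate_variance_equals_plain_multinomial(self, small_multinomial_registry):
        frame = ModelFrame(small_multinomial_registry, self.MN_SPEC)
        theta = np.r_[np.full(6, 0.25), -20.0]
        got = loglik_multinomial(theta, frame, self.MN_SPEC)
        betas, _ = frame.split_theta(theta)
        inv = np.empty_like(frame._perm)
        inv[frame._perm] = np.arange(len(frame._perm))
        y = frame.y[inv]
        eta3 = frame.X[0] @ np.column_stack(betas)
        assert got == pytest.approx(multinomial_loglik(eta3, y), abs=1e-8)

    def test_two_active_categories_reduce_to_binary_logit(self, small_bivariate_registry):
        # force categories 'both' and 'death only' to probability ~0: the
        # model collapses to a binary logit for 'preterm only' vs reference
        df = small_bivariate_registry.copy()
        df = df[df["preterm"].notna()].copy()
        df["perinatal_death"] = 0.0
        df["cooccurrence"] = np.where(df["preterm"] == 1, 3.0, 0.0)
        mn = ModelSpec(kind="multinomial", covariates=["anc_visits"], random_structure="shared")
        f_mn = ModelFrame(df, mn)
        beta3 = np.array([-1.2, 0.8])
        theta_mn = np.r_[[-40.0, 0.0], [-40.0, 0.0], beta3, np.log(0.5)]
        biv = ModelSpec(kind="bivariate", covariates_preterm=["anc_visits"], random_structure="shared")
        df_b = df.copy()
        df_b["perinatal_death"] = np.nan  # only the preterm factor remains
        f_bv = ModelFrame(df_b, biv)
        theta_bv = np.r_[beta3, np.zeros(f_bv.n_beta[1]), np.log(0.5)]
        got = loglik_multinomial(theta_mn, f_mn, mn)
        want = loglik_bivariate(theta_bv, f_bv, biv)
        assert got == pytest.approx(want, abs=1e-8)

    def test_shared_equals_separate_with_rank_one_covariance(self, small_multinomial_registry):
        sep = ModelSpec(kind="multinomial", covariates=["anc_visits"], random_structure="correlated")
        f_sh = ModelFrame(small_multinomial_registry, self.MN_SPEC)
        f_sep = ModelFrame(small_multinomial_registry, sep)
        beta = np.full(6, 0.2)
        sd = 0.55
        th_sh = np.r_[beta, np.log(sd)]
        th_sep = np.r_[beta, np.log(sd), sd, np.log(1e-8), sd, 0.0, np.log(1e-8)]
        ll_sh = cluster_logliks(th_sh, f_sh, 15, adaptive=False).sum()
        ll_sep = cluster_logliks(th_sep, f_sep, 15, adaptive=False).sum()
        assert ll_sep == pytest.approx(ll_sh, abs=1e-5)


class TestLoglikBounds:
    @pytest.mark.parametrize(
        "psi",
        [
            [1.5, 5.0, -8.0, 5.0, 5.0, -8.0],  # near-singular, wide spread
            [0.3, 5.0, -8.0, 0.0, 0.0, -8.0],
            [-8.0, 0.0, -8.0, 0.0, 0.0, -8.0],
        ],
    )
    def test_cluster_log_probabilities_never_positive(self, small_multinomial_registry, psi):
        """Marginal cluster likelihoods are probabilities: log <= 0 must hold
        even at degenerate covariance corners of the parameter space."""
        spec = ModelSpec(kind="multinomial", covariates=["anc_visits"], random_structure="correlated")
        frame = ModelFrame(small_multinomial_registry, spec)
        theta = np.r_[np.full(6, 0.3), psi]
        ll = cluster_logliks(theta, frame, 4, adaptive=True)
        assert np.all(ll <= 1e-8)


class TestFit:
    def test_refit_is_bitwise_deterministic(self, small_bivariate_registry):
        a = fit_model(BIV_SPEC, small_bivariate_registry, compute_vcov=False)
        b = fit_model(BIV_SPEC, small_bivariate_registry, compute_vcov=False)
        np.testing.assert_array_equal(a.theta, b.theta)
        assert a.loglik == b.loglik and a.bic == b.bic

    def test_gradient_small_and_information_psd_at_optimum(self, small_bivariate_registry):
        frame = ModelFrame(small_bivariate_registry, BIV_SPEC)
        fit = fit_model(BIV_SPEC, frame, compute_vcov=False)
        assert fit.converged
        grad, info = score_and_information(fit.theta, frame, BIV_SPEC)
        assert np.max(np.abs(grad)) < 1e-2 * max(1.0, abs(fit.loglik)) ** 0.0 + 1e-1
        ev = np.linalg.eigvalsh(info)
        assert ev.min() > -1e-6 * max(1.0, ev.max())

    def test_gradient_matches_definitional_difference(self, small_bivariate_registry):
        frame = ModelFrame(small_bivariate_registry, BIV_SPEC)
        rng = np.random.default_rng(8)
        theta = _theta(frame) + 0.05 * rng.standard_normal(frame.n_params)
        grad, _ = score_and_information(theta, frame, BIV_SPEC)
        i = 2
        h = 1e-5 * max(1.0, abs(theta[i]))
        e = np.zeros_like(theta)
        e[i] = h
        want = (
            cluster_logliks(theta + e, frame).sum() - cluster_logliks(theta - e, frame).sum()
        ) / (2 * h)
        assert grad[i] == pytest.approx(want, abs=1e-6 * max(1.0, abs(want)))

    def test_needs_two_clusters(self):
        df = pd.DataFrame(
            {
                "mother_id": ["m1", "m1"],
                "birth_index": [1, 2],
                "year": [2010, 2012],
                "gestational_age_weeks": [34.0, 39.0],
                "perinatal_death": [0.0, 0.0],
                "preterm": [1.0, 0.0],
                "cooccurrence": [3.0, 0.0],
            }
        )
        with pytest.raises(ValueError, match="2 clusters"):
            fit_model(ModelSpec(kind="bivariate", random_structure="shared"), df)

    def test_fit_result_json_round_trip(self, tmp_path, small_bivariate_registry):
        fit = fit_model(BIV_SPEC, small_bivariate_registry, compute_vcov=False)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = FitResult.from_json(path)
        np.testing.assert_array_equal(back.theta, fit.theta)
        assert back.bic == fit.bic and back.param_names == fit.param_names


class TestCovarianceRecovery:
    @pytest.mark.parametrize("cov_true", [-0.2, 0.0, 0.3])
    def test_bivariate_correlated_covariance_recovered(self, cov_true):
        cfg = GeneratorConfig(
            n_mothers=5000,
            births_per_mother=(0.4, 0.4, 0.2),
            covariate_marginals={"anc_visits": {"4+": 0.7, "<4": 0.3}},
            beta_preterm={"intercept": -1.2, "anc_visits:<4": 0.8},
            beta_death={"intercept": -1.5, "anc_visits:<4": 0.5},
            random_structure="correlated",
            D=[[0.6, cov_true], [cov_true, 0.7]],
            seed=int(1000 + 10 * (cov_true + 1)),
        )
        df = simulate_registry(cfg)
        spec = ModelSpec(
            kind="bivariate",
            covariates_preterm=["anc_visits"],
            covariates_death=["anc_visits"],
            random_structure="correlated",
        )
        fit = fit_model(spec, df, compute_vcov=False)
        assert abs(fit.D[0, 1] - cov_true) < 0.1


class TestRobustVariance:
    def test_robust_close_to_model_when_correctly_specified(self):
        cfg = GeneratorConfig(
            n_mothers=5000,
            births_per_mother=(0.5, 0.35, 0.15),
            covariate_marginals={"anc_visits": {"4+": 0.7, "<4": 0.3}},
            beta_preterm={"intercept": -1.5, "anc_visits:<4": 0.8},
            beta_death={"intercept": -2.0, "anc_visits:<4": 0.5},
            random_structure="shared",
            sigma2=0.5,
            seed=17,
        )
        df = simulate_registry(cfg)
        spec = ModelSpec(
            kind="bivariate",
            covariates_preterm=["anc_visits"],
            covariates_death=["anc_visits"],
            random_structure="shared",
        )
        fit = fit_model(spec, df, robust=True)
        n_beta = sum(ModelFrame(df, spec).n_beta)
        rel = np.abs(fit.se("robust")[:n_beta] / fit.se("model")[:n_beta] - 1.0)
        assert rel.max() < 0.10

        # inject extra within-mother dependence the model cannot absorb:
        # duplicating every delivery doubles the information the model-based
        # variance claims, while the sandwich sees the dependence
        dup = pd.concat([df, df.assign(birth_index=df["birth_index"] + 10)], ignore_index=True)
        fit_dup = fit_model(spec, dup, robust=True)
        rel_dup = fit_dup.se("robust")[:n_beta] / fit_dup.se("model")[:n_beta]
        assert rel_dup.min() > 1.25  # ~ sqrt(2) inflation expected
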