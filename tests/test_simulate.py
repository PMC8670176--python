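import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from perijoint.simulate import (
    GeneratorConfig,
    default_config,
    simulate_registry,
    theoretical_marginal_prevalence,
)

from .oracles import trapezoid_expectation


def _flat_config(**kw):
    base = dict(
        n_mothers=5000,
        births_per_mother=(0.5, 0.5),
        beta_preterm={"intercept": 0.0},
        beta_death={"intercept": 0.0},
        random_structure="shared",
        sigma2=0.0,
        seed=123,
    )
    base.update(kw)
    return GeneratorConfig(**base)


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        cfg = default_config(seed=5)
        a, b = simulate_registry(cfg), simulate_registry(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = simulate_registry(default_config(seed=5))
        b = simulate_registry(default_config(seed=6))
        assert not a.equals(b)


class TestMarginalPrevalence:
    def test_null_model_gives_half(self):
        df = simulate_registry(_flat_config())
        assert len(df) >= 5000
        for col in ("preterm", "perinatal_death"):
            p = df[col].mean()
            se = 0.5 / np.sqrt(len(df))
            assert abs(p - 0.5) < 4 * se

    def test_random_intercept_prevalence_matches_quadrature(self):
        # logit^-1 marginalised over N(0, 1): empirical vs 200-point rule
        cfg = _flat_config(
            n_mothers=50_000,
            births_per_mother=(1.0,),
            beta_preterm={"intercept": -2.0},
            sigma2=1.0,
            seed=77,
        )
        df = simulate_registry(cfg)
        target = theoretical_marginal_prevalence(-2.0, 1.0)
        mc_se = np.sqrt(target * (1 - target) / len(df))
        assert abs(df["preterm"].mean() - target) < 3 * mc_se


class TestTheoreticalPrevalence:
    def test_degenerate_integral(self):
        assert theoretical_marginal_prevalence(0.0, 0.0) == pytest.approx(0.5)

    def test_zero_variance_closed_form(self):
        assert theoretical_marginal_prevalence(-2.0, 0.0) == pytest.approx(0.1192, abs=5e-5)

    def test_matches_trapezoid_oracle(self):
        got = theoretical_marginal_prevalence(-2.0, 1.0)
        want = trapezoid_expectation(lambda b: expit(-2.0 + b), sd=1.0, lo=-8, hi=8)
        assert got == pytest.approx(want, abs=1e-8)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            theoretical_marginal_prevalence(0.0, -0.1)


def _within_mother_or(df: pd.DataFrame) -> float:
    t = pd.crosstab(df["preterm"], df["perinatal_death"])
    return (t.loc[1, 1] * t.loc[0, 0]) / (t.loc[1, 0] * t.loc[0, 1])


class TestCorrelationStructure:
    def test_odds_ratio_monotone_in_random_effect_covariance(self):
        ors = []
        for cov in (-0.2, 0.0, 0.3):
            cfg = _flat_config(
                n_mothers=40_000,
                births_per_mother=(1.0,),
                beta_preterm={"intercept": -1.0},
                beta_death={"intercept": -1.0},
                random_structure="correlated",
                sigma2=0.0,
                seed=31,
            )
            cfg.D = [[0.5, cov], [cov, 0.5]]
            ors.append(_within_mother_or(simulate_registry(cfg)))
        assert ors[0] < ors[1] < ors[2]
        assert ors[2] > 1.0
        assert ors[1] == pytest.approx(1.0, abs=0.12)  # diagonal D: no association

    def test_missingness_gives_unequal_denominators(self):
        cfg = _flat_config(n_mothers=5000, missing_preterm=0.12, missing_death=0.003, seed=2)
        df = simulate_registry(cfg)
        n_pt, n_dt = df["preterm"].notna().sum(), df["perinatal_death"].notna().sum()
        assert n_pt < n_dt
        assert n_pt / len(df) == pytest.approx(0.88, abs=0.02)


class TestCovariateMarginals:
    def test_chi_square_goodness_of_fit_not_rejected(self):
        marg = {"anc_visits": {"4+": 0.69, "<4": 0.31},
                "maternal_education": {"higher": 0.3, "none": 0.05, "primary": 0.5, "secondary": 0.15}}
        cfg = _flat_config(n_mothers=50_000, births_per_mother=(1.0,),
                           covariate_marginals=marg, seed=13)
        df = simulate_registry(cfg)
        for cov, probs in marg.items():
            counts = df[cov].value_counts()
            obs = np.array([counts.get(c, 0) for c in probs])
            exp = np.array(list(probs.values())) * len(df)
            _, p = stats.chisquare(obs, exp)
            assert p > 0.001

    def test_adding_covariate_keeps_outcomes_fixed(self):
        base = _flat_config(covariate_marginals={"anc_visits": {"4+": 0.7, "<4": 0.3}})
        more = _flat_config(covariate_marginals={"anc_visits": {"4+": 0.7, "<4": 0.3},
                                                 "child_sex": {"female": 0.5, "male": 0.5}})
        a, b = simulate_registry(base), simulate_registry(more)
        np.testing.assert_array_equal(a["preterm"], b["preterm"])
        np.testing.assert_array_equal(a["anc_visits"], b["anc_visits"])


class TestConfig:
    def test_probability_vector_validated(self):
        with pytest.raises(ValueError, match="births_per_mother"):
            GeneratorConfig(births_per_mother=(0.5, 0.4)).validate()

    def test_invalid_covariance_rejected(self):
        cfg = _flat_config(random_structure="correlated")
        cfg.D = [[1.0, 2.0], [2.0, 1.0]]  # not PSD
        with pytest.raises(ValueError, match="positive semi-definite"):
            cfg.validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = default_config(seed=4)
        path = tmp_path / "cfg.yaml"
        cfg.to_file(path)
        back = GeneratorConfig.from_file(path)
        assert back.as_dict() == cfg.as_dict()

    def test_multinomial_mode_requires_betas(self):
        with pytest.raises(ValueError, match="beta_multinomial"):
            _flat_config(outcome_model="multinomial").validate()

    def test_multinomial_categories_match_coding(self, small_multinomial_registry):
        df = small_multinomial_registry
        # category coding: 1 = both, 2 = death only, 3 = preterm only
        both = df[df["cooccurrence"] == 1]
        assert (both["preterm"] == 1).all() and (both["perinatal_death"] == 1).all()
        d_only = df[df["cooccurrence"] == 2]
        assert (d_only["preterm"] == 0).all() and (d_only["perinatal_death"] == 1).all()
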