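"""Synthetic mother-clustered birth-registry generator.

Emulates the data-generating process the joint models assume: each mother
carries a latent normal random intercept (a shared scalar, or a correlated
vector with one component per linear predictor), delivers 1..K singleton
babies across a span of calendar years, and each delivery's outcomes are
drawn from logistic models on the mother's covariates, a linear
calendar-year trend on the logit scale, and the random effect.

Two outcome models are available:

* ``bivariate`` -- preterm birth and perinatal death drawn as Bernoulli
  variables from two logit predictors (shared or correlated intercepts);
* ``multinomial`` -- the four-category co-occurrence outcome drawn directly
  from a random-effects multinomial logit (reference: neither event), with
  the binary outcomes derived from the category.

Covariates are drawn independently of each other and of the random effect;
the fitted models condition on covariates, so independence suffices for
parameter-recovery testing.  Randomness flows through named substreams
spawned from one seed, keyed by purpose and (for covariates) by a CRC of the
covariate name, so adding a covariate does not reshuffle the outcome draws.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .quadrature import gh_rule
from .schema import CODEBOOKS, decode_cooccurrence, derive_outcomes

__all__ = [
    "GeneratorConfig",
    "default_config",
    "simulate_registry",
    "theoretical_marginal_prevalence",
]

_MULTINOMIAL_CATEGORIES = ("both", "death_only", "preterm_only")  # codes 1, 2, 3


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic registry.

    Coefficients are on the logit scale.  ``beta_*`` maps term names to
    coefficients: ``"intercept"``, ``"year"`` (per year since
    ``year_range[0]``), or ``"<covariate>:<category>"`` for a treatment-coded
    indicator of that category.
    """

    n_mothers: int = 2000
    #: P(K_i = k) for k = 1..len(vector); mean ~1.34 births per mother
    #: matches a registry with 60,840 deliveries from 45,324 mothers.
    births_per_mother: tuple[float, ...] = (0.72, 0.23, 0.04, 0.01)
    year_range: tuple[int, int] = (2000, 2017)
    covariate_marginals: dict[str, dict[str, float]] = field(default_factory=dict)
    beta_preterm: dict[str, float] = field(default_factory=lambda: {"intercept": -2.0})
    beta_death: dict[str, float] = field(default_factory=lambda: {"intercept": -3.1})
    #: "shared" (scalar b_i in both predictors) or "correlated"
    #: (vector b_i ~ N(0, D), one component per predictor).
    random_structure: str = "shared"
    sigma2: float = 0.18
    D: list | None = None  # covariance matrix for the correlated structure
    outcome_model: str = "bivariate"  # or "multinomial"
    beta_multinomial: dict[str, dict[str, float]] | None = None
    missing_preterm: float = 0.0
    missing_death: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.births_per_mother, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("births_per_mother must be a probability vector summing to 1")
        for cov, marg in self.covariate_marginals.items():
            q = np.asarray(list(marg.values()), dtype=float)
            if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-12:
                raise ValueError(f"marginal for {cov!r} must sum to 1")
            if cov in CODEBOOKS:
                bad = set(marg) - set(CODEBOOKS[cov])
                if bad:
                    raise ValueError(f"unknown categories {sorted(bad)} for {cov!r}")
        if self.random_structure not in ("shared", "correlated"):
            raise ValueError(f"unknown random_structure {self.random_structure!r}")
        if self.random_structure == "shared":
            if self.sigma2 < 0:
                raise ValueError("sigma2 must be >= 0")
        else:
            d = self.d_matrix()
            if not np.allclose(d, d.T):
                raise ValueError("D must be symmetric")
            ev = np.linalg.eigvalsh(d)
            if ev.min() < -1e-10:
                raise ValueError("D must be positive semi-definite")
        if self.outcome_model not in ("bivariate", "multinomial"):
            raise ValueError(f"unknown outcome_model {self.outcome_model!r}")
        if self.outcome_model == "multinomial":
            if self.beta_multinomial is None:
                raise ValueError("multinomial outcome model requires beta_multinomial")
            bad = set(self.beta_multinomial) - set(_MULTINOMIAL_CATEGORIES)
            if bad:
                raise ValueError(f"beta_multinomial keys must be {_MULTINOMIAL_CATEGORIES}")

    def d_matrix(self) -> np.ndarray:
        """Random-effects covariance as a matrix (dimension 2 or 3)."""
        if self.random_structure == "shared":
            return np.array([[self.sigma2]])
        if self.D is None:
            raise ValueError("correlated structure requires D")
        return np.asarray(self.D, dtype=float)

    # -- serialisation ----------------------------------------------------
    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "GeneratorConfig":
        cfg = cls(**payload)
        if isinstance(cfg.births_per_mother, list):
            cfg.births_per_mother = tuple(cfg.births_per_mother)
        if isinstance(cfg.year_range, list):
            cfg.year_range = tuple(cfg.year_range)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        text = open(path).read()
        payload = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(payload)

    def to_file(self, path) -> None:
        payload = self.as_dict()
        with open(path, "w") as fh:
            if str(path).endswith(".json"):
                json.dump(payload, fh, indent=2, default=list)
            else:
                yaml.safe_dump(payload, fh, sort_keys=False)


def default_config(seed: int = 0) -> GeneratorConfig:
    """A registry-like preset: covariate marginals loosely matching a large
    East-African referral-hospital cohort and effect directions echoing the
    fitted joint models (strong adverse ANC<4 effect on preterm, rising
    preterm / falling death year trends).  The coefficient values are a
    plausible preset, not estimates from any real data."""
    marginals = {
        "maternal_age": {"25-29": 0.28, "15-19": 0.07, "20-24": 0.22, "30-34": 0.22, "35-39": 0.15, "40+": 0.06},
        "maternal_education": {"higher": 0.31, "none": 0.02, "primary": 0.53, "secondary": 0.14},
        "residence": {"urban": 0.59, "rural": 0.41},
        "anc_visits": {"4+": 0.69, "<4": 0.31},
        "parity": {"multipara": 0.19, "primipara": 0.81},
        "referral": {"no": 0.76, "yes": 0.24},
        "preeclampsia": {"no": 0.96, "yes": 0.04},
        "child_sex": {"female": 0.48, "male": 0.52},
    }
    beta_preterm = {
        "intercept": -2.9,
        "year": 0.04,
        "maternal_age:15-19": 0.22,
        "maternal_age:40+": 0.20,
        "maternal_education:primary": 0.25,
        "residence:rural": -0.09,
        "anc_visits:<4": 1.07,
        "referral:yes": 0.28,
        "preeclampsia:yes": 0.58,
        "child_sex:male": 0.11,
    }
    beta_death = {
        "intercept": -2.55,
        "year": -0.03,
        "maternal_age:15-19": -0.84,
        "anc_visits:<4": 0.23,
        "referral:yes": 0.31,
        "parity:primipara": -0.37,
        "preeclampsia:yes": 0.05,
        "child_sex:male": -0.19,
    }
    return GeneratorConfig(
        n_mothers=45324 // 10,
        covariate_marginals=marginals,
        beta_preterm=beta_preterm,
        beta_death=beta_death,
        random_structure="shared",
        sigma2=0.18,
        missing_preterm=0.12,
        missing_death=0.003,
        seed=seed,
    )


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Named substream: fixed spawn keys keep draws stable across config edits."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _covariate_stream(seed: int, name: str) -> np.random.Generator:
    return _stream(seed, 100, zlib.crc32(name.encode()))


def _linear_predictor(beta: dict, cov: pd.DataFrame, year_offset: np.ndarray) -> np.ndarray:
    eta = np.full(len(cov), beta.get("intercept", 0.0), dtype=float)
    eta += beta.get("year", 0.0) * year_offset
    for term, coef in beta.items():
        if term in ("intercept", "year"):
            continue
        name, _, cat = term.partition(":")
        if name not in cov.columns:
            raise ValueError(f"coefficient {term!r} refers to undrawn covariate {name!r}")
        eta += coef * (cov[name].to_numpy() == cat)
    return eta


def simulate_registry(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic registry; byte-identical output for identical config."""
    config.validate()
    seed = config.seed
    n_m = config.n_mothers

    k = 1 + _stream(seed, 0).choice(
        len(config.births_per_mother), size=n_m, p=np.asarray(config.births_per_mother, float)
    )
    n_rows = int(k.sum())
    mother_row = np.repeat(np.arange(n_m), k)
    birth_index = np.concatenate([np.arange(1, ki + 1) for ki in k])

    # mother-level random effects
    d = config.d_matrix()
    dim = d.shape[0]
    if config.random_structure == "shared":
        b = _stream(seed, 1).normal(0.0, np.sqrt(config.sigma2), size=(n_m, 1))
    else:
        chol = np.linalg.cholesky(d + 1e-12 * np.eye(dim))
        b = _stream(seed, 1).standard_normal((n_m, dim)) @ chol.T

    y0, y1 = config.year_range
    year = _stream(seed, 2).integers(y0, y1 + 1, size=n_rows)
    year_offset = (year - y0).astype(float)

    cov = pd.DataFrame(index=np.arange(n_rows))
    for name in sorted(config.covariate_marginals):
        marg = config.covariate_marginals[name]
        cats = list(marg.keys())
        cov[name] = _covariate_stream(seed, name).choice(
            cats, size=n_rows, p=np.asarray(list(marg.values()), float)
        )

    rng_out = _stream(seed, 3)
    if config.outcome_model == "bivariate":
        eta_p = _linear_predictor(config.beta_preterm, cov, year_offset)
        eta_d = _linear_predictor(config.beta_death, cov, year_offset)
        if config.random_structure == "shared":
            eta_p = eta_p + b[mother_row, 0]
            eta_d = eta_d + b[mother_row, 0]
        else:
            eta_p = eta_p + b[mother_row, 0]
            eta_d = eta_d + b[mother_row, 1]
        preterm = (rng_out.random(n_rows) < _expit(eta_p)).astype(float)
        death = (rng_out.random(n_rows) < _expit(eta_d)).astype(float)
    else:
        eta = np.zeros((n_rows, 3))
        for c_idx, cat in enumerate(_MULTINOMIAL_CATEGORIES):
            eta[:, c_idx] = _linear_predictor(config.beta_multinomial[cat], cov, year_offset)
            if config.random_structure == "shared":
                eta[:, c_idx] += b[mother_row, 0]
            else:
                eta[:, c_idx] += b[mother_row, c_idx]
        # categorical draw with reference category 0 (eta identically 0)
        full = np.column_stack([np.zeros(n_rows), eta])
        full -= full.max(axis=1, keepdims=True)
        probs = np.exp(full)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng_out.random(n_rows)
        code = (u[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1)
        pt_dt = np.array([decode_cooccurrence(c) for c in code], dtype=float)
        preterm, death = pt_dt[:, 0], pt_dt[:, 1]

    # gestational age consistent with the preterm indicator
    rng_ga = _stream(seed, 5)
    ga = np.where(
        preterm == 1,
        rng_ga.uniform(28.0, 36.9, size=n_rows),
        rng_ga.uniform(37.0, 42.0, size=n_rows),
    ).round(1)

    rng_miss = _stream(seed, 4)
    ga = np.where(rng_miss.random(n_rows) < config.missing_preterm, np.nan, ga)
    death = np.where(rng_miss.random(n_rows) < config.missing_death, np.nan, death)

    df = pd.DataFrame(
        {
            "mother_id": np.char.add("m", mother_row.astype(str)),
            "birth_index": birth_index,
            "year": year,
            "gestational_age_weeks": ga,
            "perinatal_death": death,
            "plurality": "singleton",
        }
    )
    for name in cov.columns:
        df[name] = cov[name].to_numpy()
    return derive_outcomes(df)


def true_parameters(config: GeneratorConfig) -> dict:
    """Sidecar description of the generating parameters, for recovery tests."""
    config.validate()
    return {
        "outcome_model": config.outcome_model,
        "random_structure": config.random_structure,
        "sigma2": config.sigma2 if config.random_structure == "shared" else None,
        "D": None if config.random_structure == "shared" else np.asarray(config.D).tolist(),
        "beta_preterm": dict(config.beta_preterm),
        "beta_death": dict(config.beta_death),
        "beta_multinomial": config.beta_multinomial,
        "year_origin": config.year_range[0],
    }


def theoretical_marginal_prevalence(intercept: float, variance: float, n_points: int = 200) -> float:
    """Population prevalence ``int expit(intercept + b) dN(b; 0, variance)``.

    Computed by high-order Gauss-Hermite quadrature; reduces to
    ``expit(intercept)`` at zero variance.  Used to calibrate generator
    intercepts against target marginal prevalences.
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if variance == 0:
        return float(_expit(intercept))
    rule = gh_rule(n_points)
    z = rule.std_nodes[:, 0]
    return float(rule.weights @ _expit(intercept + np.sqrt(variance) * z))
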