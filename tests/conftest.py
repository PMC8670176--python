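import numpy as np
import pandas as pd
import pytest

from perijoint.simulate import GeneratorConfig, simulate_registry


@pytest.fixture(scope="session")
def small_bivariate_registry() -> pd.DataFrame:
    """~500 mothers, shared random intercept, two binary covariates."""
    cfg = GeneratorConfig(
        n_mothers=500,
        births_per_mother=(0.5, 0.35, 0.15),
        covariate_marginals={
            "anc_visits": {"4+": 0.7, "<4": 0.3},
            "parity": {"multipara": 0.4, "primipara": 0.6},
        },
        beta_preterm={"intercept": -1.5, "anc_visits:<4": 0.8, "parity:primipara": 0.3},
        beta_death={"intercept": -2.0, "anc_visits:<4": 0.5},
        random_structure="shared",
        sigma2=0.5,
        seed=42,
    )
    return simulate_registry(cfg)


@pytest.fixture(scope="session")
def small_multinomial_registry() -> pd.DataFrame:
    """~500 mothers with the co-occurrence outcome drawn from the shared
    random-effects multinomial model."""
    cfg = GeneratorConfig(
        n_mothers=500,
        births_per_mother=(0.5, 0.35, 0.15),
        covariate_marginals={"anc_visits": {"4+": 0.7, "<4": 0.3}},
        outcome_model="multinomial",
        beta_multinomial={
            "both": {"intercept": -2.5, "anc_visits:<4": 1.2},
            "death_only": {"intercept": -2.2, "anc_visits:<4": 0.3},
            "preterm_only": {"intercept": -1.8, "anc_visits:<4": 0.8},
        },
        random_structure="shared",
        sigma2=0.3,
        seed=11,
    )
    return simulate_registry(cfg)


@pytest.fixture()
def toy_records() -> pd.DataFrame:
    """Ten deliveries: 2 missing mother ids, 3 multiple gestations, 5 eligible."""
    rows = []
    for i in range(10):
        rows.append(
            {
                "mother_id": "" if i < 2 else f"m{i}",
                "birth_index": 1,
                "year": 2010,
                "gestational_age_weeks": 38.0,
                "perinatal_death": 0.0,
                "plurality": "multiple" if 2 <= i < 5 else "singleton",
            }
        )
    return pd.DataFrame(rows)
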