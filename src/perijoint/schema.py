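"""Delivery-level data model for a mother-linked birth registry.

One row per singleton delivery, keyed by an opaque ``mother_id`` and a
``birth_index`` giving the order of the delivery within the mother.  The two
primary outcomes are preterm birth (gestational age < 37 completed weeks)
and perinatal death (stillbirth after 7 months' gestation or death within
the first 7 days of life); a four-category co-occurrence outcome combines
them with "neither event" as reference.

Categorical covariates are validated against explicit code books: unknown
category strings are errors, never silently coerced, because registry
dialects drift.  Two maternal-age partitions are supported -- a descriptive
binning with a pooled 25-34 group and a model binning splitting it into
25-29 (the modelling reference) and 30-34.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "CODEBOOKS",
    "AGE_BINNINGS",
    "COOCCURRENCE_LABELS",
    "GA_WINDOW",
    "encode_preterm",
    "encode_cooccurrence",
    "decode_cooccurrence",
    "derive_outcomes",
    "validate_registry",
    "apply_eligibility",
    "ExclusionTally",
    "load_registry",
    "write_registry",
]


class SchemaError(ValueError):
    """Raised when registry data violates the declared schema."""


#: Plausibility window for gestational age at delivery, in completed weeks.
#: Values outside are rejected at load rather than truncated.
GA_WINDOW = (20.0, 45.0)

#: Maternal-age partitions. "model" is the default because it is the
#: partition the joint models report against (reference 25-29).
AGE_BINNINGS = {
    "model": ("25-29", "15-19", "20-24", "30-34", "35-39", "40+"),
    "descriptive": ("25-34", "15-19", "20-24", "35-39", "40+"),
}

# First category of each tuple is the default reference level.
CODEBOOKS: dict[str, tuple[str, ...]] = {
    "maternal_age": AGE_BINNINGS["model"],
    "maternal_education": ("higher", "none", "primary", "secondary"),
    "maternal_occupation": ("employed", "unemployed", "farmer", "others"),
    "marital_status": ("married", "single", "widowed/divorced"),
    "residence": ("urban", "rural"),
    "bmi": ("normal", "underweight", "overweight", "obese"),
    "paternal_age": ("25-29", "15-24", "30-34", "35+"),
    "paternal_education": ("higher", "none", "primary", "secondary"),
    "paternal_occupation": ("employed", "unemployed", "farmer", "others"),
    "anc_visits": ("4+", "<4"),
    "parity": ("multipara", "primipara"),
    "referral": ("no", "yes"),
    "hiv": ("negative", "positive"),
    "anemia": ("no", "yes"),
    "malaria": ("no", "yes"),
    "infection": ("no", "yes"),
    "preeclampsia": ("no", "yes"),
    "prom": ("no", "yes"),
    "pph": ("no", "yes"),
    "abruption_placenta": ("no", "yes"),
    "placenta_previa": ("no", "yes"),
    "child_sex": ("female", "male"),
    "birth_weight": ("nbw", "lbw"),
    "presentation": ("cephalic", "breech", "transverse"),
    "delivery_mode": ("vaginal", "cs"),
    "apgar5": ("high", "low"),
    "induced_labor": ("no", "yes"),
}

PLURALITY_VALUES = ("singleton", "multiple", "unknown")

#: Co-occurrence coding: 0 neither, 1 both, 2 death only, 3 preterm only.
COOCCURRENCE_LABELS = {0: "neither", 1: "both", 2: "death_only", 3: "preterm_only"}

REQUIRED_COLUMNS = ("mother_id", "birth_index", "year", "gestational_age_weeks", "perinatal_death")


def encode_preterm(gestational_age_weeks):
    """Binary preterm indicator: 1 if < 37 completed weeks, 0 if >= 37.

    Missing input (None/NaN) propagates to missing (NaN).  A value outside
    the plausibility window ``GA_WINDOW`` raises :class:`SchemaError`.
    """
    w = gestational_age_weeks
    if w is None or (isinstance(w, float) and np.isnan(w)):
        return np.nan
    w = float(w)
    lo, hi = GA_WINDOW
    if not (lo <= w <= hi):
        raise SchemaError(
            f"gestational age {w} weeks outside plausibility window [{lo}, {hi}]"
        )
    return 1 if w < 37.0 else 0


def encode_cooccurrence(preterm, death):
    """Four-category co-occurrence code from the two binary outcomes.

    0 = neither event, 1 = both, 2 = perinatal death only, 3 = preterm birth
    only.  Missing in either component propagates; non-binary input raises.
    """
    vals = []
    for name, v in (("preterm", preterm), ("death", death)):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        iv = int(v)
        if iv != v or iv not in (0, 1):
            raise SchemaError(f"{name} must be 0/1 or missing, got {v!r}")
        vals.append(iv)
    p, d = vals
    return {(0, 0): 0, (1, 1): 1, (0, 1): 2, (1, 0): 3}[(p, d)]


def decode_cooccurrence(code):
    """Inverse of :func:`encode_cooccurrence`: code -> (preterm, death)."""
    if code is None or (isinstance(code, float) and np.isnan(code)):
        return (np.nan, np.nan)
    mapping = {0: (0, 0), 1: (1, 1), 2: (0, 1), 3: (1, 0)}
    try:
        return mapping[int(code)]
    except KeyError:
        raise SchemaError(f"co-occurrence code must be in 0..3, got {code!r}") from None


def _encode_preterm_column(ga: pd.Series) -> pd.Series:
    ga = pd.to_numeric(ga, errors="coerce")
    bad = ga.notna() & ((ga < GA_WINDOW[0]) | (ga > GA_WINDOW[1]))
    if bad.any():
        idx = list(ga.index[bad][:5])
        raise SchemaError(
            f"gestational age outside plausibility window {GA_WINDOW} "
            f"in records at index {idx}"
        )
    out = pd.Series(np.where(ga < 37.0, 1.0, 0.0), index=ga.index)
    out[ga.isna()] = np.nan
    return out


def derive_outcomes(df: pd.DataFrame) -> pd.DataFrame:
    """Add ``preterm`` and ``cooccurrence`` columns derived from the raw fields."""
    out = df.copy()
    out["preterm"] = _encode_preterm_column(out["gestational_age_weeks"])
    death = pd.to_numeric(out["perinatal_death"], errors="coerce")
    co = np.full(len(out), np.nan)
    both = out["preterm"].notna() & death.notna()
    p = out["preterm"][both].to_numpy(int)
    d = death[both].to_numpy(int)
    if both.any() and (np.any((p != 0) & (p != 1)) or np.any((d != 0) & (d != 1))):
        raise SchemaError("perinatal_death/preterm must be binary where observed")
    co[both.to_numpy()] = np.select(
        [(p == 0) & (d == 0), (p == 1) & (d == 1), (p == 0) & (d == 1)], [0, 1, 2], 3
    )
    out["cooccurrence"] = co
    return out


def validate_registry(df: pd.DataFrame) -> None:
    """Validate column presence, codebook membership and birth-index contiguity."""
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required columns: {missing_cols}")
    for cov, categories in CODEBOOKS.items():
        if cov not in df.columns:
            continue
        col = df[cov]
        observed = col[col.notna() & (col != "")]
        allowed = set(categories)
        if cov == "maternal_age":
            allowed |= set(AGE_BINNINGS["descriptive"])
        bad = set(observed.unique()) - allowed
        if bad:
            raise SchemaError(f"unknown categories {sorted(bad)} for covariate {cov!r}")
    if "plurality" in df.columns:
        pl = df["plurality"]
        bad = set(pl[pl.notna() & (pl != "")].unique()) - set(PLURALITY_VALUES)
        if bad:
            raise SchemaError(f"unknown plurality values {sorted(bad)}")
    # birth_index unique and contiguous from 1 within each mother
    with_id = df[df["mother_id"].notna() & (df["mother_id"].astype(str) != "")]
    if len(with_id):
        k = pd.to_numeric(with_id["birth_index"], errors="raise")
        grouped = k.groupby(with_id["mother_id"])
        ok = grouped.agg(lambda s: sorted(s) == list(range(1, len(s) + 1)))
        if not ok.all():
            bad_ids = list(ok.index[~ok][:5])
            raise SchemaError(f"birth_index not contiguous from 1 for mothers {bad_ids}")
    # gestational age window (raises on violation)
    _encode_preterm_column(df["gestational_age_weeks"])


@dataclass
class ExclusionTally:
    """Counts removed at each eligibility step, mirroring the cohort flow chart."""

    total: int
    missing_mother_id: int
    multiple_gestation: int
    unknown_plurality: int
    kept: int

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "missing_mother_id": self.missing_mother_id,
            "multiple_gestation": self.multiple_gestation,
            "unknown_plurality": self.unknown_plurality,
            "kept": self.kept,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def apply_eligibility(df: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionTally]:
    """Apply the cohort eligibility filters in order, preserving row order.

    Removes (1) records missing a mother identifier, (2) multiple
    gestations, (3) records of unknown plurality; returns the surviving
    records and a tally of removals at each step.
    """
    total = len(df)
    mid = df["mother_id"]
    has_id = mid.notna() & (mid.astype(str).str.strip() != "")
    n_noid = int((~has_id).sum())
    df1 = df[has_id]
    if "plurality" in df.columns:
        pl = df1["plurality"].fillna("")
        is_multiple = pl == "multiple"
        n_mult = int(is_multiple.sum())
        df2 = df1[~is_multiple]
        is_unknown = df2["plurality"].fillna("").isin(("unknown", ""))
        n_unk = int(is_unknown.sum())
        kept = df2[~is_unknown]
    else:
        n_mult = n_unk = 0
        kept = df1
    tally = ExclusionTally(
        total=total,
        missing_mother_id=n_noid,
        multiple_gestation=n_mult,
        unknown_plurality=n_unk,
        kept=len(kept),
    )
    return kept.copy(), tally


def load_registry(path, validate: bool = True, derive: bool = True) -> pd.DataFrame:
    """Read a registry CSV (empty string = missing) and derive outcome columns."""
    df = pd.read_csv(path, dtype={"mother_id": str}, keep_default_na=True, na_values=[""])
    if validate:
        validate_registry(df)
    if derive:
        df = derive_outcomes(df)
    return df


def write_registry(df: pd.DataFrame, path) -> None:
    """Write a registry CSV with empty strings for missing values."""
    out = df.drop(columns=[c for c in ("preterm", "cooccurrence") if c in df.columns])
    out.to_csv(path, index=False, na_rep="")
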