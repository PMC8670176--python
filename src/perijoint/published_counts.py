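"""Published summary counts from the KCMC birth-registry cohort (2000-2017).

The record-level registry is restricted, but the published descriptive
tables print raw cell counts: per-stratum totals and event counts for
preterm birth (complete gestational-age information, N = 49,113) and
perinatal death (complete perinatal status, N = 55,736), plus the cohort
flow (60,840 recorded deliveries, of which 52 lacked a mother identifier,
3,669 were multiple gestations and 1,212 of unknown plurality, leaving
55,907 analysed singleton deliveries).

These cells let every published descriptive statistic be *recomputed* from
counts: :func:`expand_counts` rebuilds a record-level frame with exactly the
printed cross-tabulation, so the descriptive layer runs on it unchanged.
Covariate cross-correlations are of course not recoverable from margins;
the expansion is per-stratifier.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ELIGIBILITY_FLOW", "TABLE_CELLS", "expand_counts", "eligibility_records"]

#: Cohort flow: total recorded deliveries and exclusions, in filter order.
ELIGIBILITY_FLOW = {
    "total": 60_840,
    "missing_mother_id": 52,
    "multiple_gestation": 3_669,
    "unknown_plurality": 1_212,
}

#: (stratifier, outcome) -> {category: (total, events)}.  ``outcome`` is
#: "preterm" (denominator 49,113) or "death" (denominator 55,736).
TABLE_CELLS: dict[tuple[str, str], dict[str, tuple[int, int]]] = {
    ("anc_visits", "preterm"): {"4+": (33_291, 2_488), "<4": (15_087, 3_581)},
    ("anc_visits", "death"): {"4+": (37_619, 1_111), "<4": (17_198, 1_161)},
    ("birth_weight", "preterm"): {"nbw": (43_619, 3_313), "lbw": (5_373, 2_889)},
    ("birth_weight", "death"): {"nbw": (49_596, 1_190), "lbw": (6_008, 1_148)},
    ("abruption_placenta", "preterm"): {"no": (48_950, 6_180), "yes": (163, 83)},
    ("abruption_placenta", "death"): {"no": (55_552, 2_275), "yes": (184, 102)},
    ("apgar5", "preterm"): {"high": (46_015, 4_981), "low": (2_543, 1_068)},
    ("apgar5", "death"): {"high": (52_117, 161), "low": (3_006, 1_817)},
    # overall totals, as a single-stratum table
    ("overall", "preterm"): {"all": (49_113, 6_263)},
    ("overall", "death"): {"all": (55_736, 2_377)},
}


def expand_counts(stratifier: str, outcome: str) -> pd.DataFrame:
    """Record-level frame reproducing the printed (stratum x outcome) cells.

    Emits one row per delivery with the stratifier category and the outcome
    columns the descriptive layer expects (``preterm`` derived via a
    gestational age consistent with the indicator; ``perinatal_death``
    direct).  Records outside this table's complete-case denominator are not
    represented -- exactly the complete-case behaviour of the published
    tables.
    """
    try:
        cells = TABLE_CELLS[(stratifier, outcome)]
    except KeyError:
        raise KeyError(
            f"no published cells for ({stratifier!r}, {outcome!r}); "
            f"available: {sorted(TABLE_CELLS)}"
        ) from None
    cats, ga, death = [], [], []
    for cat, (total, events) in cells.items():
        cats += [cat] * total
        flags = np.r_[np.ones(events), np.zeros(total - events)]
        if outcome == "preterm":
            ga.append(np.where(flags == 1, 34.0, 39.0))
            death.append(np.full(total, np.nan))
        else:
            ga.append(np.full(total, np.nan))
            death.append(flags)
    n = len(cats)
    df = pd.DataFrame(
        {
            "mother_id": [f"m{i}" for i in range(n)],
            "birth_index": 1,
            "year": 2008,
            "gestational_age_weeks": np.concatenate(ga),
            "perinatal_death": np.concatenate(death),
            stratifier if stratifier != "overall" else "overall": cats,
        }
    )
    df["preterm"] = np.where(
        df["gestational_age_weeks"].notna(),
        (df["gestational_age_weeks"] < 37.0).astype(float),
        np.nan,
    )
    df["cooccurrence"] = np.nan
    return df


def eligibility_records() -> pd.DataFrame:
    """Skeleton frame reproducing the published cohort flow for the filters."""
    flow = ELIGIBILITY_FLOW
    n = flow["total"]
    n_noid = flow["missing_mother_id"]
    n_mult = flow["multiple_gestation"]
    n_unk = flow["unknown_plurality"]
    mother_id = np.array([""] * n_noid + [f"m{i}" for i in range(n - n_noid)], dtype=object)
    plurality = np.array(
        ["singleton"] * n_noid
        + ["multiple"] * n_mult
        + ["unknown"] * n_unk
        + ["singleton"] * (n - n_noid - n_mult - n_unk),
        dtype=object,
    )
    return pd.DataFrame(
        {
            "mother_id": mother_id,
            "birth_index": 1,
            "year": 2008,
            "gestational_age_weeks": np.nan,
            "perinatal_death": np.nan,
            "plurality": plurality,
        }
    )
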