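"""Descriptive layer: stratified proportion tables and annual trends.

The chi-square tests deliberately ignore mother-level clustering, matching
standard registry descriptive practice; within-mother dependence is handled
by the model layer.  Annual trends regress the unweighted per-year outcome
percentage on calendar year by ordinary least squares, so the slope reads as
percentage points per year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["ProportionTable", "TrendResult", "proportion_table", "annual_trend", "perinatal_mortality_rate"]

_OUTCOME_COLUMNS = {"preterm": "preterm", "death": "perinatal_death", "perinatal_death": "perinatal_death"}


@dataclass
class ProportionTable:
    """Stratified event proportions with a Pearson chi-square test."""

    stratifier: str
    outcome: str
    rows: pd.DataFrame  # category, total, column_pct, events, event_pct
    chi2: float
    df: int
    p_value: float
    total_n: int
    total_events: int

    @property
    def total_event_pct(self) -> float:
        return 100.0 * self.total_events / self.total_n if self.total_n else float("nan")

    def render(self, decimals: int = 1) -> str:
        lines = [f"{self.stratifier} vs {self.outcome}"]
        for _, r in self.rows.iterrows():
            lines.append(
                f"  {r['category']:<18} {int(r['total']):>8,} ({r['column_pct']:.{decimals}f})"
                f"  {int(r['events']):>7,} ({r['event_pct']:.{decimals}f})"
            )
        lines.append(
            f"  {'Total':<18} {self.total_n:>8,}          {self.total_events:>7,}"
            f" ({self.total_event_pct:.{decimals}f})"
        )
        lines.append(f"  chi2={self.chi2:.3f}, df={self.df}, p={self.p_value:.3g}")
        return "\n".join(lines)


@dataclass
class TrendResult:
    """OLS linear trend of annual outcome percentages."""

    outcome: str
    years: np.ndarray
    pct: np.ndarray
    slope: float  # percentage points per calendar year
    se: float
    ci_low: float
    ci_high: float
    p_value: float


def _outcome_column(outcome: str) -> str:
    try:
        return _OUTCOME_COLUMNS[outcome]
    except KeyError:
        raise ValueError(
            f"unknown outcome {outcome!r}; expected one of {sorted(set(_OUTCOME_COLUMNS))}"
        ) from None


def proportion_table(
    records: pd.DataFrame,
    stratifier: str,
    outcome: str,
    continuity_correction: bool = False,
) -> ProportionTable:
    """Event counts and proportions by stratum with a Pearson chi-square test.

    Complete-case within the outcome: rows with a missing outcome are
    excluded from this table only.  Strata with zero total are reported but
    dropped from the test.  Category order follows first appearance unless
    the column is an ordered categorical.
    """
    if stratifier not in records.columns:
        available = [c for c in records.columns if records[c].dtype == object]
        raise ValueError(f"unknown stratifier {stratifier!r}; available: {available}")
    col = _outcome_column(outcome)
    if col not in records.columns:
        raise ValueError(f"outcome column {col!r} missing; derive outcomes first")
    y = pd.to_numeric(records[col], errors="coerce")
    mask = y.notna() & records[stratifier].notna() & (records[stratifier].astype(str) != "")
    sub = records.loc[mask, [stratifier]].assign(_y=y[mask].astype(int))

    if isinstance(sub[stratifier].dtype, pd.CategoricalDtype):
        categories = [c for c in sub[stratifier].cat.categories]
    else:
        categories = list(dict.fromkeys(sub[stratifier]))
    grouped = sub.groupby(stratifier, sort=False, observed=True)["_y"]
    totals = grouped.size().reindex(categories, fill_value=0)
    events = grouped.sum().reindex(categories, fill_value=0).astype(int)
    n, n_events = int(totals.sum()), int(events.sum())
    rows = pd.DataFrame(
        {
            "category": categories,
            "total": totals.to_numpy(),
            "column_pct": 100.0 * totals.to_numpy() / n if n else np.nan,
            "events": events.to_numpy(),
            "event_pct": np.where(
                totals.to_numpy() > 0, 100.0 * events.to_numpy() / np.maximum(totals.to_numpy(), 1), 0.0
            ),
        }
    )
    nonzero = rows["total"] > 0
    table = np.column_stack(
        [rows.loc[nonzero, "events"], rows.loc[nonzero, "total"] - rows.loc[nonzero, "events"]]
    )
    if table.shape[0] >= 2 and table.sum(axis=0).min() > 0:
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=continuity_correction)
    else:  # degenerate: one stratum, or no events/non-events at all
        chi2, p, dof = 0.0, 1.0, max(int(nonzero.sum()) - 1, 0)
    return ProportionTable(
        stratifier=stratifier,
        outcome=outcome,
        rows=rows,
        chi2=float(chi2),
        df=int(dof),
        p_value=float(p),
        total_n=n,
        total_events=n_events,
    )


def perinatal_mortality_rate(records: pd.DataFrame) -> float:
    """Perinatal deaths per 1,000 births among records with known status."""
    y = pd.to_numeric(records["perinatal_death"], errors="coerce").dropna()
    if not len(y):
        return float("nan")
    return 1000.0 * float(y.mean())


def annual_trend(records: pd.DataFrame, outcome: str) -> TrendResult:
    """OLS regression of the annual outcome percentage on calendar year.

    Each year contributes one (year, percentage) point; the slope is in
    percentage points per one-year increase, with a normal-theory 95% CI.
    """
    col = _outcome_column(outcome)
    y = pd.to_numeric(records[col], errors="coerce")
    mask = y.notna()
    per_year = y[mask].groupby(records.loc[mask, "year"]).mean() * 100.0
    per_year = per_year[per_year.index.notna()]
    if len(per_year) < 3:
        raise ValueError(f"need >= 3 distinct years with data, got {len(per_year)}")
    years = per_year.index.to_numpy(dtype=float)
    pct = per_year.to_numpy(dtype=float)
    x = sm.add_constant(years)
    fit = sm.OLS(pct, x).fit()
    slope, se = float(fit.params[1]), float(fit.bse[1])
    scale = max(1.0, float(np.abs(pct).max()))
    if abs(slope) < 1e-10 * scale:  # numerically flat series
        slope = 0.0
    if se <= 1e-10 * scale:
        p = 1.0 if slope == 0.0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(slope / se)))
    half = 1.96 * se
    return TrendResult(
        outcome=outcome,
        years=years,
        pct=pct,
        slope=slope,
        se=se,
        ci_low=slope - half,
        ci_high=slope + half,
        p_value=p,
    )
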