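"""Post-fit inference tables and BIC model comparison.

Odds ratios are ``exp(beta)`` with Wald confidence intervals on the log
scale; the critical value is fixed at z = 1.959964 and printed intervals are
rounded to two decimals, mirroring standard epidemiological table style.
Model comparison uses BIC = -2 loglik + p log N with N the number of
delivery records in the fit; ties break to the first model in input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import FitResult

__all__ = ["Z_CRIT", "odds_ratio_table", "compare_models", "ComparisonReport", "render_fit"]

Z_CRIT = 1.959964


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def odds_ratio_table(fit: FitResult, vcov: str = "model", force: bool = False) -> pd.DataFrame:
    """Odds ratios, Wald 95% CIs, p-values and significance stars.

    Covers the fixed-effect terms only (variance parameters are reported on
    their own scale by :func:`render_fit`).  Refuses a non-converged fit
    unless ``force=True``.
    """
    if not fit.converged and not force:
        raise ValueError("fit did not converge; pass force=True to tabulate anyway")
    se = fit.se(vcov)
    rows = []
    for name, est, s in zip(fit.param_names, fit.theta, se):
        if name.startswith(("log_sd", "atanh_rho", "chol[", "log_chol[")):
            continue
        if s > 0:
            z = est / s
            p = float(2.0 * stats.norm.sf(abs(z)))
        else:
            z, p = 0.0, 1.0
        rows.append(
            {
                "term": name,
                "estimate": est,
                "se": s,
                "or": float(np.exp(est)),
                "ci_low": float(np.exp(est - Z_CRIT * s)),
                "ci_high": float(np.exp(est + Z_CRIT * s)),
                "p_value": p,
                "stars": _stars(p),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """Per-model BIC table with the minimum-BIC model flagged."""

    table: pd.DataFrame  # name, loglik, n_params, bic, delta_bic, preferred
    preferred: str

    def render(self) -> str:
        lines = [f"{'model':<28}{'loglik':>14}{'p':>5}{'BIC':>14}{'dBIC':>10}"]
        for _, r in self.table.iterrows():
            flag = " <- preferred" if r["preferred"] else ""
            lines.append(
                f"{r['name']:<28}{r['loglik']:>14.2f}{int(r['n_params']):>5}"
                f"{r['bic']:>14.2f}{r['delta_bic']:>10.2f}{flag}"
            )
        return "\n".join(lines)


def compare_models(fits: list, names: list | None = None) -> ComparisonReport:
    """Compare >= 2 fits of the same records by BIC (smaller is better).

    Fits must share the record-count fingerprint (same number of mothers and
    of delivery records); mismatched sets raise.  The first model in input
    order wins exact ties.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    fp = {(f.n_records, f.n_mothers) for f in fits}
    if len(fp) > 1:
        raise ValueError(f"fits are not on the same record set: fingerprints {sorted(fp)}")
    if names is None:
        names = [f"{f.model}/{f.random_structure}" for f in fits]
    bics = np.asarray([f.bic for f in fits], dtype=float)
    best = int(np.argmin(bics))  # argmin takes the first minimum: stable tie-break
    table = pd.DataFrame(
        {
            "name": names,
            "loglik": [f.loglik for f in fits],
            "n_params": [f.n_params for f in fits],
            "bic": bics,
            "delta_bic": bics - bics[best],
            "preferred": [i == best for i in range(len(fits))],
        }
    )
    return ComparisonReport(table=table, preferred=names[best])


def render_fit(fit: FitResult, vcov: str = "model", force: bool = False) -> str:
    """Aligned-text table of ORs with 95% CIs and significance stars."""
    tab = odds_ratio_table(fit, vcov=vcov, force=force)
    lines = [
        f"{fit.model} model, {fit.random_structure} random effects "
        f"({fit.n_mothers:,} mothers, {fit.n_records:,} deliveries)",
        f"{'term':<36}{'OR (95% CI)':>26}{'p':>10}",
    ]
    for _, r in tab.iterrows():
        ci = f"{r['or']:.2f} ({r['ci_low']:.2f}, {r['ci_high']:.2f}){r['stars']}"
        lines.append(f"{r['term']:<36}{ci:>26}{r['p_value']:>10.3g}")
    d = fit.D
    if d.shape[0] == 1:
        lines.append(f"Variance of the random effects: {d[0, 0]:.3f}")
    else:
        for i in range(d.shape[0]):
            lines.append(f"Variance component {i + 1}: {d[i, i]:.3f}")
        for i in range(d.shape[0]):
            for j in range(i):
                lines.append(f"Covariance ({j + 1},{i + 1}): {d[i, j]:.3f}")
    lines.append(f"log-likelihood {fit.loglik:.2f}, BIC {fit.bic:.2f}")
    return "\n".join(lines)
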