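"""Descriptive layer on the synthetic registry.

Stratified proportion tables with chi-square tests for a handful of key
exposures, overall prevalences and PMR, and the annual OLS trend of both
outcomes.  Expects results/registry.csv from 01_simulate_registry.py.
"""

import pathlib

import pandas as pd

from perijoint.descriptives import annual_trend, perinatal_mortality_rate, proportion_table
from perijoint.schema import load_registry

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    df = load_registry(OUT / "registry.csv")
    print(
        f"overall: preterm {100 * df['preterm'].mean():.1f}% "
        f"(N={int(df['preterm'].notna().sum()):,}), "
        f"perinatal death {100 * df['perinatal_death'].mean():.1f}% "
        f"(N={int(df['perinatal_death'].notna().sum()):,}), "
        f"PMR {perinatal_mortality_rate(df):.1f}/1,000"
    )
    tables = []
    for stratifier in ("anc_visits", "maternal_education", "referral", "preeclampsia"):
        for outcome in ("preterm", "death"):
            tab = proportion_table(df, stratifier, outcome)
            print()
            print(tab.render())
            rows = tab.rows.assign(stratifier=stratifier, outcome=outcome,
                                   chi2=tab.chi2, df=tab.df, p_value=tab.p_value)
            tables.append(rows)
    pd.concat(tables, ignore_index=True).to_csv(OUT / "proportion_tables.csv", index=False)

    print()
    trends = []
    for outcome in ("preterm", "death"):
        tr = annual_trend(df, outcome)
        print(
            f"{outcome} trend: {tr.slope:+.2f} percentage points/year "
            f"(95% CI {tr.ci_low:.2f}, {tr.ci_high:.2f}; p={tr.p_value:.3g})"
        )
        trends.append({"outcome": outcome, "slope": tr.slope, "se": tr.se,
                       "ci_low": tr.ci_low, "ci_high": tr.ci_high, "p_value": tr.p_value})
    pd.DataFrame(trends).to_csv(OUT / "annual_trends.csv", index=False)


if __name__ == "__main__":
    main()
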