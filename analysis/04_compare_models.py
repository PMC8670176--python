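"""BIC comparison of the fitted joint-model variants.

Reads the FitResult JSONs written by 03_fit_joint_models.py and prints the
comparison table, flagging the minimum-BIC model.  Bivariate and multinomial
fits are compared within their own outcome definitions (their record sets
and likelihood scales differ).
"""

import pathlib

from perijoint.models import FitResult
from perijoint.reporting import compare_models

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for family in ("bivariate", "multinomial"):
        fits, names = [], []
        for structure in ("shared", "correlated"):
            path = OUT / f"fit_{family}_{structure}.json"
            if path.exists():
                fits.append(FitResult.from_json(path))
                names.append(f"{family}/{structure}")
        if len(fits) < 2:
            print(f"{family}: need both fits, run 03_fit_joint_models.py first")
            continue
        report = compare_models(fits, names=names)
        print(report.render())
        report.table.to_csv(OUT / f"bic_comparison_{family}.csv", index=False)
        print()


if __name__ == "__main__":
    main()
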