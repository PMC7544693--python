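"""Fit the per-cohort mixed-effect trajectory models.

For each severity cohort: log-transform, test the quadratic time term,
run the single outlier pass, and report the fitted equation with variance
components and information criteria.  Writes results/cohort_models.csv.
"""

import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).parent))
from study_setup import make_filtered_study

from adprogress import COHORT_ORDER, fit_cohort

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main():
    records, _ = make_filtered_study()
    rows = []
    for cohort in COHORT_ORDER:
        sub = records[records["cohort"] == cohort]
        model, report, p_quad = fit_cohort(sub)
        rows.append({
            "cohort": cohort,
            "n_patients": model.n_patients, "n_obs": model.n_obs,
            "beta0": model.beta0, "beta1": model.beta1, "beta2": model.beta2,
            "sigma_b": model.sigma_b, "sigma_e": model.sigma_e,
            "quadratic_p": p_quad,
            "quadratic_kept": model.has_quadratic,
            "outliers_removed": len(report.removed_obs_ids),
            "aic_before": report.ic_before[0], "aic_after": report.ic_after[0],
            "bic_after": report.ic_after[1], "aicc_after": report.ic_after[2],
        })
        print(f"{cohort}: {model.equation()}")
        print(f"  quadratic p={p_quad:.3g} "
              f"({'kept' if model.has_quadratic else 'dropped'}); "
              f"{len(report.removed_obs_ids)} outlier obs removed; "
              f"AIC {report.ic_before[0]:.1f} -> {report.ic_after[0]:.1f}")
    (ROOT / "results").mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(ROOT / "results" / "cohort_models.csv", index=False)


if __name__ == "__main__":
    main()
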