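#!/usr/bin/env python
"""Score the TLS signature and test its prognostic value.

Computes the six immune-population scores, dichotomizes the B-lineage
(TLS) score at the top quartile, tabulates clinical characteristics per
TLS group, and tests the TLS-PFS association by Kaplan-Meier/log-rank and
a multivariable Cox model adjusted for age, stage and residual disease —
the synthetic analogue of the cohort's survival analysis (the planted
truth is HR = 0.55 per score SD).
"""

import json
from pathlib import Path

import pandas as pd

from tlskit import (
    cox_fit,
    dichotomize_scores,
    km_estimate,
    load_default_marker_db,
    logrank_test,
    mcp_score,
    score_all_populations,
)
from tlskit.io import cohort_table, read_clinical, read_matrix
from tlskit.scoring import TLS_POPULATION

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "tls_survival"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    expr = read_matrix(BASE / "cohort" / "expression.tsv")
    clinical = read_clinical(BASE / "cohort" / "clinical.csv")
    db = load_default_marker_db()
    tls_markers = next(m for m in db if m.name == TLS_POPULATION)

    scores = mcp_score(expr, tls_markers)
    labels = dichotomize_scores(scores, high_quantile=0.75)
    pops = score_all_populations(expr, db)
    pd.DataFrame({"score": scores, "tls_label": labels}).to_csv(
        OUT / "tls_scores.tsv", sep="\t", index_label="sample_id")
    pops.to_csv(OUT / "population_scores.tsv", sep="\t", index_label="sample_id")

    agreement = (labels == clinical["tls_label"]).mean()
    print(f"TLS dichotomization: {int(labels.sum())} high / {int((labels == 0).sum())} low "
          f"(agreement with simulated truth {agreement:.0%})")

    clin = clinical.copy()
    clin["age_band"] = (clin["age_years"] >= 70).map({False: "<70", True: ">=70"})
    clin["relapse"] = clin["event"].map({1: "yes", 0: "no"})
    tab = cohort_table(clin, labels, categorical=["age_band", "stage",
                                                  "residual_disease", "relapse"])
    tab.to_csv(OUT / "cohort_table.tsv", sep="\t")

    chi2, p = logrank_test(clin["time_months"], clin["event"], labels)
    km = {g: km_estimate(clin.loc[labels == g, "time_months"],
                         clin.loc[labels == g, "event"])
          for g in (0, 1)}
    print(f"KM median PFS: TLS-low {km[0].median:.1f} vs TLS-high {km[1].median:.1f} months")
    print(f"log-rank: chi2 = {chi2:.2f}, p = {p:.3g}")

    z = (scores - scores.mean()) / scores.std(ddof=0)
    fit = cox_fit(clin.assign(tls=z.to_numpy()),
                  ["tls", "age_years", "stage", "residual_disease"])
    row = fit.summary().loc["tls"]
    print(f"multivariable Cox (TLS per SD): HR = {row.hr:.2f} "
          f"(95% CI {row.ci_low:.2f}-{row.ci_high:.2f}, p = {row.p:.3g}) "
          f"[planted HR 0.55]")
    with open(OUT / "survival.json", "w") as fh:
        json.dump({
            "logrank_chi2": chi2, "logrank_p": p,
            "km_median": {str(g): r.median for g, r in km.items()},
            "cox": fit.summary().to_dict(orient="index"),
        }, fh, indent=2, sort_keys=True)
    print(f"wrote tls_scores.tsv, population_scores.tsv, cohort_table.tsv, survival.json -> {OUT}")


if __name__ == "__main__":
    main()
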