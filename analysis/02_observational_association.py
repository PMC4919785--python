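"""Derive eGFR and quantify its observational association with CHD.

Serum creatinine is converted to eGFR with the MDRD equation, subjects are
banded into the clinical <60 / 60-90 / >=90 ml/min/1.73m² categories, and
CHD risk is regressed on eGFR (study-adjusted logistic), overall and by
eGFR quintile.
"""

import pandas as pd

from common import load_cohort, outdir
from egfr_mr.mr import observational_association


def main():
    _, cohort = load_cohort()
    phen = cohort.phenotypes
    with_egfr = phen[phen["egfr"].notna()]

    bands = with_egfr["egfr_category"].value_counts().sort_index()
    print("eGFR category distribution (subjects with creatinine):")
    print(bands.to_string())

    res = observational_association(phen)
    print(
        f"\nObservational association: OR = {res.or_:.3f} per ml/min/1.73m² "
        f"(95% CI {res.ci95[0]:.3f}-{res.ci95[1]:.3f}, p = {res.p:.2e}, n = {res.n})"
    )
    res10 = observational_association(phen, per_units=10.0)
    print(f"Per 10 ml/min/1.73m²: OR = {res10.or_:.3f}")

    q = pd.qcut(with_egfr["egfr"], 5)
    quintiles = with_egfr.groupby(q, observed=True)["chd"].agg(["size", "mean"])
    quintiles.columns = ["n", "chd_rate"]
    print("\nCHD rate by eGFR quintile (lowest kidney function first):")
    print(quintiles.round(3).to_string())

    out = outdir()
    tab = pd.DataFrame(
        {
            "model": ["per_1_unit", "per_10_units"],
            "or": [res.or_, res10.or_],
            "ci_low": [res.ci95[0], res10.ci95[0]],
            "ci_high": [res.ci95[1], res10.ci95[1]],
            "p": [res.p, res10.p],
            "n": [res.n, res10.n],
        }
    )
    tab.to_csv(out / "02_observational_or.csv", index=False)
    quintiles.reset_index().to_csv(out / "02_chd_by_quintile.csv", index=False)
    print(f"\nWrote {out / '02_observational_or.csv'} and {out / '02_chd_by_quintile.csv'}")


if __name__ == "__main__":
    main()
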