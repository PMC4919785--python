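"""Screen the trait panel for confounders and test the MR assumptions.

Runs the dual trait scan (eGFR-trait and CHD-trait associations, BH FDR at
0.05 within each family), intersects the rejections into a candidate
confounder set (excluding renally cleared pathway markers and single-study
traits), checks the score-trait scan for pleiotropy, calibrates the FDR
procedure by within-study permutation, and re-fits the observational
eGFR-CHD association adjusted for the identified confounders.
"""

import json

import pandas as pd

from common import load_cohort, outdir
from egfr_mr.score import build_score, estimate_weights
from egfr_mr.screen import (
    adjusted_observational,
    identify_confounders,
    permutation_fdr_check,
    trait_scan,
)


def main():
    cfg, cohort = load_cohort()
    phen = cohort.phenotypes
    traits = [t.name for t in cfg.trait_spec]
    study_counts = {
        t.name: (len(t.studies) if t.studies is not None else len(cfg.study_names))
        for t in cfg.trait_spec
    }

    exposure_scan = trait_scan(phen, "egfr", traits)
    outcome_scan = trait_scan(phen, "chd", traits)
    conf = identify_confounders(
        exposure_scan,
        outcome_scan,
        pathway_markers=("ntprobnp",),
        min_study_coverage=2,
        trait_study_counts=study_counts,
    )
    print(f"Traits scanned: {len(traits)}")
    print(f"eGFR-associated: {int(exposure_scan['rejected'].sum())}; "
          f"CHD-associated: {int(outcome_scan['rejected'].sum())}")
    print(f"Potential confounders ({len(conf.confounders)}): {', '.join(conf.confounders)}")
    for name, reason in conf.exclusions:
        print(f"  excluded {name}: {reason}")

    # third assumption: the gene scores should associate with nothing
    # beyond kidney function
    weights = estimate_weights(cohort.genotypes, cohort.snps, phen)
    score_scans = {}
    for kind in ("unweighted", "weighted"):
        score = build_score(cohort.genotypes, cohort.snps, weights, kind,
                            study=phen["study"])
        scan = trait_scan(phen, score, traits)
        score_scans[kind] = scan
        hits = scan.loc[scan["rejected"], "name"].tolist()
        print(f"{kind} score-trait rejections: {hits if hits else 'none'}")

    perm = permutation_fdr_check(
        phen, "egfr", traits, n_permutations=200, seed=cfg.seed
    )
    print(
        f"Permutation calibration: P(any BH rejection under the null) = "
        f"{perm['p_any_rejection']:.3f} (MC SE {perm['mc_se']:.3f})"
    )

    adj = adjusted_observational(phen, conf.confounders, per_units=10.0)
    print(
        f"Adjusted observational OR per 10 ml/min/1.73m² = {adj.or_:.3f} "
        f"(95% CI {adj.ci95[0]:.3f}-{adj.ci95[1]:.3f}, p = {adj.p:.3g}, "
        f"complete cases n = {adj.n})"
    )

    out = outdir()
    scans = pd.concat(
        [exposure_scan, outcome_scan, score_scans["unweighted"], score_scans["weighted"]],
        ignore_index=True,
    )
    scans.to_csv(out / "04_trait_scans.tsv", sep="\t", index=False)
    with open(out / "04_confounders.json", "w") as fh:
        json.dump(
            {
                "confounders": conf.confounders,
                "exclusions": conf.exclusions,
                "adjusted_or_per_10": adj.or_,
                "adjusted_ci95": adj.ci95,
                "adjusted_p": adj.p,
                "permutation_p_any_rejection": perm["p_any_rejection"],
            },
            fh,
            indent=2,
        )
    print(f"\nWrote {out / '04_trait_scans.tsv'} and {out / '04_confounders.json'}")


if __name__ == "__main__":
    main()
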