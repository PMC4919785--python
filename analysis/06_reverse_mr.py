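"""Reverse MR: does CHD liability causally affect kidney function?

A weighted score of 51 genome-wide significant CHD SNPs (synthetic
published log odds ratios as weights) is tested against eGFR: the cohort
supplies per-SNP eGFR regression coefficients, which are pooled with the
CHD weights by the same estimator with the roles swapped.  The generator
contains no CHD→eGFR arrow, so the truth here is a null effect.
"""

import json

import numpy as np
import pandas as pd

from common import STUDY_SEED, outdir, study_config
from egfr_mr.config import SnpSpec
from egfr_mr.mr import reverse_mr
from egfr_mr.phenotypes import add_egfr
from egfr_mr.score import estimate_weights
from egfr_mr.simulate import generate_cohort


def main():
    rng = np.random.default_rng(STUDY_SEED + 7)
    n_snps = 51
    chd_snps = [
        SnpSpec(id=f"chd_rs{k:02d}", freq=float(rng.uniform(0.1, 0.9)), egfr_effect=0.0)
        for k in range(n_snps)
    ]
    cfg = study_config().model_copy(
        update={"snps": chd_snps, "target_score_r2": None}
    )
    cohort = generate_cohort(cfg)
    cohort.phenotypes = add_egfr(cohort.phenotypes)

    # cohort-side per-SNP eGFR associations act as the outcome statistics
    w = estimate_weights(cohort.genotypes, cohort.snps, cohort.phenotypes)
    egfr_summary = pd.DataFrame(
        {
            "snp_id": w.index,
            "effect_allele": cohort.snps["effect_allele"].values,
            "other_allele": cohort.snps["other_allele"].values,
            "beta": w["beta_counted"].values,
            "se": w["se_w"].values,
            "n_cases": 0,
            "n_controls": 0,
            "source": "cohort",
        }
    )
    # synthetic published CHD log odds ratios for the instrument SNPs
    chd_weights = pd.DataFrame(
        {
            "increasing_allele": cohort.snps["effect_allele"].values,
            "other_allele": cohort.snps["other_allele"].values,
            "w": rng.uniform(0.05, 0.25, n_snps),
            "se_w": rng.uniform(0.01, 0.03, n_snps),
        },
        index=w.index,
    )

    est = reverse_mr(chd_weights, egfr_summary)
    print(
        f"Reverse MR (CHD score on eGFR): beta = {est.beta_hat:.3f} "
        f"ml/min/1.73m² per score unit (95% CI {est.ci95[0]:.3f} to "
        f"{est.ci95[1]:.3f}, p = {est.p:.3f}, {est.n_snps_used} SNPs)"
    )
    verdict = "no evidence of reverse causation" if est.p > 0.05 else "signal detected"
    print(f"Conclusion under the generative null: {verdict}.")

    out = outdir()
    with open(out / "06_reverse_mr.json", "w") as fh:
        json.dump(
            {
                "beta": est.beta_hat,
                "se": est.se,
                "ci95": est.ci95,
                "p": est.p,
                "n_snps": est.n_snps_used,
            },
            fh,
            indent=2,
        )
    print(f"Wrote {out / '06_reverse_mr.json'}")


if __name__ == "__main__":
    main()
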