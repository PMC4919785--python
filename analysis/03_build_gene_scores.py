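"""Estimate per-SNP weights, build both gene scores, assess instrument strength.

Per-SNP weights come from study-adjusted linear regressions of eGFR on
allele count; each SNP is oriented to its eGFR-increasing allele.  The
unweighted score counts increasing alleles, the weighted score multiplies
them by the regression slopes, and both are checked for instrument
strength (partial R² and F in the study-adjusted eGFR regression).
"""

import pandas as pd

from common import load_cohort, outdir
from egfr_mr.io import write_weights
from egfr_mr.score import build_score, estimate_weights, instrument_strength


def main():
    _, cohort = load_cohort()
    weights = estimate_weights(cohort.genotypes, cohort.snps, cohort.phenotypes)
    print("Per-SNP oriented weights (eGFR units per increasing allele):")
    print(weights[["increasing_allele", "w", "se_w", "n"]].round(3).to_string())
    smallest = weights["w"].idxmin()
    print(f"\nSmallest weight: {smallest} (w = {weights.at[smallest, 'w']:.3f})")

    rows = []
    for kind in ("unweighted", "weighted"):
        score = build_score(
            cohort.genotypes, cohort.snps, weights, kind,
            study=cohort.phenotypes["study"],
        )
        st = instrument_strength(score, cohort.phenotypes)
        rows.append(dict(score=kind, r_squared=st.r_squared,
                         f_statistic=st.f_statistic, n=st.n_used))
        print(
            f"{kind:>10} score: partial R² = {st.r_squared:.4f}, "
            f"F = {st.f_statistic:.1f} (n = {st.n_used})"
        )
    strength = pd.DataFrame(rows)

    out = outdir()
    write_weights(weights, out / "03_weights.tsv")
    strength.to_csv(out / "03_instrument_strength.csv", index=False)
    print(f"\nWrote {out / '03_weights.tsv'} and {out / '03_instrument_strength.csv'}")


if __name__ == "__main__":
    main()
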