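"""Gene-score construction and instrument-strength diagnostics.

Per-SNP instrument weights are slopes from linear regressions of eGFR on
allele count (additive coding) adjusted for study as a categorical
covariate.  Each SNP is oriented so its *exposure-increasing* allele is
counted: the unweighted score is the plain count of eGFR-increasing alleles
summed over SNPs; the weighted score multiplies each oriented count by the
oriented (non-negative) regression slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._linalg import ols_fit, study_dummies

WEIGHT_COLUMNS = [
    "increasing_allele",
    "other_allele",
    "w",
    "se_w",
    "beta_counted",
    "n",
    "source",
    "flag",
]


@dataclass
class InstrumentStrength:
    """Partial R² of the score in a study-adjusted eGFR regression and the
    corresponding single-predictor F statistic (= t²)."""

    r_squared: float
    f_statistic: float
    n_used: int


def estimate_weights(
    genotypes: pd.DataFrame,
    snps: pd.DataFrame,
    phenotypes: pd.DataFrame,
    outcome: str = "egfr",
) -> pd.DataFrame:
    """Per-SNP exposure regressions and allele orientation.

    For each SNP: OLS of ``outcome`` on the counted-allele dosage with study
    as a categorical covariate (complete cases for that SNP).  The slope's
    sign picks the exposure-increasing allele; ``w`` is the slope on the
    oriented (non-negative) scale, ``beta_counted`` the raw slope per
    counted allele.  Monomorphic SNPs are flagged ``monomorphic`` and get
    missing weights; an exactly zero slope is oriented to the
    alphabetically first allele and flagged ``zero_weight_tiebreak``.

    Returns a frame indexed by snp_id with columns {}.
    """.format(WEIGHT_COLUMNS)
    if outcome not in phenotypes:
        raise KeyError(f"phenotype column {outcome!r} not found")
    y_all = phenotypes[outcome].to_numpy(dtype=float)
    if np.all(np.isnan(y_all)):
        raise ValueError(f"all values of {outcome!r} are missing")
    study = phenotypes["study"].to_numpy()
    base_X, _ = study_dummies(study)

    rows = []
    for sid in genotypes.columns:
        g = genotypes[sid].to_numpy(dtype=float)
        mask = ~np.isnan(g) & ~np.isnan(y_all)
        eff = snps.loc[sid, "effect_allele"]
        oth = snps.loc[sid, "other_allele"]
        n = int(mask.sum())
        if n < 2 or np.nanstd(g[mask]) == 0.0:
            warnings.warn(f"SNP {sid} monomorphic or unusable; weight undefined")
            rows.append(
                dict(
                    snp_id=sid, increasing_allele=eff, other_allele=oth,
                    w=np.nan, se_w=np.nan, beta_counted=np.nan, n=n,
                    source="internal_regression", flag="monomorphic",
                )
            )
            continue
        Xs = base_X[mask]
        # drop all-constant dummy columns within the complete-case subset
        keep = np.concatenate([[True], Xs[:, 1:].std(axis=0) > 0])
        X = np.column_stack([Xs[:, keep], g[mask]])
        coef, se, _ = ols_fit(X, y_all[mask])
        slope, s = float(coef[-1]), float(se[-1])
        if slope > 0:
            inc, other, w, flag = eff, oth, slope, ""
        elif slope < 0:
            inc, other, w, flag = oth, eff, -slope, ""
        else:
            inc, other = sorted([eff, oth])
            w, flag = 0.0, "zero_weight_tiebreak"
        rows.append(
            dict(
                snp_id=sid, increasing_allele=inc, other_allele=other,
                w=w, se_w=s, beta_counted=slope, n=n,
                source="internal_regression", flag=flag,
            )
        )
    return pd.DataFrame(rows).set_index("snp_id")


def orient_from_external(weights: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Replace internal orientations by an external direction catalog.

    ``catalog`` carries ``snp_id`` and ``increasing_allele`` columns (larger
    external studies often resolve direction more reliably than the cohort
    itself).  For catalogued SNPs whose external increasing allele is the
    internal *other* allele, the orientation is flipped (the oriented weight
    changes sign); uncatalogued SNPs keep the internal orientation.  A
    catalog allele matching neither allele flags the SNP ``allele_mismatch``
    and leaves it unchanged.
    """
    out = weights.copy()
    cat = catalog.set_index("snp_id")["increasing_allele"]
    for sid, allele in cat.items():
        if sid not in out.index:
            continue
        inc = out.at[sid, "increasing_allele"]
        oth = out.at[sid, "other_allele"]
        if allele == inc:
            out.at[sid, "source"] = "external_catalog"
        elif allele == oth:
            out.at[sid, "increasing_allele"] = oth
            out.at[sid, "other_allele"] = inc
            out.at[sid, "w"] = -out.at[sid, "w"]
            out.at[sid, "beta_counted"] = out.at[sid, "beta_counted"]
            out.at[sid, "source"] = "external_catalog"
        else:
            warnings.warn(
                f"catalog allele {allele!r} for {sid} matches neither "
                f"{inc!r} nor {oth!r}; possible strand/label error"
            )
            out.at[sid, "flag"] = "allele_mismatch"
    return out


def oriented_dosage(
    genotypes: pd.DataFrame,
    snps: pd.DataFrame,
    weights: pd.DataFrame,
    study: pd.Series | None = None,
) -> pd.DataFrame:
    """Allele counts of each SNP's increasing allele, with missing genotypes
    mean-imputed from the SNP's non-missing counts within study."""
    cols = {}
    for sid in weights.index:
        g = genotypes[sid].astype(float)
        if g.isna().any():
            if study is not None:
                fill = g.groupby(study.to_numpy()).transform("mean")
            else:
                fill = pd.Series(g.mean(), index=g.index)
            g = g.fillna(fill)
        if weights.at[sid, "increasing_allele"] != snps.at[sid, "effect_allele"]:
            g = 2.0 - g
        cols[sid] = g
    return pd.DataFrame(cols)


def build_score(
    genotypes: pd.DataFrame,
    snps: pd.DataFrame,
    weights: pd.DataFrame,
    score_type: str = "unweighted",
    study: pd.Series | None = None,
) -> pd.Series:
    """Per-subject gene score.

    ``unweighted``: sum of increasing-allele counts over SNPs with a defined
    orientation; ``weighted``: Σ_j w_j g_ij with the oriented weights.
    Missing genotypes are mean-imputed per SNP (within study when ``study``
    is given); a subject missing every genotype gets a missing score.
    """
    if score_type not in ("unweighted", "weighted"):
        raise ValueError("score_type must be 'unweighted' or 'weighted'")
    usable = weights[weights["w"].notna()]
    if usable.empty:
        raise ValueError("no SNP with a defined weight/orientation")
    dropped = len(weights) - len(usable)
    if dropped:
        warnings.warn(f"excluding {dropped} SNP(s) without defined weights from the score")
    dosage = oriented_dosage(genotypes, snps, usable, study=study)
    if score_type == "unweighted":
        score = dosage.sum(axis=1)
    else:
        score = dosage @ usable["w"]
    all_missing = genotypes[usable.index.tolist()].isna().all(axis=1)
    score[all_missing] = np.nan
    score.name = score_type
    return score


def instrument_strength(score: pd.Series, phenotypes: pd.DataFrame) -> InstrumentStrength:
    """Strength of the score as an instrument for eGFR.

    Study-adjusted OLS of eGFR on the score; reports the score's partial R²
    (t²/(t²+df)) and its F statistic (t² for a single predictor).  Values of
    F well above 10 indicate negligible weak-instrument bias.
    """
    y = phenotypes["egfr"].to_numpy(dtype=float)
    s = score.reindex(phenotypes.index).to_numpy(dtype=float)
    mask = ~np.isnan(y) & ~np.isnan(s)
    if mask.sum() < 3:
        raise ValueError("need at least 3 subjects with score and eGFR")
    if np.std(s[mask]) == 0.0:
        raise ValueError("score has zero variance")
    base_X, _ = study_dummies(phenotypes["study"].to_numpy()[mask])
    keep = np.concatenate([[True], base_X[:, 1:].std(axis=0) > 0])
    X = np.column_stack([base_X[:, keep], s[mask]])
    coef, se, df = ols_fit(X, y[mask])
    if se[-1] == 0.0:  # exact fit (e.g. score == eGFR)
        return InstrumentStrength(r_squared=1.0, f_statistic=np.inf, n_used=int(mask.sum()))
    t2 = (coef[-1] / se[-1]) ** 2
    r2_partial = t2 / (t2 + df)
    return InstrumentStrength(
        r_squared=float(r2_partial), f_statistic=float(t2), n_used=int(mask.sum())
    )
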