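"""Summary-statistic causal estimation and sensitivity analyses.

The causal effect of the exposure on the outcome is estimated from per-SNP
outcome associations (log odds ratios with standard errors) and
predetermined instrument weights by precision-weighted pooling::

    beta_hat = sum_j w_j b_Yj / s_Yj**2  /  sum_j w_j**2 / s_Yj**2
    se       = ( sum_j w_j**2 / s_Yj**2 ) ** -0.5

which is exactly weighted least squares of b_Yj on w_j through the origin
with weights 1/s_Yj² — the allelic-score analogue of the inverse-variance
weighted two-sample MR estimator.  The unweighted-score variant sets every
w_j = 1.  Two-sided p-values compare beta_hat/se to a standard normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .score import estimate_weights
from .screen import OddsRatioResult, _logistic_or

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class MREstimate:
    """Pooled causal estimate on the log-odds (or outcome-beta) scale."""

    beta_hat: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p: float
    n_snps_used: int
    score_type: str
    dropped: list[str] = field(default_factory=list)
    subgroup: Optional[str] = None
    bias_caveat: bool = False


def harmonize(summary: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Align outcome summary statistics to the exposure-increasing alleles.

    For each instrument SNP present in the summary set the outcome effect is
    re-signed so it refers to the exposure-increasing allele; SNPs whose
    summary alleles match neither orientation are excluded with an
    ``allele_mismatch`` note, palindromic (A/T, C/G) SNPs are kept but
    flagged (no frequency-based strand inference is attempted), and
    instrument SNPs absent from the summary set are dropped with a ledger
    entry.  If a SNP appears under several sources the most precise
    (smallest-SE) row is used.

    Returns one row per usable SNP: ``snp_id, beta, se, w, se_w, n_cases,
    n_controls, source, palindromic`` with ``beta`` per increasing allele.
    ``.attrs['ledger']`` records drops and flags.
    """
    ledger: dict[str, list[str]] = {"missing": [], "allele_mismatch": [], "palindromic": []}
    summ = (
        summary.sort_values(["snp_id", "se"], kind="mergesort")
        .groupby("snp_id", sort=False)
        .head(1)
        .set_index("snp_id")
    )
    rows = []
    for sid in weights.index:
        if not np.isfinite(weights.at[sid, "w"]):
            ledger["missing"].append(sid)
            continue
        if sid not in summ.index:
            ledger["missing"].append(sid)
            continue
        row = summ.loc[sid]
        inc = weights.at[sid, "increasing_allele"]
        oth = weights.at[sid, "other_allele"]
        ea, oa = row["effect_allele"], row["other_allele"]
        if frozenset((ea, oa)) in _PALINDROMIC:
            ledger["palindromic"].append(sid)
            warnings.warn(f"SNP {sid} has palindromic alleles {ea}/{oa}; harmonised by label only")
        if ea == inc and oa == oth:
            beta = float(row["beta"])
        elif ea == oth and oa == inc:
            beta = -float(row["beta"])
        else:
            ledger["allele_mismatch"].append(sid)
            warnings.warn(
                f"SNP {sid}: summary alleles {ea}/{oa} do not match instrument "
                f"alleles {inc}/{oth}; excluded"
            )
            continue
        rows.append(
            dict(
                snp_id=sid,
                beta=beta,
                se=float(row["se"]),
                w=float(weights.at[sid, "w"]),
                se_w=float(weights.at[sid, "se_w"]) if "se_w" in weights else np.nan,
                n_cases=row.get("n_cases", np.nan),
                n_controls=row.get("n_controls", np.nan),
                source=row.get("source", ""),
                palindromic=frozenset((ea, oa)) in _PALINDROMIC,
            )
        )
    out = pd.DataFrame(rows)
    if ledger["missing"]:
        warnings.warn(
            f"{len(ledger['missing'])} instrument SNP(s) absent from the summary set: "
            + ", ".join(ledger["missing"])
        )
    out.attrs["ledger"] = ledger
    return out


def johnson_estimate(
    harmonized: pd.DataFrame, unit_weights: bool = False, score_type: Optional[str] = None
) -> MREstimate:
    """Precision-weighted pooled estimate of the causal effect.

    ``unit_weights=True`` gives the unweighted-score estimator (effect per
    additional exposure-increasing allele); otherwise the first-stage
    weights give the effect per unit of exposure as proxied by the weighted
    score.
    """
    if len(harmonized) == 0:
        raise ValueError("no SNPs available for estimation")
    b = harmonized["beta"].to_numpy(dtype=float)
    s = harmonized["se"].to_numpy(dtype=float)
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("all summary standard errors must be positive")
    w = np.ones_like(b) if unit_weights else harmonized["w"].to_numpy(dtype=float)
    denom = float(np.sum(w**2 / s**2))
    if denom == 0.0:
        raise ValueError("all instrument weights are zero; estimate undefined")
    beta_hat = float(np.sum(w * b / s**2)) / denom
    se = denom**-0.5
    z = beta_hat / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    if score_type is None:
        score_type = "unweighted" if unit_weights else "weighted"
    return MREstimate(
        beta_hat=beta_hat,
        se=se,
        or_=float(np.exp(beta_hat)),
        ci95=(float(np.exp(beta_hat - 1.96 * se)), float(np.exp(beta_hat + 1.96 * se))),
        p=p,
        n_snps_used=int(len(b)),
        score_type=score_type,
        dropped=list(harmonized.attrs.get("ledger", {}).get("missing", [])),
    )


def leave_one_out(harmonized: pd.DataFrame, unit_weights: bool = False, alpha: float = 0.05) -> pd.DataFrame:
    """One pooled estimate per excluded SNP.

    Flags exclusions that move the estimate across the significance
    boundary relative to the full-set estimate — the signature of a single
    SNP driving (or masking) the signal.
    """
    if len(harmonized) < 2:
        raise ValueError("leave-one-out needs at least 2 SNPs")
    full = johnson_estimate(harmonized, unit_weights=unit_weights)
    rows = []
    for sid in harmonized["snp_id"]:
        sub = harmonized[harmonized["snp_id"] != sid]
        est = johnson_estimate(sub, unit_weights=unit_weights)
        rows.append(
            dict(
                excluded_snp=sid,
                beta_hat=est.beta_hat,
                se=est.se,
                or_=est.or_,
                ci_low=est.ci95[0],
                ci_high=est.ci95[1],
                p=est.p,
                crosses_significance=(est.p > alpha) != (full.p > alpha),
            )
        )
    return pd.DataFrame(rows)


def exclude_snps(
    harmonized: pd.DataFrame, snp_ids: Sequence[str], unit_weights: bool = False
) -> MREstimate:
    """Pooled estimate after removing named SNPs (e.g. known pleiotropic
    variants).  Unknown ids raise ``KeyError`` naming the offender."""
    present = set(harmonized["snp_id"])
    unknown = [s for s in snp_ids if s not in present]
    if unknown:
        raise KeyError(f"SNP(s) not in harmonized set: {', '.join(unknown)}")
    sub = harmonized[~harmonized["snp_id"].isin(set(snp_ids))]
    est = johnson_estimate(sub, unit_weights=unit_weights)
    est.dropped = est.dropped + list(snp_ids)
    return est


def subgroup_estimate(
    genotypes: pd.DataFrame,
    snps: pd.DataFrame,
    phenotypes: pd.DataFrame,
    summary: pd.DataFrame,
    category: str = "low",
    unit_weights: bool = False,
    min_subjects: int = 200,
) -> MREstimate:
    """Causal estimate restricted to an eGFR category (e.g. ``low`` < 60).

    First-stage weights are re-estimated within the subgroup, then pooled
    against the (unrestricted) outcome summary statistics.  Conditioning on
    the exposure can bias the causal estimate, so the result carries a
    ``bias_caveat`` flag.  ``category='all'`` reproduces the main analysis.
    """
    if category == "all":
        keep = phenotypes.index
    else:
        keep = phenotypes.index[phenotypes["egfr_category"] == category]
    sub_phen = phenotypes.loc[keep]
    n_egfr = int(sub_phen["egfr"].notna().sum())
    if n_egfr < min_subjects:
        raise ValueError(
            f"subgroup {category!r} has only {n_egfr} subjects with eGFR "
            f"(minimum {min_subjects}) — too small for weight regressions"
        )
    w = estimate_weights(genotypes.loc[keep], snps, sub_phen)
    est = johnson_estimate(harmonize(summary, w), unit_weights=unit_weights)
    est.subgroup = category
    est.bias_caveat = category != "all"
    return est


def reverse_mr(chd_weights: pd.DataFrame, egfr_summary: pd.DataFrame) -> MREstimate:
    """Reverse-direction MR: does CHD liability causally lower eGFR?

    The instrument is a weighted score of genome-wide significant CHD SNPs
    (weights = published per-SNP CHD log odds ratios); the 'outcome'
    summary statistics are per-SNP linear regression coefficients of eGFR
    on allele count estimated in the cohort.  The same pooling formula
    applies with the roles swapped; ``beta_hat`` is in eGFR units per unit
    of CHD-log-odds score.
    """
    est = johnson_estimate(harmonize(egfr_summary, chd_weights), score_type="reverse_weighted")
    # a beta for a continuous outcome is not a log OR
    est.or_ = float("nan")
    est.ci95 = (est.beta_hat - 1.96 * est.se, est.beta_hat + 1.96 * est.se)
    return est


def observational_association(
    phenotypes: pd.DataFrame,
    covariates: Sequence[str] = (),
    per_units: float = 1.0,
) -> OddsRatioResult:
    """Observational logistic regression of CHD on eGFR (study-adjusted),
    optionally with covariates such as creatinine and serum urea."""
    return _logistic_or(phenotypes, "egfr", list(covariates), per_units)
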