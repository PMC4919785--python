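"""Phenome-wide confounder / pleiotropy screening with FDR control.

Potential confounders of the eGFR-CHD association are traits associated
with *both* the exposure and the outcome.  Each trait in the panel is
tested against a target (eGFR, CHD status, or a gene score) in a
study-adjusted regression — trait-on-target linear regression for
continuous targets (logistic when the trait is binary, e.g. sex), and
logistic regression of CHD on the trait for the binary outcome target.
P-values are Benjamini-Hochberg adjusted within each scan family, and a
within-study permutation procedure checks that correlation among traits
does not break the FDR guarantee.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._linalg import ols_slope_test, study_dummies

_SCAN_KIND = {"egfr": "exposure_trait", "chd": "outcome_trait", "score": "score_trait"}


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries are ignored (m = number of non-missing p-values) and
    returned as missing.  Values outside [0, 1] raise ``ValueError``.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _logistic_slope(y: np.ndarray, X: np.ndarray):
    """Wald test for the last column of a logistic regression; returns
    (beta, se, p) with p missing on separation/non-convergence."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise PerfectSeparationError
        return float(fit.params[-1]), float(fit.bse[-1]), float(fit.pvalues[-1])
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        return np.nan, np.nan, np.nan


def trait_scan(
    phenotypes: pd.DataFrame,
    target,
    traits: list[str],
    q: float = 0.05,
) -> pd.DataFrame:
    """Scan every trait against a target, with BH adjustment in-family.

    ``target`` is ``"egfr"``, ``"chd"`` or a per-subject score Series
    aligned to ``phenotypes``.  Models are complete-case per trait (trait
    sample sizes vary), adjusted for study.  Zero-variance traits are
    skipped with a warning; separated logistic fits keep their row with a
    missing p.  Output rows are ordered by trait name.
    """
    if isinstance(target, pd.Series):
        tvec = target.reindex(phenotypes.index).to_numpy(dtype=float)
        kind = _SCAN_KIND["score"]
        logistic_target = False
    elif target in ("egfr", "chd"):
        tvec = phenotypes[target].to_numpy(dtype=float)
        kind = _SCAN_KIND[target]
        logistic_target = target == "chd"
    else:
        raise ValueError("target must be 'egfr', 'chd' or a score Series")
    study = phenotypes["study"].to_numpy()

    rows = []
    for name in traits:
        x = phenotypes[name].to_numpy(dtype=float)
        mask = ~np.isnan(x) & ~np.isnan(tvec)
        n = int(mask.sum())
        if n < 3:
            warnings.warn(f"trait {name}: fewer than 3 overlapping observations; skipped")
            continue
        if np.std(x[mask]) == 0.0:
            warnings.warn(f"trait {name}: zero variance; skipped")
            continue
        base, _ = study_dummies(study[mask])
        keep = np.concatenate([[True], base[:, 1:].std(axis=0) > 0])
        base = base[:, keep]
        vals = x[mask]
        binary_trait = np.isin(np.unique(vals), (0.0, 1.0)).all()
        if logistic_target:
            # outcome scan: logistic CHD ~ study + trait
            X = np.column_stack([base, vals])
            beta, se, p = _logistic_slope(tvec[mask], X)
        elif binary_trait:
            # binary trait (e.g. sex) on continuous target: logistic
            X = np.column_stack([base, tvec[mask]])
            beta, se, p = _logistic_slope(vals, X)
        else:
            # continuous trait on continuous target: linear
            X = np.column_stack([base, tvec[mask]])
            beta, se, p = ols_slope_test(X, vals, col=X.shape[1] - 1)
        rows.append(dict(name=name, n=n, beta=beta, se=se, p=p, scan_kind=kind))

    res = pd.DataFrame(rows, columns=["name", "n", "beta", "se", "p", "scan_kind"])
    res = res.sort_values("name", kind="mergesort").reset_index(drop=True)
    res["p_adj"] = bh_adjust(res["p"]) if len(res) else np.nan
    res["rejected"] = res["p_adj"] <= q
    return res[["name", "n", "beta", "se", "p", "p_adj", "rejected", "scan_kind"]]


@dataclass
class ConfounderSet:
    """Traits flagged in both the exposure and outcome scans, with an
    exclusion ledger for traits removed despite a dual signal."""

    confounders: list[str]
    exclusions: list[tuple[str, str]] = field(default_factory=list)


def identify_confounders(
    exposure_scan: pd.DataFrame,
    outcome_scan: pd.DataFrame,
    pathway_markers: tuple[str, ...] = ("ntprobnp",),
    min_study_coverage: int = 2,
    trait_study_counts: dict[str, int] | None = None,
) -> ConfounderSet:
    """Potential confounders = traits rejected in both scans, minus
    documented exclusions.

    Dual association is necessary but not sufficient for confounding:
    renally cleared biomarkers sit on the causal pathway rather than behind
    it and are excluded by name (``pathway_markers``), and traits measured
    in fewer than ``min_study_coverage`` studies are excluded as
    single-study artefacts (requires ``trait_study_counts``).
    """
    exp_rej = set(exposure_scan.loc[exposure_scan["rejected"], "name"])
    out_rej = set(outcome_scan.loc[outcome_scan["rejected"], "name"])
    dual = sorted(exp_rej & out_rej)
    confounders, exclusions = [], []
    for name in dual:
        if name in pathway_markers:
            exclusions.append((name, "renally cleared / on causal pathway"))
        elif (
            trait_study_counts is not None
            and trait_study_counts.get(name, min_study_coverage) < min_study_coverage
        ):
            exclusions.append(
                (name, f"measured in fewer than {min_study_coverage} studies")
            )
        else:
            confounders.append(name)
    return ConfounderSet(confounders=confounders, exclusions=exclusions)


def permutation_fdr_check(
    phenotypes: pd.DataFrame,
    target,
    traits: list[str],
    n_permutations: int = 500,
    seed: int = 0,
    q: float = 0.05,
) -> dict:
    """Empirical calibration of the BH scan under the global null.

    The target vector is permuted within study (preserving study-level
    trait differences while destroying every trait-target association), the
    scan + BH adjustment is re-run per permutation, and the distribution of
    rejection counts is summarised.  Under the FDR guarantee the
    probability of any rejection is at most q up to Monte-Carlo error, even
    for correlated traits.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(target, pd.Series):
        base = target.reindex(phenotypes.index)
    else:
        base = phenotypes[target]
    tvec = base.to_numpy(dtype=float)
    study = phenotypes["study"].to_numpy()
    counts = np.zeros(n_permutations, dtype=int)
    work = phenotypes.copy()
    for b in range(n_permutations):
        perm = tvec.copy()
        for lev in np.unique(study):
            idx = np.flatnonzero(study == lev)
            perm[idx] = perm[idx[rng.permutation(len(idx))]]
        if isinstance(target, pd.Series):
            ptarget: object = pd.Series(perm, index=phenotypes.index)
        else:
            work[target] = perm
            ptarget = target
        scan = trait_scan(work if not isinstance(target, pd.Series) else phenotypes,
                          ptarget, traits, q=q)
        counts[b] = int(scan["rejected"].sum())
    p_any = float((counts > 0).mean())
    mc_se = float(np.sqrt(max(p_any * (1 - p_any), 1e-12) / n_permutations))
    return {
        "rejection_counts": counts,
        "p_any_rejection": p_any,
        "mc_se": mc_se,
        "n_permutations": n_permutations,
        "q": q,
    }


@dataclass
class OddsRatioResult:
    """Logistic-regression odds ratio on a chosen per-unit step."""

    or_: float
    ci95: tuple[float, float]
    p: float
    beta: float
    se: float
    n: int
    per_units: float


def _logistic_or(
    phenotypes: pd.DataFrame,
    exposure: str,
    covariates: list[str],
    per_units: float,
    min_margin: int = 10,
) -> OddsRatioResult:
    cols = [exposure] + list(covariates)
    needed = phenotypes[cols + ["chd", "study"]]
    cc = needed.dropna()
    n = len(cc)
    base, _ = study_dummies(cc["study"].to_numpy())
    keep = np.concatenate([[True], base[:, 1:].std(axis=0) > 0])
    X = np.column_stack(
        [base[:, keep]] + [cc[c].to_numpy(dtype=float) for c in covariates] + [cc[exposure].to_numpy(dtype=float)]
    )
    if n < X.shape[1] + min_margin:
        raise ValueError(
            f"complete-case n={n} too small for {X.shape[1]} parameters "
            f"(need at least {X.shape[1] + min_margin}); check trait missingness"
        )
    beta, se, p = _logistic_slope(cc["chd"].to_numpy(dtype=float), X)
    if np.isnan(beta):
        raise RuntimeError("logistic fit failed (separation or non-convergence)")
    b = beta * per_units
    s = se * per_units
    return OddsRatioResult(
        or_=float(np.exp(b)),
        ci95=(float(np.exp(b - 1.96 * s)), float(np.exp(b + 1.96 * s))),
        p=p,
        beta=b,
        se=s,
        n=n,
        per_units=per_units,
    )


def adjusted_observational(
    phenotypes: pd.DataFrame,
    confounders: list[str],
    per_units: float = 1.0,
) -> OddsRatioResult:
    """Observational CHD-on-eGFR odds ratio adjusted for the identified
    confounders, on complete cases across all of them.

    ``per_units`` rescales the reported OR to a per-1 or per-10
    ml/min/1.73m² step (OR_10 = OR_1^10).  Refuses to fit when the
    complete-case sample is too small for the parameter count.
    """
    return _logistic_or(phenotypes, "egfr", list(confounders), per_units)
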