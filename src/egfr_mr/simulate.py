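"""Synthetic cohort and consortium-style outcome-sample generator.

Emulates the two samples of a two-sample MR design with known ground truth:

* an individual-level multi-study cohort — Hardy-Weinberg genotypes at the
  instrument SNPs, eGFR built from SNP effects + confounders + Gaussian
  noise (per-SNP effects rescaled jointly so the gene score explains a
  target fraction of eGFR variance), serum creatinine obtained by inverting
  the MDRD equation so derived eGFR round-trips, CHD drawn from a logistic
  model, and a trait panel wired per declared roles;
* an independent case/control outcome sample, ascertained by oversampling
  cases from the same generative population, summarised as per-SNP logistic
  log odds ratios split over three pseudo-meta-analyses with per-SNP
  availability gaps.

A single master seed spawns named substreams (genotypes, demographics,
traits, disease, outcome sample), so regenerating the outcome sample leaves
the cohort unchanged and vice versa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimConfig
from .phenotypes import invert_mdrd

# substream tags appended to the master seed
_STREAM_GENOTYPES = 1
_STREAM_DEMOGRAPHICS = 2
_STREAM_TRAITS = 3
_STREAM_DISEASE = 4
_STREAM_OUTCOME = 5
_STREAM_MISSING = 6

#: floor applied to latent eGFR so the MDRD inversion stays defined
_EGFR_FLOOR = 5.0


@dataclass
class Cohort:
    """Individual-level synthetic cohort.

    ``genotypes``: subjects × SNPs allele counts (float, NaN = missing) of
    the *effect allele* recorded in ``snps``.  ``snps``: per-SNP metadata
    (alleles, configured frequency, true scaled per-allele eGFR effect).
    ``phenotypes``: study label, demographics, creatinine, CHD status and
    the trait panel.  ``truth`` holds generative quantities used only by
    tests (latent eGFR, true score, scaled effects, causal log OR).
    """

    genotypes: pd.DataFrame
    snps: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: dict = field(default_factory=dict, repr=False)


def scaled_snp_effects(config: SimConfig) -> np.ndarray:
    """Per-allele eGFR effects rescaled jointly so the population R² of the
    true score on eGFR equals ``target_score_r2``.

    With raw effects δ_j and allele frequency f_j, the raw score variance is
    V_s = Σ δ_j² · 2 f_j (1−f_j); the remaining eGFR variance V_o collects
    noise plus trait contributions.  Scaling every δ_j by
    c = sqrt(R² V_o / (V_s (1−R²))) gives score variance c²V_s with
    c²V_s / (c²V_s + V_o) = R² exactly.
    """
    delta = np.array([s.egfr_effect for s in config.snps], dtype=float)
    if config.target_score_r2 is None:
        return delta
    r2 = config.target_score_r2
    if r2 == 0.0:
        return np.zeros_like(delta)
    freq = np.array([s.freq for s in config.snps], dtype=float)
    v_raw = float(np.sum(delta**2 * 2.0 * freq * (1.0 - freq)))
    if v_raw == 0.0:
        raise ValueError("target_score_r2 > 0 requires at least one nonzero SNP effect")
    v_other = config.egfr_noise_sd**2 + sum(
        t.effect_egfr**2
        for t in config.trait_spec
        if t.role in ("confounder", "exposure_only")
    )
    c = np.sqrt(r2 * v_other / (v_raw * (1.0 - r2)))
    return c * delta


def _study_offsets(config: SimConfig) -> np.ndarray:
    """Fixed study-level eGFR intercepts, evenly spread over ±4 ml/min."""
    k = len(config.study_names)
    if k == 1:
        return np.zeros(1)
    return np.linspace(-4.0, 4.0, k)


def _draw_population(
    config: SimConfig,
    n: int,
    rng_geno: np.random.Generator,
    rng_demo: np.random.Generator,
    rng_trait: np.random.Generator,
    rng_dis: np.random.Generator,
    study_offset: np.ndarray,
    effects: np.ndarray,
):
    """Draw n subjects from the generative model.

    Returns (genotypes n×K, age, female, black, egfr, chd, trait_values n×m,
    true_score).  ``study_offset`` is a per-subject intercept vector.
    """
    freq = np.array([s.freq for s in config.snps])
    geno = rng_geno.binomial(2, freq, size=(n, len(freq))).astype(float)

    age = rng_demo.normal(68.0, 7.0, size=n).clip(35.0, 95.0)
    female = rng_demo.random(n) < 0.48
    black = rng_demo.random(n) < 0.01

    traits = config.trait_spec
    z = rng_trait.normal(size=(n, len(traits))) if traits else np.zeros((n, 0))

    # genotype contribution centred at the population mean allele counts so
    # the configured egfr_mean is the population mean eGFR
    score = geno @ effects
    egfr = (
        config.egfr_mean
        + study_offset
        + score
        - float(2.0 * freq @ effects)
        + rng_demo.normal(0.0, config.egfr_noise_sd, size=n)
    )
    for j, t in enumerate(traits):
        if t.role in ("confounder", "exposure_only"):
            egfr = egfr + t.effect_egfr * z[:, j]
    egfr = np.maximum(egfr, _EGFR_FLOOR)

    logit = np.full(n, config.baseline_chd_logodds)
    logit = logit + config.true_causal_logor_per_egfr_unit * egfr
    for j, t in enumerate(traits):
        if t.role in ("confounder", "outcome_only"):
            logit = logit + t.effect_chd * z[:, j]
    chd = (rng_dis.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    # observed trait values: pathway markers load on realised eGFR
    values = np.empty_like(z)
    if traits:
        egfr_std = (egfr - egfr.mean()) / max(egfr.std(), 1e-12)
        for j, t in enumerate(traits):
            if t.role == "pathway_marker":
                load = np.clip(t.effect_egfr, -0.99, 0.99)
                values[:, j] = load * egfr_std + np.sqrt(1.0 - load**2) * z[:, j]
            elif t.binary:
                values[:, j] = (z[:, j] > 0).astype(float)
            else:
                values[:, j] = z[:, j]
    return geno, age, female, black, egfr, chd, values, score


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate the individual-level exposure cohort.

    Creatinine (and hence derivable eGFR) is set missing in studies outside
    ``config.egfr_studies``, mirroring eGFR being measured in only a subset
    of contributing studies; CHD status and traits are available everywhere
    (traits restricted to their declared studies).  Deterministic under the
    config seed.
    """
    seed = config.seed
    rng_geno = np.random.default_rng([seed, _STREAM_GENOTYPES])
    rng_demo = np.random.default_rng([seed, _STREAM_DEMOGRAPHICS])
    rng_trait = np.random.default_rng([seed, _STREAM_TRAITS])
    rng_dis = np.random.default_rng([seed, _STREAM_DISEASE])
    rng_miss = np.random.default_rng([seed, _STREAM_MISSING])

    n = int(sum(config.n_subjects_per_study))
    study = np.repeat(np.asarray(config.study_names, dtype=object), config.n_subjects_per_study)
    offsets = _study_offsets(config)
    study_offset = np.repeat(offsets, config.n_subjects_per_study)

    effects = scaled_snp_effects(config)
    geno, age, female, black, egfr, chd, trait_vals, score = _draw_population(
        config, n, rng_geno, rng_demo, rng_trait, rng_dis, study_offset, effects
    )

    creatinine = invert_mdrd(egfr, age, female, black)
    has_egfr = np.isin(study, config.egfr_studies)
    creatinine = np.where(has_egfr, creatinine, np.nan)

    if config.genotype_missing_rate > 0:
        mask = rng_miss.random(geno.shape) < config.genotype_missing_rate
        geno = np.where(mask, np.nan, geno)

    subject_id = pd.Index([f"S{i:06d}" for i in range(n)], name="subject_id")
    snp_ids = [s.id for s in config.snps]
    genotypes = pd.DataFrame(geno, index=subject_id, columns=snp_ids)
    snps = pd.DataFrame(
        {
            "effect_allele": [s.effect_allele for s in config.snps],
            "other_allele": [s.other_allele for s in config.snps],
            "freq": [s.freq for s in config.snps],
            "true_effect": effects,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    phen = pd.DataFrame(
        {
            "study": study,
            "age": age,
            "female": female.astype(int),
            "black": black.astype(int),
            "creatinine": creatinine,
            "chd": chd,
        },
        index=subject_id,
    )
    for j, t in enumerate(config.trait_spec):
        col = trait_vals[:, j].copy()
        if t.studies is not None:
            col = np.where(np.isin(study, t.studies), col, np.nan)
        phen[t.name] = col

    truth = {
        "scaled_effects": dict(zip(snp_ids, effects)),
        "latent_egfr": pd.Series(egfr, index=subject_id),
        "true_score": pd.Series(score, index=subject_id),
        "causal_logor_per_egfr_unit": config.true_causal_logor_per_egfr_unit,
        "study_offsets": dict(zip(config.study_names, offsets)),
    }
    return Cohort(genotypes=genotypes, snps=snps, phenotypes=phen, truth=truth)


# ---------------------------------------------------------------------------
# outcome sample
# ---------------------------------------------------------------------------


def persnp_logistic(y: np.ndarray, G: np.ndarray, max_iter: int = 50, tol: float = 1e-10):
    """Per-column logistic regression of binary y on each genotype column.

    Newton-Raphson on the 2-parameter model logit P(y=1) = b0 + b1·g, run
    simultaneously for all columns.  Returns (beta1, se1) arrays; columns
    with a degenerate genotype distribution yield NaN.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    n, k = G.shape
    ybar = min(max(y.mean(), 1e-12), 1 - 1e-12)
    b0 = np.full(k, np.log(ybar / (1.0 - ybar)))
    b1 = np.zeros(k)
    ok = G.std(axis=0) > 0
    h00 = h01 = h11 = np.full(k, np.nan)
    for _ in range(max_iter):
        eta = b0 + G * b1
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        r = y[:, None] - p
        g0 = r.sum(axis=0)
        g1 = (G * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * G).sum(axis=0)
        h11 = (w * G * G).sum(axis=0)
        det = h00 * h11 - h01 * h01
        with np.errstate(divide="ignore", invalid="ignore"):
            db0 = np.where(ok, (h11 * g0 - h01 * g1) / det, 0.0)
            db1 = np.where(ok, (-h01 * g0 + h00 * g1) / det, 0.0)
        b0 = b0 + db0
        b1 = b1 + db1
        if max(np.abs(db0).max(initial=0.0), np.abs(db1).max(initial=0.0)) < tol:
            break
    det = h00 * h11 - h01 * h01
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.where(ok, np.sqrt(h00 / det), np.nan)
    beta1 = np.where(ok, b1, np.nan)
    return beta1, se1


def _ascertain(
    config: SimConfig,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    effects: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Case/control genotype sample drawn by oversampling from the
    generative population (no study structure in the outcome sample)."""
    zeros = np.zeros(1)
    cases, controls = [], []
    got_cases = got_controls = 0
    for _ in range(10_000):
        if got_cases >= n_cases and got_controls >= n_controls:
            break
        batch = 100_000 if n_cases + n_controls > 20_000 else 20_000
        geno, _, _, _, _, chd, _, _ = _draw_population(
            config, batch, rng, rng, rng, rng, zeros, effects
        )
        is_case = chd == 1
        if got_cases < n_cases:
            cases.append(geno[is_case])
            got_cases += int(is_case.sum())
        if got_controls < n_controls:
            controls.append(geno[~is_case])
            got_controls += int((~is_case).sum())
    if got_cases < n_cases or got_controls < n_controls:
        raise RuntimeError("outcome-sample ascertainment failed to fill quotas")
    case_g = np.concatenate(cases)[:n_cases]
    control_g = np.concatenate(controls)[:n_controls]
    return case_g, control_g


def generate_outcome_summary(
    config: SimConfig, cohort: Optional[Cohort] = None
) -> pd.DataFrame:
    """Consortium-style per-SNP outcome summary statistics.

    By default (``cohort=None``, the two-sample design) an independent
    case/control sample is ascertained from the outcome substream of the
    master seed, split across the three pseudo-meta-analyses, and each SNP
    is fit by logistic regression of CHD on allele count within every
    analysis whose availability mask contains it.  Rows report the analysis
    with the smallest standard error (largest effective N).  SNPs absent
    from every analysis are omitted.  Each SNP's reported effect allele is
    chosen at random between the two alleles (with the log OR signed
    accordingly), so downstream harmonisation is always exercised.

    Passing an existing ``cohort`` instead computes the per-SNP statistics
    from that cohort's own subjects (a one-sample variant for contrast).
    """
    spec = config.outcome_sample
    effects = scaled_snp_effects(config)
    snp_ids = [s.id for s in config.snps]
    k = len(snp_ids)
    avail = np.ones((k, len(spec.meta_names)), dtype=bool)
    for j, sid in enumerate(snp_ids):
        if sid in spec.availability:
            avail[j] = spec.availability[sid]

    rng = np.random.default_rng([config.seed, _STREAM_OUTCOME])

    rows = []
    if cohort is not None:
        y = cohort.phenotypes["chd"].to_numpy(dtype=float)
        G = cohort.genotypes.to_numpy(dtype=float)
        keep = ~np.isnan(G).any(axis=1)
        beta, se = persnp_logistic(y[keep], G[keep])
        for j, sid in enumerate(snp_ids):
            rows.append(
                dict(
                    snp_id=sid,
                    beta=beta[j],
                    se=se[j],
                    n_cases=int(y[keep].sum()),
                    n_controls=int((1 - y[keep]).sum()),
                    source="cohort",
                )
            )
    else:
        for m, name in enumerate(spec.meta_names):
            frac = spec.meta_fractions[m]
            n_ca = max(1, int(round(spec.n_cases * frac)))
            n_co = max(1, int(round(spec.n_controls * frac)))
            case_g, control_g = _ascertain(config, n_ca, n_co, rng, effects)
            cols = np.flatnonzero(avail[:, m])
            G = np.concatenate([case_g, control_g])[:, cols]
            y = np.concatenate([np.ones(n_ca), np.zeros(n_co)])
            beta, se = persnp_logistic(y, G)
            for idx, j in enumerate(cols):
                rows.append(
                    dict(
                        snp_id=snp_ids[j],
                        beta=beta[idx],
                        se=se[idx],
                        n_cases=n_ca,
                        n_controls=n_co,
                        source=name,
                    )
                )

    allframe = pd.DataFrame(rows)
    degenerate = allframe["se"].isna()
    if degenerate.any():
        warnings.warn(
            f"dropping {int(degenerate.sum())} degenerate per-SNP fits "
            "(monomorphic genotype in an analysis)"
        )
        allframe = allframe[~degenerate]
    # per SNP keep the most precise analysis
    best = (
        allframe.sort_values(["snp_id", "se"], kind="mergesort")
        .groupby("snp_id", sort=False)
        .head(1)
        .reset_index(drop=True)
    )

    # reported effect allele chosen at random per SNP
    meta = {s.id: s for s in config.snps}
    flip = rng.random(len(best)) < 0.5
    eff_alleles, oth_alleles, betas = [], [], []
    for i, row in best.iterrows():
        s = meta[row["snp_id"]]
        if flip[best.index.get_loc(i)]:
            eff_alleles.append(s.other_allele)
            oth_alleles.append(s.effect_allele)
            betas.append(-row["beta"])
        else:
            eff_alleles.append(s.effect_allele)
            oth_alleles.append(s.other_allele)
            betas.append(row["beta"])
    best["effect_allele"] = eff_alleles
    best["other_allele"] = oth_alleles
    best["beta"] = betas
    best = best[
        ["snp_id", "effect_allele", "other_allele", "beta", "se", "n_cases", "n_controls", "source"]
    ]
    # preserve instrument order for SNPs that survived
    order = {sid: j for j, sid in enumerate(snp_ids)}
    best = best.sort_values("snp_id", key=lambda s: s.map(order), kind="mergesort")
    best = best.reset_index(drop=True)
    best.attrs["all_analyses"] = allframe
    return best
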