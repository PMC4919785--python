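"""Harmonisation, the pooled summary-statistic estimator, sensitivity
analyses, reverse MR and the observational association."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from egfr_mr.mr import (
    exclude_snps,
    harmonize,
    johnson_estimate,
    leave_one_out,
    observational_association,
    reverse_mr,
    subgroup_estimate,
)
from egfr_mr.phenotypes import add_egfr
from egfr_mr.pipeline import calibration_config, run_two_sample_mr
from egfr_mr.score import estimate_weights
from egfr_mr.simulate import generate_cohort, generate_outcome_summary

from conftest import make_config, toy_summary, toy_weights


# ---------------------------------------------------------------------------
# harmonisation
# ---------------------------------------------------------------------------


def test_harmonize_identity_when_aligned():
    h = harmonize(toy_summary(), toy_weights())
    assert np.allclose(h["beta"], [0.01, 0.03, 0.05])
    assert len(h) == 3


def test_harmonize_flips_swapped_alleles():
    s = toy_summary()
    s.loc[0, ["effect_allele", "other_allele"]] = ["G", "A"]
    s.loc[0, "beta"] = 0.05
    h = harmonize(s, toy_weights()).set_index("snp_id")
    assert h.at["rs1", "beta"] == pytest.approx(-0.05)


def test_harmonize_involution():
    def swap(s):
        out = s.copy()
        out[["effect_allele", "other_allele"]] = out[["other_allele", "effect_allele"]].values
        out["beta"] = -out["beta"]
        return out

    s = toy_summary()
    h0 = harmonize(s, toy_weights())
    h2 = harmonize(swap(swap(s)), toy_weights())
    pd.testing.assert_frame_equal(h0, h2)


def test_harmonize_drops_missing_with_ledger():
    s = toy_summary().iloc[:1]
    with pytest.warns(UserWarning, match="absent from the summary"):
        h = harmonize(s, toy_weights())
    assert len(h) == 1
    assert sorted(h.attrs["ledger"]["missing"]) == ["rs2", "rs3"]
    est = johnson_estimate(h, unit_weights=True)
    assert est.n_snps_used == 1 and set(est.dropped) == {"rs2", "rs3"}


def test_harmonize_allele_mismatch_excluded():
    s = toy_summary()
    s.loc[1, ["effect_allele", "other_allele"]] = ["A", "G"]  # rs2 is C/T
    with pytest.warns(UserWarning, match="do not match"):
        h = harmonize(s, toy_weights())
    assert "rs2" not in set(h["snp_id"])
    assert h.attrs["ledger"]["allele_mismatch"] == ["rs2"]


def test_harmonize_flags_palindromic():
    s = toy_summary()
    s.loc[0, ["effect_allele", "other_allele"]] = ["A", "T"]
    w = toy_weights()
    w.loc["rs1", ["increasing_allele", "other_allele"]] = ["A", "T"]
    with pytest.warns(UserWarning, match="palindromic"):
        h = harmonize(s, w).set_index("snp_id")
    assert bool(h.at["rs1", "palindromic"])


def test_harmonize_prefers_most_precise_source():
    s = pd.concat([toy_summary(), toy_summary().assign(se=0.005, source="BIG")])
    h = harmonize(s, toy_weights()).set_index("snp_id")
    assert (h["source"] == "BIG").all()
    assert np.allclose(h["se"], 0.005)


# ---------------------------------------------------------------------------
# pooled estimator
# ---------------------------------------------------------------------------


def test_single_snp_identity():
    s = toy_summary().iloc[:1].assign(beta=-0.02, se=0.01)
    est = johnson_estimate(harmonize(s, toy_weights().iloc[:1]), unit_weights=True)
    assert est.beta_hat == pytest.approx(-0.02)
    assert est.se == pytest.approx(0.01)
    assert est.ci95[0] == pytest.approx(np.exp(-0.02 - 1.96 * 0.01))


def test_equal_snp_precision_pooling():
    k, b, s_ = 9, 0.04, 0.02
    s = pd.DataFrame(
        {
            "snp_id": [f"x{i}" for i in range(k)],
            "beta": b,
            "se": s_,
            "w": 1.0,
        }
    )
    est = johnson_estimate(s, unit_weights=True)
    assert est.beta_hat == pytest.approx(b)
    assert est.se == pytest.approx(s_ / np.sqrt(k))


def wls_origin_oracle(beta, w, se):
    """Independent oracle: WLS of beta on w through the origin, weights 1/se²."""
    fit = sm.WLS(
        np.asarray(beta, dtype=float),
        np.asarray(w, dtype=float)[:, None],
        weights=1.0 / np.asarray(se, dtype=float) ** 2,
    ).fit()
    return float(fit.params[0]), float(fit.bse[0] / np.sqrt(fit.scale))


def test_estimator_equals_origin_wls():
    h = harmonize(toy_summary(), toy_weights())
    est = johnson_estimate(h)
    b_ref, se_ref = wls_origin_oracle(h["beta"], h["w"], h["se"])
    assert est.beta_hat == pytest.approx(b_ref, rel=1e-12)
    assert est.se == pytest.approx(se_ref, rel=1e-12)


def test_estimator_scale_invariance():
    h = harmonize(toy_summary(), toy_weights())
    est1 = johnson_estimate(h)
    h2 = h.assign(w=5.0 * h["w"])
    est2 = johnson_estimate(h2)
    assert est2.beta_hat == pytest.approx(est1.beta_hat / 5.0)
    assert est2.se == pytest.approx(est1.se / 5.0)
    assert est2.p == pytest.approx(est1.p)


def test_estimator_error_paths():
    h = harmonize(toy_summary(), toy_weights())
    with pytest.raises(ValueError, match="zero"):
        johnson_estimate(h.assign(w=0.0))
    with pytest.raises(ValueError, match="no SNPs"):
        johnson_estimate(h.iloc[:0])
    with pytest.raises(ValueError, match="positive"):
        johnson_estimate(h.assign(se=[0.01, -1.0, 0.01]))


# ---------------------------------------------------------------------------
# sensitivity analyses
# ---------------------------------------------------------------------------


def test_leave_one_out_symmetry_and_recomputation():
    k = 5
    sym = pd.DataFrame(
        {"snp_id": [f"x{i}" for i in range(k)], "beta": 0.03, "se": 0.01, "w": 1.0}
    )
    loo = leave_one_out(sym, unit_weights=True)
    assert loo["beta_hat"].nunique() == 1

    h = harmonize(toy_summary(), toy_weights())
    loo = leave_one_out(h).set_index("excluded_snp")
    direct = johnson_estimate(h[h["snp_id"] != "rs2"])
    assert loo.at["rs2", "beta_hat"] == pytest.approx(direct.beta_hat, rel=1e-12)


def test_leave_one_out_flags_driver_snp():
    # ten exchangeable null SNPs plus one planted pleiotropic driver
    base = pd.DataFrame(
        {"snp_id": [f"x{i}" for i in range(10)], "beta": 0.0, "se": 0.01, "w": 1.0}
    )
    driver = pd.DataFrame(
        {"snp_id": ["drv"], "beta": [-0.12], "se": [0.01], "w": [1.0]}
    )
    h = pd.concat([base, driver], ignore_index=True)
    full = johnson_estimate(h, unit_weights=True)
    assert full.p < 0.05
    loo = leave_one_out(h, unit_weights=True).set_index("excluded_snp")
    assert bool(loo.at["drv", "crosses_significance"])
    assert not loo.drop(index="drv")["crosses_significance"].any()
    # excluding the driver moves the estimate toward the null consensus
    assert abs(loo.at["drv", "beta_hat"]) < abs(full.beta_hat)


def test_exclude_snps_identities():
    h = harmonize(toy_summary(), toy_weights())
    full = johnson_estimate(h)
    assert exclude_snps(h, []).beta_hat == pytest.approx(full.beta_hat)
    single = exclude_snps(h, ["rs1", "rs2"], unit_weights=True)
    assert single.beta_hat == pytest.approx(0.05)
    with pytest.raises(KeyError, match="rs99"):
        exclude_snps(h, ["rs99"])


# ---------------------------------------------------------------------------
# subgroup, reverse MR, observational
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def mr_run():
    return run_two_sample_mr(calibration_config(seed=61, n_exposure=6000, n_outcome=8000))


def test_subgroup_all_equals_main(mr_run):
    cohort = mr_run.cohort
    est = subgroup_estimate(
        cohort.genotypes, cohort.snps, cohort.phenotypes, mr_run.summary, category="all"
    )
    assert est.beta_hat == pytest.approx(mr_run.weighted.beta_hat, rel=1e-12)
    assert not est.bias_caveat


def test_subgroup_low_egfr_null_consistent():
    cfg = calibration_config(seed=63, n_exposure=8000, n_outcome=8000, causal_logor=0.0)
    run = run_two_sample_mr(cfg)
    est = subgroup_estimate(
        run.cohort.genotypes,
        run.cohort.snps,
        run.cohort.phenotypes,
        run.summary,
        category="low",
    )
    assert est.bias_caveat and est.subgroup == "low"
    assert abs(est.beta_hat) < 4 * est.se


def test_subgroup_too_small_refuses(mr_run):
    cohort = mr_run.cohort
    with pytest.raises(ValueError, match="too small"):
        subgroup_estimate(
            cohort.genotypes,
            cohort.snps,
            cohort.phenotypes,
            mr_run.summary,
            category="low",
            min_subjects=10**7,
        )


def test_reverse_mr_null():
    # CHD-associated SNPs with no effect on eGFR: reverse estimate ~ 0
    from egfr_mr.config import SnpSpec

    cfg = make_config(
        seed=65,
        n_subjects_per_study=[3000, 3000, 3000],
        snps=[SnpSpec(id=f"chd{k}", freq=0.2 + 0.01 * k, egfr_effect=0.0) for k in range(20)],
        target_score_r2=None,
        trait_spec=[],
    )
    c = generate_cohort(cfg)
    c.phenotypes = add_egfr(c.phenotypes)
    w = estimate_weights(c.genotypes, c.snps, c.phenotypes)
    # cohort-side per-SNP eGFR betas become the 'outcome' summary statistics
    egfr_summary = pd.DataFrame(
        {
            "snp_id": w.index,
            "effect_allele": c.snps["effect_allele"].values,
            "other_allele": c.snps["other_allele"].values,
            "beta": w["beta_counted"].values,
            "se": w["se_w"].values,
            "n_cases": 0,
            "n_controls": 0,
            "source": "cohort",
        }
    )
    rng = np.random.default_rng(0)
    chd_weights = pd.DataFrame(
        {
            "increasing_allele": c.snps["effect_allele"].values,
            "other_allele": c.snps["other_allele"].values,
            "w": rng.uniform(0.05, 0.2, len(w)),  # published CHD log ORs
            "se_w": 0.01,
        },
        index=w.index,
    )
    est = reverse_mr(chd_weights, egfr_summary)
    assert est.score_type == "reverse_weighted"
    assert abs(est.beta_hat) < 4 * est.se
    assert np.isnan(est.or_)
    # equal weights reduce to the unit-weight estimator's z statistic
    eq = chd_weights.assign(w=0.1)
    est_eq = reverse_mr(eq, egfr_summary)
    unit = johnson_estimate(harmonize(egfr_summary, eq), unit_weights=True)
    assert est_eq.beta_hat / est_eq.se == pytest.approx(unit.beta_hat / unit.se)


def test_observational_association_recovers_generative_or():
    cfg = make_config(seed=67, n_subjects_per_study=[4000, 3000, 3000], trait_spec=[])
    c = generate_cohort(cfg)
    phen = add_egfr(c.phenotypes)
    res = observational_association(phen)
    assert res.beta == pytest.approx(-0.016, abs=4 * res.se)
    assert res.or_ < 1
    # permuting eGFR against CHD gives OR ~ 1
    rng = np.random.default_rng(5)
    phen2 = phen.copy()
    phen2["egfr"] = phen["egfr"].to_numpy()[rng.permutation(len(phen))]
    null = observational_association(phen2)
    assert abs(null.beta) < 4 * null.se


def test_quintile_trend_is_monotone():
    cfg = make_config(seed=69, n_subjects_per_study=[5000, 5000, 4000], trait_spec=[])
    c = generate_cohort(cfg)
    phen = add_egfr(c.phenotypes)
    q = pd.qcut(phen["egfr"], 5, labels=False)
    rates = phen.groupby(q)["chd"].mean()
    from scipy import stats as st

    rho = st.spearmanr(rates.index, rates.values).statistic
    assert rho == pytest.approx(-1.0)
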