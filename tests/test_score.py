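"""Weight estimation, allele orientation, gene scores, instrument strength."""

import numpy as np
import pandas as pd
import pytest

from egfr_mr.phenotypes import add_egfr
from egfr_mr.score import (
    build_score,
    estimate_weights,
    instrument_strength,
    orient_from_external,
)
from egfr_mr.simulate import generate_cohort

from conftest import make_config, toy_weights


@pytest.fixture(scope="module")
def big_cohort():
    cfg = make_config(seed=31, n_subjects_per_study=[3000, 2000, 2000], trait_spec=[])
    c = generate_cohort(cfg)
    c.phenotypes = add_egfr(c.phenotypes)
    return c


@pytest.fixture(scope="module")
def weights(big_cohort):
    return estimate_weights(big_cohort.genotypes, big_cohort.snps, big_cohort.phenotypes)


def test_weights_recover_generative_effects(big_cohort, weights):
    truth = big_cohort.snps["true_effect"]
    for sid in truth.index:
        w = weights.loc[sid]
        assert w["beta_counted"] == pytest.approx(truth[sid], abs=4 * w["se_w"]), sid
    # oriented weights are non-negative for internal regressions
    assert (weights["w"] >= 0).all()
    # generative effects are positive per effect allele, so orientation
    # should agree with the effect allele for these well-powered SNPs
    strong = truth[truth > 0.3].index
    assert (
        weights.loc[strong, "increasing_allele"]
        == big_cohort.snps.loc[strong, "effect_allele"]
    ).all()


def test_weights_invariant_to_subject_order(big_cohort):
    perm = np.random.default_rng(0).permutation(len(big_cohort.genotypes))
    g = big_cohort.genotypes.iloc[perm]
    p = big_cohort.phenotypes.iloc[perm]
    w1 = estimate_weights(big_cohort.genotypes, big_cohort.snps, big_cohort.phenotypes)
    w2 = estimate_weights(g, big_cohort.snps, p)
    pd.testing.assert_frame_equal(w1, w2)


def test_monomorphic_snp_flagged(big_cohort):
    g = big_cohort.genotypes.copy()
    g["rs1"] = 2.0
    with pytest.warns(UserWarning, match="monomorphic"):
        w = estimate_weights(g, big_cohort.snps, big_cohort.phenotypes)
    assert w.at["rs1", "flag"] == "monomorphic"
    assert np.isnan(w.at["rs1", "w"])


def test_all_missing_outcome_errors(big_cohort):
    phen = big_cohort.phenotypes.copy()
    phen["egfr"] = np.nan
    with pytest.raises(ValueError, match="missing"):
        estimate_weights(big_cohort.genotypes, big_cohort.snps, phen)


def test_toy_weighted_score_dot_product():
    # g = (0,1,2), w = (0.5,1.0,0.25) -> weighted score 1.5
    snps = pd.DataFrame(
        {
            "effect_allele": ["A", "C", "G"],
            "other_allele": ["G", "T", "A"],
        },
        index=pd.Index(["rs1", "rs2", "rs3"], name="snp_id"),
    )
    geno = pd.DataFrame([[0.0, 1.0, 2.0]], index=["s1"], columns=["rs1", "rs2", "rs3"])
    w = toy_weights(w=(0.5, 1.0, 0.25))
    s = build_score(geno, snps, w, score_type="weighted")
    assert s.loc["s1"] == pytest.approx(1.5)


def test_unweighted_maximum_and_reduction_identity(big_cohort, weights):
    k = len(weights)
    homo = pd.DataFrame(
        [[2.0] * k], index=["smax"], columns=weights.index
    )
    # orient the row: subject homozygous for the increasing allele everywhere
    snps = big_cohort.snps.copy()
    flip = weights["increasing_allele"] != snps["effect_allele"]
    homo.loc["smax", flip[flip].index] = 0.0
    u = build_score(homo, snps, weights, score_type="unweighted")
    assert u.loc["smax"] == pytest.approx(2 * k)
    # all w_j = 1 makes the weighted score equal the unweighted score
    w1 = weights.copy()
    w1["w"] = 1.0
    uw = build_score(big_cohort.genotypes, snps, w1, score_type="unweighted")
    ww = build_score(big_cohort.genotypes, snps, w1, score_type="weighted")
    assert np.allclose(uw, ww)


def test_score_linearity_in_weights(big_cohort, weights):
    w2 = weights.copy()
    w2["w"] = 3.0 * w2["w"]
    s1 = build_score(big_cohort.genotypes, big_cohort.snps, weights, "weighted")
    s3 = build_score(big_cohort.genotypes, big_cohort.snps, w2, "weighted")
    assert np.allclose(3.0 * s1, s3)


def test_missing_genotype_policy(big_cohort, weights):
    g = big_cohort.genotypes.copy()
    subj = g.index[0]
    g.loc[subj, :] = np.nan  # all genotypes missing -> missing score
    subj2 = g.index[1]
    g.loc[subj2, "rs1"] = np.nan  # one missing -> study-mean imputation
    s = build_score(g, big_cohort.snps, weights, "unweighted",
                    study=big_cohort.phenotypes["study"])
    assert np.isnan(s.loc[subj])
    study2 = big_cohort.phenotypes.at[subj2, "study"]
    in_study = big_cohort.phenotypes["study"] == study2
    fill = g.loc[in_study, "rs1"].mean()
    expected_g = fill if weights.at["rs1", "increasing_allele"] == big_cohort.snps.at["rs1", "effect_allele"] else 2 - fill
    manual = build_score(g.drop(columns="rs1"), big_cohort.snps,
                         weights.drop(index="rs1"), "unweighted",
                         study=big_cohort.phenotypes["study"])
    assert s.loc[subj2] == pytest.approx(manual.loc[subj2] + expected_g)


def test_external_orientation_noop_and_flip(big_cohort, weights):
    agree = pd.DataFrame(
        {"snp_id": weights.index, "increasing_allele": weights["increasing_allele"].values}
    )
    same = orient_from_external(weights, agree)
    assert (same["increasing_allele"] == weights["increasing_allele"]).all()
    assert np.allclose(same["w"], weights["w"])

    flip_ids = list(weights.index[:2])
    cat = pd.DataFrame(
        {
            "snp_id": flip_ids,
            "increasing_allele": weights.loc[flip_ids, "other_allele"].values,
        }
    )
    flipped = orient_from_external(weights, cat)
    s_old = build_score(big_cohort.genotypes, big_cohort.snps, weights, "unweighted")
    s_new = build_score(big_cohort.genotypes, big_cohort.snps, flipped, "unweighted")
    # flipping SNP j replaces g_ij by 2 - g_ij in the unweighted score
    delta = sum(
        2.0 - 2.0 * (
            big_cohort.genotypes[sid]
            if weights.at[sid, "increasing_allele"] == big_cohort.snps.at[sid, "effect_allele"]
            else 2.0 - big_cohort.genotypes[sid]
        )
        for sid in flip_ids
    )
    assert np.allclose(s_new, s_old + delta)


def test_orientation_involution(big_cohort, weights):
    flip_ids = list(weights.index[:3])
    cat1 = pd.DataFrame(
        {"snp_id": flip_ids, "increasing_allele": weights.loc[flip_ids, "other_allele"].values}
    )
    once = orient_from_external(weights, cat1)
    cat2 = pd.DataFrame(
        {"snp_id": flip_ids, "increasing_allele": weights.loc[flip_ids, "increasing_allele"].values}
    )
    twice = orient_from_external(once, cat2)
    s0 = build_score(big_cohort.genotypes, big_cohort.snps, weights, "weighted")
    s2 = build_score(big_cohort.genotypes, big_cohort.snps, twice, "weighted")
    assert np.allclose(s0, s2)


def test_external_allele_mismatch_flagged(weights):
    cat = pd.DataFrame({"snp_id": [weights.index[0]], "increasing_allele": ["Z"]})
    with pytest.warns(UserWarning, match="strand/label"):
        out = orient_from_external(weights, cat)
    assert out.iloc[0]["flag"] == "allele_mismatch"


def test_instrument_strength_identities(big_cohort, weights):
    phen = big_cohort.phenotypes
    perfect = instrument_strength(phen["egfr"], phen)
    assert perfect.r_squared == pytest.approx(1.0)

    rng = np.random.default_rng(4)
    null_score = pd.Series(rng.normal(size=len(phen)), index=phen.index)
    null = instrument_strength(null_score, phen)
    assert null.r_squared < 0.002
    assert null.f_statistic < 8.0

    score = build_score(big_cohort.genotypes, big_cohort.snps, weights, "weighted")
    strength = instrument_strength(score, phen)
    # partial-R² identity F = df * R2/(1-R2), computed via an independent
    # full-vs-reduced statsmodels comparison
    import statsmodels.api as sm

    d = pd.get_dummies(phen["study"], drop_first=True).astype(float)
    X_full = sm.add_constant(pd.concat([d, score.rename("score")], axis=1))
    X_red = sm.add_constant(d)
    full = sm.OLS(phen["egfr"], X_full).fit()
    red = sm.OLS(phen["egfr"], X_red).fit()
    f_ref = (red.ssr - full.ssr) / (full.ssr / full.df_resid)
    assert strength.f_statistic == pytest.approx(f_ref, rel=1e-8)
    df = full.df_resid
    assert strength.f_statistic == pytest.approx(
        df * strength.r_squared / (1 - strength.r_squared), rel=1e-8
    )


def test_strength_in_paper_regime():
    # 1.5% score R² at n ~ 6,700 puts the F statistic in the several-tens range
    cfg = make_config(
        seed=33,
        n_subjects_per_study=[2300, 2200, 2200],
        target_score_r2=0.015,
        trait_spec=[],
    )
    c = generate_cohort(cfg)
    c.phenotypes = add_egfr(c.phenotypes)
    w = estimate_weights(c.genotypes, c.snps, c.phenotypes)
    score = build_score(c.genotypes, c.snps, w, "weighted")
    st = instrument_strength(score, c.phenotypes)
    # design: intercept + 2 study dummies + score -> residual df = n - 4
    expected_f = (st.n_used - 4) * st.r_squared / (1 - st.r_squared)
    assert st.f_statistic == pytest.approx(expected_f, rel=0.02)
    assert 20 < st.f_statistic < 400


def test_zero_variance_score_errors(big_cohort):
    s = pd.Series(1.0, index=big_cohort.phenotypes.index)
    with pytest.raises(ValueError, match="zero variance"):
        instrument_strength(s, big_cohort.phenotypes)
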