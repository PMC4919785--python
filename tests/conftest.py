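import numpy as np
import pandas as pd
import pytest

from egfr_mr.config import OutcomeSampleSpec, SimConfig, SnpSpec, TraitSpec


def make_config(seed=0, **overrides) -> SimConfig:
    """Small, fast study configuration used across the unit tests."""
    base = dict(
        study_names=["S1", "S2", "S3"],
        n_subjects_per_study=[400, 300, 300],
        egfr_studies=["S1", "S2", "S3"],
        snps=[
            SnpSpec(id="rs1", freq=0.30, egfr_effect=1.2),
            SnpSpec(id="rs2", freq=0.45, egfr_effect=0.8),
            SnpSpec(id="rs3", freq=0.20, egfr_effect=1.0),
            SnpSpec(id="rs4", freq=0.50, egfr_effect=0.6),
            SnpSpec(id="rs5", freq=0.10, egfr_effect=1.5),
        ],
        target_score_r2=0.02,
        trait_spec=[
            TraitSpec(name="bmi", role="confounder", effect_egfr=-2.0, effect_chd=0.25),
            TraitSpec(name="crp", role="confounder", effect_egfr=-1.5, effect_chd=0.2),
            TraitSpec(name="ntprobnp", role="pathway_marker", effect_egfr=-0.4),
            TraitSpec(name="fev1", role="exposure_only", effect_egfr=1.5),
            TraitSpec(name="qt_interval", role="outcome_only", effect_chd=0.2),
            TraitSpec(name="noise1", role="null"),
            TraitSpec(name="noise2", role="null"),
        ],
        true_causal_logor_per_egfr_unit=-0.016,
        baseline_chd_logodds=-0.4,
        egfr_noise_sd=15.0,
        outcome_sample=OutcomeSampleSpec(
            n_cases=600,
            n_controls=1400,
            meta_names=["ALL"],
            meta_fractions=[1.0],
        ),
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return make_config(seed=42)


@pytest.fixture(scope="session")
def cohort(small_config):
    from egfr_mr.phenotypes import add_egfr
    from egfr_mr.simulate import generate_cohort

    c = generate_cohort(small_config)
    c.phenotypes = add_egfr(c.phenotypes)
    return c


def toy_summary() -> pd.DataFrame:
    """Hand-sized outcome summary-statistics frame (3 SNPs)."""
    return pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3"],
            "effect_allele": ["A", "C", "G"],
            "other_allele": ["G", "T", "A"],
            "beta": [0.01, 0.03, 0.05],
            "se": [0.01, 0.02, 0.02],
            "n_cases": [1000, 1000, 1000],
            "n_controls": [2000, 2000, 2000],
            "source": ["ALL"] * 3,
        }
    )


def toy_weights(w=(0.5, 1.0, 2.0)) -> pd.DataFrame:
    """Weights aligned with toy_summary's effect alleles."""
    return pd.DataFrame(
        {
            "increasing_allele": ["A", "C", "G"],
            "other_allele": ["G", "T", "A"],
            "w": list(w),
            "se_w": [0.1, 0.1, 0.1],
            "beta_counted": list(w),
            "n": [5000] * 3,
            "source": ["internal_regression"] * 3,
            "flag": [""] * 3,
        },
        index=pd.Index(["rs1", "rs2", "rs3"], name="snp_id"),
    )
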