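"""Simulation configuration.

A :class:`SimConfig` fully determines one synthetic "study": a multi-study
individual-level cohort (genotypes at the instrument SNPs, demographics,
serum creatinine / eGFR, CHD status and a panel of quantitative traits) and
an independent consortium-style case/control outcome sample summarised per
SNP.  The same master ``seed`` always reproduces the same data; the cohort
and the outcome sample are drawn from disjoint random substreams so either
can be regenerated without disturbing the other.
"""

from __future__ import annotations

import warnings
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

TraitRole = Literal[
    "confounder", "exposure_only", "outcome_only", "null", "pathway_marker"
]

#: Non-palindromic allele pairs cycled through when assigning SNP alleles.
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T")]


class SnpSpec(BaseModel):
    """One instrument SNP: identifier, effect-allele frequency and its
    per-allele effect on eGFR (ml/min/1.73m² per counted allele)."""

    id: str
    freq: float = Field(gt=0.0, lt=1.0)
    egfr_effect: float = 0.0
    effect_allele: Optional[str] = None
    other_allele: Optional[str] = None

    @field_validator("freq")
    @classmethod
    def _freq_plausible(cls, v: float) -> float:
        if not (0.01 <= v <= 0.99):
            raise ValueError(f"effect-allele frequency {v} outside [0.01, 0.99]")
        return v


class TraitSpec(BaseModel):
    """A quantitative (or binary) trait in the cohort panel.

    ``role`` controls the generative wiring: confounders influence both eGFR
    and the CHD log-odds, exposure-only traits influence eGFR alone,
    outcome-only traits the CHD log-odds alone, pathway markers are driven by
    eGFR itself (downstream, e.g. a renally cleared biomarker), and null
    traits are independent noise.  Effects are per standard deviation of the
    trait; eGFR effects in ml/min/1.73m², CHD effects on the log-odds scale.
    """

    name: str
    role: TraitRole = "null"
    effect_egfr: float = 0.0
    effect_chd: float = 0.0
    binary: bool = False
    #: study labels the trait is measured in; None = all studies
    studies: Optional[list[str]] = None


class OutcomeSampleSpec(BaseModel):
    """Shape of the consortium-style outcome sample.

    Cases and controls are split across three pseudo-meta-analyses
    (mirroring a GWAS + a second GWAS + a combined chip analysis); each SNP
    is genotyped only in the analyses its availability mask marks, so the
    effective sample size varies across SNPs.
    """

    n_cases: int = Field(gt=0)
    n_controls: int = Field(gt=0)
    meta_names: list[str] = ["GWAS1", "GWAS2", "CHIP"]
    #: fraction of cases/controls allocated to each pseudo-meta-analysis
    meta_fractions: list[float] = [0.25, 0.15, 0.60]
    #: snp_id -> availability flags, one per pseudo-meta-analysis;
    #: SNPs not listed are available everywhere
    availability: dict[str, list[bool]] = {}

    @model_validator(mode="after")
    def _check(self) -> "OutcomeSampleSpec":
        if len(self.meta_names) != len(self.meta_fractions):
            raise ValueError("meta_names and meta_fractions must have equal length")
        if abs(sum(self.meta_fractions) - 1.0) > 1e-9:
            raise ValueError("meta_fractions must sum to 1")
        for snp, mask in self.availability.items():
            if len(mask) != len(self.meta_names):
                raise ValueError(f"availability mask for {snp} has wrong length")
            if not any(mask):
                warnings.warn(
                    f"SNP {snp} unavailable in every pseudo-meta-analysis; "
                    "it will be omitted from the outcome summary"
                )
        return self


class SimConfig(BaseModel):
    """Master configuration for the synthetic cohort + outcome sample."""

    study_names: list[str]
    n_subjects_per_study: list[int]
    #: studies in which creatinine (hence eGFR) is measured
    egfr_studies: list[str]
    snps: list[SnpSpec]
    #: population fraction of eGFR variance explained by the gene score;
    #: per-SNP effects are rescaled jointly to hit this in expectation.
    #: None leaves the configured effects untouched.
    target_score_r2: Optional[float] = None
    trait_spec: list[TraitSpec] = []
    true_causal_logor_per_egfr_unit: float = 0.0
    baseline_chd_logodds: float = -0.45
    egfr_mean: float = 70.0
    egfr_noise_sd: float = Field(default=15.0, gt=0.0)
    genotype_missing_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    outcome_sample: OutcomeSampleSpec
    seed: int = 0

    @field_validator("snps")
    @classmethod
    def _nonempty_snps(cls, v: list[SnpSpec]) -> list[SnpSpec]:
        if not v:
            raise ValueError("snp list must not be empty")
        ids = [s.id for s in v]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")
        return v

    @field_validator("target_score_r2")
    @classmethod
    def _plausible_r2(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not (0.0 <= v < 0.5):
            raise ValueError(
                f"target_score_r2={v} rejected: a polygenic eGFR score explaining "
                ">=50% of variance is implausible and signals a config error"
            )
        return v

    @model_validator(mode="after")
    def _consistent(self) -> "SimConfig":
        if len(self.study_names) != len(self.n_subjects_per_study):
            raise ValueError("study_names and n_subjects_per_study length mismatch")
        if len(set(self.study_names)) != len(self.study_names):
            raise ValueError("duplicate study names")
        unknown = set(self.egfr_studies) - set(self.study_names)
        if unknown:
            raise ValueError(f"egfr_studies not among study_names: {sorted(unknown)}")
        for t in self.trait_spec:
            if t.studies is not None:
                bad = set(t.studies) - set(self.study_names)
                if bad:
                    raise ValueError(f"trait {t.name} lists unknown studies {sorted(bad)}")
        snp_ids = {s.id for s in self.snps}
        bad = set(self.outcome_sample.availability) - snp_ids
        if bad:
            raise ValueError(f"availability mask for unknown SNPs: {sorted(bad)}")
        # assign default allele labels where unset
        for j, s in enumerate(self.snps):
            pair = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
            if s.effect_allele is None:
                s.effect_allele = pair[0]
            if s.other_allele is None:
                s.other_allele = pair[1]
            if s.effect_allele == s.other_allele:
                raise ValueError(f"SNP {s.id}: effect and other allele identical")
        return self

    # -- serialisation -----------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Default study conditions: a consortium-like 7-study cohort (eGFR measured
# in 4 studies) and a large CHD-consortium-style outcome sample released as three
# meta-analyses with per-SNP availability gaps.
# ---------------------------------------------------------------------------

#: 17 eGFR-associated SNPs used as the default instrument set: (id,
#: effect-allele frequency, relative per-allele eGFR effect).  Identifiers
#: follow well-known kidney-function loci; frequencies and effects are
#: synthetic (relative effect sizes are rescaled jointly to the target score
#: R²).  rs653178 is deliberately given the weakest effect, mirroring its
#: weak creatinine-eGFR association in richly phenotyped cohorts.
DEFAULT_SNPS: list[tuple[str, float, float]] = [
    ("rs653178", 0.48, 0.20),
    ("rs1260326", 0.41, 1.10),
    ("rs17319721", 0.43, 1.40),
    ("rs12917707", 0.18, 1.30),
    ("rs2467853", 0.47, 0.90),
    ("rs1933182", 0.42, 0.80),
    ("rs4744712", 0.39, 0.85),
    ("rs7805747", 0.26, 1.20),
    ("rs2453533", 0.38, 1.00),
    ("rs6420094", 0.35, 0.95),
    ("rs13538", 0.22, 0.70),
    ("rs347685", 0.29, 0.75),
    ("rs11959928", 0.44, 0.90),
    ("rs2928148", 0.49, 0.65),
    ("rs6431731", 0.07, 1.50),
    ("rs881858", 0.30, 0.85),
    ("rs3925584", 0.45, 0.80),
]

#: Default per-SNP availability across (GWAS1, GWAS2, CHIP): a handful of
#: SNPs are missing from one or two pseudo-meta-analyses, so total N varies
#: by SNP, but every SNP is present somewhere.
DEFAULT_AVAILABILITY: dict[str, list[bool]] = {
    "rs12917707": [True, False, True],
    "rs6431731": [False, False, True],
    "rs13538": [True, True, False],
    "rs347685": [False, True, True],
}


def default_trait_panel(n_total: int = 94) -> list[TraitSpec]:
    """Default cohort trait panel: a realistic mix of confounders,
    kidney-pathway markers and null traits, padded to ``n_total`` traits.

    Roughly emulates a cardiovascular-cohort phenotype panel: a block of
    true eGFR-CHD confounders (adiposity, lipids, inflammation, smoking
    exposure), one renally cleared biomarker (NTproBNP, downstream of eGFR),
    one confounder measured in a single study only (percent_body_fat), a few
    one-sided traits, and independent null traits for the remainder.
    """
    named: list[TraitSpec] = [
        TraitSpec(name="bmi", role="confounder", effect_egfr=-1.5, effect_chd=0.15),
        TraitSpec(name="weight", role="confounder", effect_egfr=-1.2, effect_chd=0.12),
        TraitSpec(name="waist_circumference", role="confounder", effect_egfr=-1.3, effect_chd=0.14),
        TraitSpec(name="triglyceride", role="confounder", effect_egfr=-1.0, effect_chd=0.18),
        TraitSpec(name="hdl", role="confounder", effect_egfr=1.0, effect_chd=-0.20),
        TraitSpec(name="crp", role="confounder", effect_egfr=-1.1, effect_chd=0.16),
        TraitSpec(name="il6", role="confounder", effect_egfr=-1.0, effect_chd=0.15),
        TraitSpec(name="fibrinogen", role="confounder", effect_egfr=-0.9, effect_chd=0.17),
        TraitSpec(name="d_dimer", role="confounder", effect_egfr=-0.8, effect_chd=0.12),
        TraitSpec(name="von_willebrand_factor", role="confounder", effect_egfr=-0.7, effect_chd=0.10),
        TraitSpec(name="cotinine", role="confounder", effect_egfr=-0.8, effect_chd=0.20),
        TraitSpec(name="factor_viii", role="confounder", effect_egfr=-0.6, effect_chd=0.10),
        TraitSpec(
            name="percent_body_fat",
            role="confounder",
            effect_egfr=-1.2,
            effect_chd=0.12,
            studies=["ET2DS"],
        ),
        TraitSpec(name="ntprobnp", role="pathway_marker", effect_egfr=-0.35),
        TraitSpec(name="fev1", role="exposure_only", effect_egfr=1.0),
        TraitSpec(name="peak_flow", role="exposure_only", effect_egfr=0.8),
        TraitSpec(name="qt_interval", role="outcome_only", effect_chd=0.12),
        TraitSpec(name="cornell_product", role="outcome_only", effect_chd=0.10),
    ]
    fillers = [
        TraitSpec(name=f"trait_{k:02d}", role="null")
        for k in range(1, n_total - len(named) + 1)
    ]
    return named + fillers


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study conditions.

    A 7-study cohort of 13,145 subjects (2,249 of them CHD cases in
    expectation) with creatinine/eGFR measured in 4 studies, a 17-SNP
    instrument rescaled to explain 1.5% of eGFR variance, a 94-trait panel,
    a modest protective causal effect of eGFR on CHD (log OR −0.016 per
    ml/min/1.73m²), and a 63,746-case / 130,681-control outcome sample split
    over three pseudo-meta-analyses.
    """
    base = dict(
        study_names=["BRHS", "BWHHS", "CAPS", "ET2DS", "EAS", "ELSA", "WHII"],
        n_subjects_per_study=[2453, 2024, 1394, 1057, 855, 1985, 3377],
        egfr_studies=["BRHS", "BWHHS", "CAPS", "ET2DS"],
        snps=[
            SnpSpec(id=sid, freq=f, egfr_effect=eff) for sid, f, eff in DEFAULT_SNPS
        ],
        target_score_r2=0.015,
        trait_spec=default_trait_panel(),
        true_causal_logor_per_egfr_unit=-0.016,
        baseline_chd_logodds=-0.45,
        egfr_mean=70.0,
        egfr_noise_sd=15.0,
        outcome_sample=OutcomeSampleSpec(
            n_cases=63746,
            n_controls=130681,
            availability=DEFAULT_AVAILABILITY,
        ),
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)
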