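"""Shared state for the numbered analysis scripts.

Every script regenerates the same synthetic study deterministically from
``STUDY_SEED`` via the package's simulator, so the scripts can be run in
any order and leave no intermediate data files behind; only small result
tables are written under ``results/``.
"""

from pathlib import Path

from egfr_mr.config import default_config
from egfr_mr.phenotypes import add_egfr
from egfr_mr.simulate import generate_cohort, generate_outcome_summary

STUDY_SEED = 1

RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_config(seed: int = STUDY_SEED):
    return default_config(seed=seed)


def load_cohort(seed: int = STUDY_SEED):
    cfg = study_config(seed)
    cohort = generate_cohort(cfg)
    cohort.phenotypes = add_egfr(cohort.phenotypes)
    return cfg, cohort


def load_outcome_summary(seed: int = STUDY_SEED):
    return generate_outcome_summary(study_config(seed))


def outdir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
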