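"""Plain-text readers and writers for the pipeline's tabular interfaces.

Dialects:

* phenotype table — CSV, one header row, missing values as empty fields;
* genotype matrix — TSV, ``subject_id`` plus one column per SNP with allele
  counts in {0, 1, 2} (empty = missing);
* outcome summary statistics — TSV with the fixed header
  ``snp_id effect_allele other_allele beta se n_cases n_controls source``
  where ``beta`` is a natural-log odds ratio for binary outcomes (an OR
  column can be ingested via ``or_column``);
* instrument weights — TSV ``snp_id increasing_allele other_allele w se_w
  source``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SUMMARY_COLUMNS = [
    "snp_id",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "n_cases",
    "n_controls",
    "source",
]


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=True, na_rep="")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    out = genotypes.copy()
    # integer counts where observed, empty where missing
    out = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=True)


def read_genotypes(path) -> pd.DataFrame:
    g = pd.read_csv(path, sep="\t", index_col="subject_id")
    return g.astype(float)


def write_summary_stats(summary: pd.DataFrame, path) -> None:
    summary[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(path, or_column: str | None = None) -> pd.DataFrame:
    """Read outcome summary statistics; ``or_column`` names a column of
    odds ratios to be log-converted into ``beta``."""
    df = pd.read_csv(path, sep="\t")
    if or_column is not None:
        if or_column not in df:
            raise KeyError(f"OR column {or_column!r} not found")
        df["beta"] = np.log(df[or_column].astype(float))
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-stats file missing columns: {missing}")
    if (df["se"] <= 0).any():
        raise ValueError("summary standard errors must be positive")
    return df[SUMMARY_COLUMNS]


def write_weights(weights: pd.DataFrame, path) -> None:
    out = weights.reset_index()[
        ["snp_id", "increasing_allele", "other_allele", "w", "se_w", "source"]
    ]
    out.to_csv(path, sep="\t", index=False)


def read_weights(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("snp_id")
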