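"""Analytic power for two-sample MR with a binary outcome.

Under the asymptotic normal approximation, a score explaining a fraction R²
of the exposure variance, tested against a case/control outcome sample of
total size N with case fraction K, yields a causal-effect z-statistic with
non-centrality::

    sqrt(NCP) = |ln OR| * sqrt( N * R² * K * (1 - K) )

for a hypothesised causal odds ratio OR per exposure unit (on the scale on
which R² is defined).  Two-sided power at level alpha is
Phi(sqrt(NCP) − z_{1−alpha/2}) + Phi(−sqrt(NCP) − z_{1−alpha/2}); at OR = 1
this reduces to alpha exactly, and power is symmetric in OR ↔ 1/OR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def binary_outcome_power(
    n_total: float,
    case_fraction: float,
    r_squared: float,
    causal_or: float,
    alpha: float = 0.05,
) -> float:
    """Two-sided power to detect a causal odds ratio ``causal_or``."""
    if causal_or <= 0:
        raise ValueError("causal_or must be positive")
    if not (0 < case_fraction < 1):
        raise ValueError("case_fraction must lie in (0, 1)")
    if not (0 < r_squared < 1):
        raise ValueError("r_squared must lie in (0, 1)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    ncp_sqrt = abs(np.log(causal_or)) * np.sqrt(
        n_total * r_squared * case_fraction * (1.0 - case_fraction)
    )
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(ncp_sqrt - z) + stats.norm.cdf(-ncp_sqrt - z))


def power_curve(
    or_grid,
    n_total: float,
    case_fraction: float,
    r_squared: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Power over a grid of hypothesised causal odds ratios."""
    grid = np.asarray(or_grid, dtype=float)
    power = [
        binary_outcome_power(n_total, case_fraction, r_squared, o, alpha=alpha)
        for o in grid
    ]
    return pd.DataFrame({"causal_or": grid, "power": power})
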