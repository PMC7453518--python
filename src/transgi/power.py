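"""Analytic power for the instrument-to-CpG test.

The instrument explains ``r2_gi`` of the variance in expression; a trans
effect of ``effect_sd`` standard deviations of methylation per standard
deviation of expression then leaves the instrument explaining

    r2_m = effect_sd^2 * r2_gi / (effect_sd^2 * r2_gi + 1)

of the methylation variance (non-genetic variance normalized to 1). Power is
the upper-tail probability of a noncentral F(1, n - 2) with noncentrality
``n * r2_m / (1 - r2_m)`` beyond the central critical value at ``alpha``.
The denominator df deliberately ignores covariates (slightly conservative).

For the neighbor-corrected analysis the same formula is evaluated at the
partial R^2 of the instrument given the neighboring instruments.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

__all__ = ["analytic_power", "power_profile"]


def analytic_power(n: int, r2_gi: float, effect_sd: float, alpha: float) -> float:
    """Power of the two-sided instrument-to-CpG test at level ``alpha``."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if not (0.0 <= r2_gi < 1.0):
        raise ValueError("r2_gi must be in [0, 1)")
    if n <= 3:
        raise ValueError("n must exceed 3")
    a = effect_sd * effect_sd * r2_gi
    r2_m = a / (a + 1.0)
    ncp = n * r2_m / (1.0 - r2_m)
    dfd = n - 2
    crit = stats.f.isf(alpha, 1, dfd)
    if ncp == 0.0:
        return float(alpha)
    return float(stats.ncf.sf(crit, 1, dfd, ncp))


def power_profile(
    summaries: pd.DataFrame,
    n: int,
    effect_grid: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0),
    alpha: float = 1.4e-11,
) -> pd.DataFrame:
    """Per-gene power table for both analysis modes.

    ``summaries`` must carry ``gene``, ``r2_marginal`` and ``r2_partial``
    columns (instrument strength before and after accounting for neighboring
    instruments). One output row per gene per mode, with one power column per
    effect size on the grid.
    """
    rows = []
    for _, s in summaries.iterrows():
        for mode, col in (("uncorrected", "r2_marginal"), ("corrected", "r2_partial")):
            r2 = float(s[col])
            row = {"gene": s["gene"], "mode": mode, "r2": r2, "n": n, "alpha": alpha}
            for e in effect_grid:
                r2c = min(max(r2, 0.0), 1.0 - 1e-12)
                row[f"power_{e:g}"] = analytic_power(n, r2c, e, alpha)
            rows.append(row)
    return pd.DataFrame(rows)
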