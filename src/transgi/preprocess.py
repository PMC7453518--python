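"""Preprocessing primitives: expression filtering, rank-based inverse normal
transformation, principal components, and covariate design matrices.

All matrices follow the samples x features orientation used throughout the
package.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_expressed",
    "rank_inverse_normal",
    "compute_pcs",
    "PCModel",
    "fit_pcs",
    "build_design",
]

_BLOM_OFFSET = 3.0 / 8.0


def filter_expressed(
    counts: pd.DataFrame,
    min_median_cpm: float = 1.0,
    biotypes: pd.Series | None = None,
    allowed_biotypes: tuple[str, ...] = ("protein_coding", "lincRNA"),
) -> list[str]:
    """Return gene ids whose median counts-per-million is >= ``min_median_cpm``.

    Parameters
    ----------
    counts:
        Samples x genes matrix of non-negative expression counts.
    min_median_cpm:
        Inclusive lower bound on the per-gene median CPM.
    biotypes:
        Optional per-gene biotype labels; when given, genes whose biotype is
        not in ``allowed_biotypes`` are removed before the CPM filter.
    """
    if (counts.values < 0).any():
        raise ValueError("expression counts must be non-negative")
    libsize = counts.sum(axis=1)
    if (libsize == 0).any():
        bad = list(counts.index[libsize == 0])
        raise ValueError(f"all-zero library for samples: {bad}")
    cpm = counts.div(libsize, axis=0) * 1e6
    keep = cpm.median(axis=0) >= min_median_cpm
    genes = counts.columns[keep]
    if biotypes is not None:
        ok = biotypes.reindex(genes).isin(allowed_biotypes)
        genes = genes[ok.to_numpy(dtype=bool)]
    return list(genes)


def _rint_vector(x: np.ndarray, c: float = _BLOM_OFFSET) -> np.ndarray:
    n = x.size
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - c) / (n - 2 * c + 1))


def rank_inverse_normal(
    values: pd.DataFrame | pd.Series,
    cohorts: pd.Series | None = None,
) -> pd.DataFrame | pd.Series:
    """Rank-based inverse normal transform, applied within each cohort.

    Uses the Blom offset (c = 3/8): ``v -> Phi^-1((rank - c) / (n - 2c + 1))``
    with average ranks for ties. Raises if any column is constant within a
    cohort (the transform is undefined there).
    """
    squeeze = isinstance(values, pd.Series)
    frame = values.to_frame() if squeeze else values
    if cohorts is None:
        cohorts = pd.Series(0, index=frame.index)
    cohorts = cohorts.reindex(frame.index)
    out = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for label, idx in frame.groupby(cohorts).groups.items():
        block = frame.loc[idx]
        n_distinct = block.nunique(axis=0)
        if (n_distinct < 2).any():
            bad = list(block.columns[n_distinct < 2])
            raise ValueError(
                f"constant values within cohort {label!r} for: {bad[:5]}"
            )
        out.loc[idx] = np.apply_along_axis(_rint_vector, 0, block.to_numpy(float))
    return out.iloc[:, 0] if squeeze else out


class PCModel:
    """Centered SVD principal components, fit on one sample set and
    projectable onto another (used for train-fit / test-project covariates)."""

    def __init__(self, mean: np.ndarray, components: np.ndarray, explained_variance: np.ndarray):
        self.mean = mean
        self.components = components  # k x features
        self.explained_variance = explained_variance

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        scores = (matrix.to_numpy(float) - self.mean) @ self.components.T
        cols = [f"PC{i + 1}" for i in range(self.components.shape[0])]
        return pd.DataFrame(scores, index=matrix.index, columns=cols)


def fit_pcs(matrix: pd.DataFrame, k: int = 5) -> PCModel:
    """Fit a :class:`PCModel` with up to ``k`` components on ``matrix``."""
    x = matrix.to_numpy(float)
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = max(xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if k > rank:
        warnings.warn(f"requested {k} components but rank is {rank}; returning {rank}")
        k = rank
    comps = vt[:k]
    # sign convention: the largest-magnitude loading of each component is positive
    for i in range(k):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    ev = (s[:k] ** 2) / max(x.shape[0] - 1, 1)
    return PCModel(mean, comps, ev)


def compute_pcs(matrix: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Top-``k`` principal component scores of a samples x features matrix."""
    model = fit_pcs(matrix, k)
    return model.transform(matrix)


def build_design(
    covariates: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Build a numeric covariate design matrix from a covariate table.

    Categorical columns (``cohort`` or any non-numeric column) are one-hot
    encoded dropping the first level; cell-fraction columns (prefix ``cf_``)
    drop the last one since fractions sum to one. Numeric columns pass
    through unchanged. The intercept column is named ``const``.
    """
    parts: list[pd.DataFrame] = []
    if add_intercept:
        parts.append(pd.DataFrame({"const": 1.0}, index=covariates.index))
    cf_cols = [c for c in covariates.columns if c.startswith("cf_")]
    for col in covariates.columns:
        s = covariates[col]
        if col == "cohort" or not pd.api.types.is_numeric_dtype(s):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
        elif col in cf_cols and col == cf_cols[-1] and len(cf_cols) > 1:
            continue  # fractions sum to 1: drop the last to keep full rank
        else:
            parts.append(s.astype(float).to_frame())
    if pcs is not None:
        parts.append(pcs)
    design = pd.concat(parts, axis=1)
    return design
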