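"""Multi-SNP genetic instruments for gene expression.

A per-gene instrument is built on a training split by a two-step LASSO:
step 1 selects cis SNPs at the cross-validation-minimizing penalty, step 2
refits on the selected SNPs only and applies the one-standard-error rule
(largest penalty whose CV error is within one SE of the minimum, constrained
to keep at least one non-zero SNP weight). Covariates enter both steps
unpenalized; this is implemented exactly by partialling them out of the
response and the dosages before the penalized fit (Frisch-Waugh-Lovell).

The instrument is then scored on the disjoint test split: an ANOVA
F-statistic for its added explanatory power over the covariates, the partial
R^2, and a strict F > 10 validity gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

__all__ = [
    "SplitAssignment",
    "GeneticInstrument",
    "split_train_test",
    "select_cis_snps",
    "fit_instrument",
    "validate_instrument",
    "instrument_is_valid",
    "predict_gi",
    "instruments_to_frames",
]

logger = logging.getLogger(__name__)

F_VALID_CUTOFF = 10.0
DEFAULT_CIS_WINDOW = 100_000


@dataclass
class SplitAssignment:
    """Sample-to-{train,test} mapping stratified by cohort and sex."""

    assignments: pd.Series  # sample id -> "train" / "test"
    ratio: float
    seed: int

    @property
    def train(self) -> pd.Index:
        return self.assignments.index[self.assignments == "train"]

    @property
    def test(self) -> pd.Index:
        return self.assignments.index[self.assignments == "test"]


@dataclass
class GeneticInstrument:
    gene: str
    snp_ids: list[str]
    weights: np.ndarray  # per dosage unit, aligned with snp_ids
    lambda1: float
    lambda2: float
    n_train: int
    f_test: float | None = None
    partial_r2: float | None = None
    valid: bool | None = None
    reason: str = ""
    calibration: float | None = None  # test-set expression-per-GI-unit slope
    extra: dict = field(default_factory=dict)


def instrument_is_valid(f_test: float | None) -> bool:
    """Strict validity gate: F-statistic strictly greater than 10."""
    return bool(f_test is not None and np.isfinite(f_test) and f_test > F_VALID_CUTOFF)


def split_train_test(
    samples: pd.Index | list[str],
    cohorts: pd.Series,
    sexes: pd.Series,
    ratio: float = 1.0 / 3.0,
    seed: int = 0,
) -> SplitAssignment:
    """Assign each sample to train/test, with the train fraction equal to
    ``ratio`` (to within one sample) inside every cohort x sex stratum."""
    samples = pd.Index(samples)
    if len(samples) == 0:
        raise ValueError("empty sample list")
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must be in (0, 1)")
    cohorts = cohorts.reindex(samples)
    sexes = sexes.reindex(samples)
    if cohorts.isna().any() or sexes.isna().any():
        raise ValueError("every sample needs a cohort and a sex label")
    rng = np.random.default_rng(seed)
    labels = pd.Series("test", index=samples, dtype=object)
    strata = pd.DataFrame({"cohort": cohorts, "sex": sexes})
    for _, idx in sorted(
        strata.groupby(["cohort", "sex"]).groups.items(), key=lambda kv: str(kv[0])
    ):
        members = list(idx)
        n_train = int(round(ratio * len(members)))
        order = rng.permutation(len(members))
        chosen = [members[i] for i in order[:n_train]]
        labels.loc[chosen] = "train"
    return SplitAssignment(assignments=labels, ratio=ratio, seed=seed)


def select_cis_snps(
    gene: str,
    genes: pd.DataFrame,
    snps: pd.DataFrame,
    window: int = DEFAULT_CIS_WINDOW,
) -> list[str]:
    """SNPs on the gene's chromosome within the closed interval
    ``[min(TSS, TES) - window, max(TSS, TES) + window]`` (boundaries in)."""
    if gene not in genes.index:
        raise KeyError(f"gene {gene!r} absent from annotation")
    row = genes.loc[gene]
    lo = min(row["tss"], row["tes"]) - window
    hi = max(row["tss"], row["tes"]) + window
    mask = (snps["chrom"] == row["chrom"]) & (snps["pos"] >= lo) & (snps["pos"] <= hi)
    return list(snps.index[mask])


# ---------------------------------------------------------------------------
# two-step LASSO
# ---------------------------------------------------------------------------

def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return y - q @ (q.T @ y)


def _cv_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Deterministic folds: seeded shuffle then modulo assignment."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[perm] = np.arange(n) % k
    return folds


def _alpha_grid(x: np.ndarray, y: np.ndarray, n_alphas: int, eps: float) -> np.ndarray:
    """Descending geometric penalty grid from the smallest all-zero penalty."""
    n = x.shape[0]
    alpha_max = np.max(np.abs(x.T @ y)) / n
    alpha_max = max(alpha_max, 1e-12)
    return np.geomspace(alpha_max, alpha_max * eps, n_alphas)


def _cv_mse(
    x: np.ndarray, y: np.ndarray, alphas: np.ndarray, folds: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-alpha mean CV MSE and its standard error over folds."""
    fold_mse = np.empty((k, alphas.size))
    for f in range(k):
        tr = folds != f
        te = ~tr
        _, coefs, _ = lasso_path(x[tr], y[tr], alphas=alphas)
        pred = x[te] @ coefs + y[tr].mean()
        fold_mse[f] = ((pred - y[te][:, None]) ** 2).mean(axis=0)
    mean = fold_mse.mean(axis=0)
    se = fold_mse.std(axis=0, ddof=1) / np.sqrt(k)
    return mean, se


def fit_instrument(
    dosages: pd.DataFrame,
    expression: pd.Series,
    covariates: pd.DataFrame,
    cis_snps: list[str],
    cv_folds: int = 5,
    seed: int = 0,
    n_alphas: int = 60,
    eps: float = 1e-3,
    gene: str | None = None,
) -> GeneticInstrument | None:
    """Fit the two-step LASSO instrument on training samples.

    Returns ``None`` (gene skipped) when there are no cis SNPs, all cis SNPs
    are constant, or step 1 selects nothing. Weights are reported per dosage
    unit; penalized predictors are standardized internally so the penalty is
    scale-free.
    """
    gene = gene or str(expression.name)
    if not cis_snps:
        logger.info("gene %s skipped: no cis SNPs", gene)
        return None
    d = dosages.loc[:, cis_snps].to_numpy(float)
    y = expression.to_numpy(float)
    xc = np.column_stack([np.ones(len(y)), covariates.to_numpy(float)])
    # unpenalized covariates: partial them out of y and D (exact for lasso)
    y_r = _residualize(y, xc)
    d_r = _residualize(d, xc)
    sds = d_r.std(axis=0)
    keep = sds > 1e-12
    if not keep.any():
        logger.info("gene %s skipped: all cis SNPs constant", gene)
        return None
    snp_ids = [s for s, k in zip(cis_snps, keep) if k]
    d_s = d_r[:, keep] / sds[keep]
    n = len(y)
    folds = _cv_folds(n, cv_folds, seed)

    # step 1: CV-min lambda on all cis SNPs
    grid1 = _alpha_grid(d_s, y_r, n_alphas, eps)
    alphas1, coefs1, _ = lasso_path(d_s, y_r, alphas=grid1)
    mean1, _ = _cv_mse(d_s, y_r, alphas1, folds, cv_folds)
    # ties broken toward the sparser (larger-alpha) model: first index wins
    i1 = int(np.argmin(mean1))
    lambda1 = float(alphas1[i1])
    active = np.abs(coefs1[:, i1]) > 0
    if not active.any():
        logger.info("gene %s skipped: step-1 selection empty", gene)
        return None

    # step 2: one-SE rule on the selected SNPs, restricted to alphas >= lambda1
    # so the final penalty is never smaller than the CV-min one
    d2 = d_s[:, active]
    alphas2_full = _alpha_grid(d2, y_r, n_alphas, eps)
    alphas2 = np.unique(np.concatenate([alphas2_full[alphas2_full >= lambda1],
                                        [lambda1]]))[::-1]
    _, coefs2, _ = lasso_path(d2, y_r, alphas=alphas2)
    mean2, se2 = _cv_mse(d2, y_r, alphas2, folds, cv_folds)
    nnz = (np.abs(coefs2) > 0).sum(axis=0)
    i_min = int(np.argmin(mean2))
    threshold = mean2[i_min] + se2[i_min]
    ok = (mean2 <= threshold) & (nnz >= 1)
    if ok.any():
        i2 = int(np.argmax(ok))  # alphas descend: first qualifying = largest
    else:
        with_snp = np.flatnonzero(nnz >= 1)
        if with_snp.size == 0:
            logger.info("gene %s skipped: no penalty retains a SNP", gene)
            return None
        i2 = int(with_snp[0])  # largest alpha retaining >= 1 SNP
    lambda2 = float(alphas2[i2])
    w_std = coefs2[:, i2]
    sel = np.abs(w_std) > 0
    ids = [s for s, k in zip(snp_ids, active) if k]
    ids = [s for s, k in zip(ids, sel) if k]
    weights = (w_std[sel] / sds[keep][active][sel])  # back to dosage scale
    return GeneticInstrument(
        gene=gene,
        snp_ids=ids,
        weights=np.asarray(weights, dtype=float),
        lambda1=lambda1,
        lambda2=lambda2,
        n_train=n,
    )


def predict_gi(gi: GeneticInstrument, dosages: pd.DataFrame) -> pd.Series:
    """GI = D @ beta: weighted sum of dosages."""
    vals = dosages.loc[:, gi.snp_ids].to_numpy(float) @ gi.weights
    return pd.Series(vals, index=dosages.index, name=gi.gene)


def validate_instrument(
    dosages: pd.DataFrame,
    expression: pd.Series,
    covariates: pd.DataFrame,
    gi: GeneticInstrument,
) -> GeneticInstrument:
    """Score the instrument on the test split.

    ``F = ((RSS_reduced - RSS_full) / 1) / (RSS_full / (n - p - 1))``
    comparing covariates-only against covariates + GI;
    ``partial_r2 = (RSS_reduced - RSS_full) / RSS_reduced``;
    valid iff F > 10 strictly. A constant GI yields ``valid=False`` with a
    reason code. Also stores the covariate-adjusted slope of expression on
    the GI (used to convert scan effects to the per-SD-expression scale).
    """
    g = predict_gi(gi, dosages).to_numpy(float)
    y = expression.to_numpy(float)
    x0 = np.column_stack([np.ones(len(y)), covariates.to_numpy(float)])
    if np.std(g) < 1e-12:
        gi.f_test = np.nan
        gi.partial_r2 = np.nan
        gi.valid = False
        gi.reason = "constant_gi"
        return gi
    x1 = np.column_stack([x0, g])
    b0, rss0 = _ols_rss(x0, y)
    b1, rss1 = _ols_rss(x1, y)
    df = len(y) - x1.shape[1]
    gi.f_test = float(((rss0 - rss1) / 1.0) / (rss1 / df))
    gi.partial_r2 = float((rss0 - rss1) / rss0) if rss0 > 0 else np.nan
    gi.valid = instrument_is_valid(gi.f_test)
    gi.calibration = float(b1[-1])
    if not gi.valid:
        gi.reason = gi.reason or "weak_instrument"
    return gi


def _ols_rss(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, res, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, float(resid @ resid)


def instruments_to_frames(
    instruments: list[GeneticInstrument],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(weights table, per-gene summary table) for the instrument store."""
    w_rows = []
    s_rows = []
    for gi in instruments:
        for sid, w in zip(gi.snp_ids, gi.weights):
            w_rows.append({"gene": gi.gene, "snp": sid, "weight": w})
        s_rows.append(
            {
                "gene": gi.gene,
                "n_snps": len(gi.snp_ids),
                "lambda1": gi.lambda1,
                "lambda2": gi.lambda2,
                "n_train": gi.n_train,
                "f_test": gi.f_test,
                "partial_r2": gi.partial_r2,
                "valid": gi.valid,
                "reason": gi.reason,
                "calibration": gi.calibration,
            }
        )
    weights = pd.DataFrame(w_rows, columns=["gene", "snp", "weight"])
    summary = pd.DataFrame(
        s_rows,
        columns=["gene", "n_snps", "lambda1", "lambda2", "n_train", "f_test",
                 "partial_r2", "valid", "reason", "calibration"],
    )
    return weights, summary
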