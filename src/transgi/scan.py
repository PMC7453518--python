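"""Directed genome-wide trans association scan.

Tests every valid genetic instrument against every trans CpG
(different chromosome, or more than 10 Mb from both TSS and TES) with
ordinary least squares, pools the resulting z-scores, and rescales them with
a three-component Gaussian-mixture model of the z ensemble (central null
component N(bias, inflation^2) plus two tail components, fit by EM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import GeneticInstrument, predict_gi

__all__ = [
    "ScanCalibration",
    "linear_assoc",
    "trans_pairs",
    "run_scan",
    "correct_bias_inflation",
    "bonferroni_threshold",
    "z_from_t",
]

logger = logging.getLogger(__name__)

DEFAULT_TRANS_DISTANCE = 10_000_000

STAGE_FLAGS = [
    "marginal_sig",
    "conditional_sig",
    "dropped_corr95",
    "dropped_residual_pleiotropy",
    "dropped_longrange",
    "dropped_wbc",
    "final",
]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """``alpha / n_tests``."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _check_design(x: np.ndarray, names: list[str] | None = None) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the offending columns via pivoted-QR-style diagnostics
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        tol = x.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
        bad_idx = np.flatnonzero(diag <= tol)
        if names is not None:
            bad = [names[i] for i in bad_idx]
        else:
            bad = list(bad_idx)
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear columns: {bad}")


def linear_assoc(
    y: np.ndarray | pd.Series,
    x: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
    names: list[str] | None = None,
) -> tuple[float, float, float, float]:
    """OLS of ``y`` on ``x`` plus covariates; returns (beta, se, t, p).

    The p-value is two-sided from the t distribution with ``n - p - 1``
    degrees of freedom where ``p`` counts all non-intercept predictors.
    Raises a ``LinAlgError`` naming collinear columns on a rank-deficient
    design.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    parts = [np.ones((n, 1))]
    col_names = ["const"]
    if covariates is not None:
        c = covariates.to_numpy(float) if hasattr(covariates, "to_numpy") else np.asarray(covariates, float)
        if c.ndim == 1:
            c = c[:, None]
        parts.append(c)
        if hasattr(covariates, "columns"):
            col_names += list(covariates.columns)
        else:
            col_names += [f"c{i}" for i in range(c.shape[1])]
    parts.append(x[:, None])
    col_names.append("x")
    design = np.column_stack(parts)
    if n <= design.shape[1] + 1:
        raise ValueError("not enough samples for the design")
    _check_design(design, names or col_names)
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    df = n - design.shape[1]
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    b = float(beta[-1])
    if se == 0.0:
        return b, 0.0, np.inf if b != 0 else 0.0, 1.0 if b == 0 else 0.0
    t = b / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return b, se, float(t), float(min(max(p, np.nextafter(0, 1)), 1.0))


def trans_pairs(
    genes: pd.DataFrame,
    probes: pd.DataFrame,
    min_distance: int = DEFAULT_TRANS_DISTANCE,
) -> Iterator[tuple[str, str]]:
    """Yield (gene, probe) pairs satisfying the trans criterion: probe on a
    different chromosome, or strictly more than ``min_distance`` from both
    TSS and TES (and outside the gene body)."""
    for gene, grow in genes.iterrows():
        lo, hi = min(grow["tss"], grow["tes"]), max(grow["tss"], grow["tes"])
        for probe, prow in probes.iterrows():
            if prow["chrom"] != grow["chrom"]:
                yield gene, probe
                continue
            pos = prow["pos"]
            if lo <= pos <= hi:
                continue
            d = min(abs(pos - grow["tss"]), abs(pos - grow["tes"]))
            if d > min_distance:
                yield gene, probe


def z_from_t(t: np.ndarray, df: int) -> np.ndarray:
    """Signed normal quantile of the two-sided t-test p-value.

    Falls back to the t value itself when the tail probability underflows
    (the two agree to float precision in that regime for the df used here).
    """
    t = np.asarray(t, dtype=float)
    sf = stats.t.sf(np.abs(t), df)
    z = np.where(sf > 1e-280, stats.norm.isf(np.clip(sf, 1e-300, 1.0)), np.abs(t))
    return np.sign(t) * z


def run_scan(
    instruments: list[GeneticInstrument],
    dosages: pd.DataFrame,
    methylation: pd.DataFrame,
    covariates: pd.DataFrame,
    genes: pd.DataFrame,
    probes: pd.DataFrame,
    min_distance: int = DEFAULT_TRANS_DISTANCE,
) -> pd.DataFrame:
    """One association record per (valid GI, trans probe) pair.

    ``covariates`` is a numeric design matrix (no intercept column needed;
    one is added). All matrices must share the sample index. Effects are per
    unit GI; ``phi_expr`` rescales them to the per-unit-expression scale
    using each instrument's test-set calibration slope.
    """
    for m in (methylation, covariates):
        if not m.index.equals(dosages.index):
            raise ValueError("sample indices are misaligned across matrices")
    valid = [gi for gi in instruments if gi.valid]
    n = len(dosages)
    xc = np.column_stack([np.ones(n), covariates.to_numpy(float)])
    q, _ = np.linalg.qr(xc)

    def resid(m: np.ndarray) -> np.ndarray:
        return m - q @ (q.T @ m)

    meth = methylation.to_numpy(float)
    meth_r = resid(meth)
    meth_ss = (meth_r**2).sum(axis=0)
    df = n - xc.shape[1] - 1
    pair_map: dict[str, list[str]] = {}
    probe_cols = {p: j for j, p in enumerate(methylation.columns)}
    for gene, probe in trans_pairs(genes, probes, min_distance):
        if probe in probe_cols:
            pair_map.setdefault(gene, []).append(probe)
    records = []
    for gi in valid:
        targets = pair_map.get(gi.gene, [])
        if not targets:
            continue
        g = predict_gi(gi, dosages).to_numpy(float)
        g_r = resid(g)
        g_ss = float(g_r @ g_r)
        if g_ss <= 1e-12:
            logger.warning("GI for %s constant after covariate adjustment", gi.gene)
            continue
        cols = np.array([probe_cols[p] for p in targets])
        xty = meth_r[:, cols].T @ g_r
        beta = xty / g_ss
        rss = meth_ss[cols] - beta * xty
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / df / g_ss)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        p = np.clip(2.0 * stats.t.sf(np.abs(t), df), np.nextafter(0, 1), 1.0)
        z = z_from_t(t, df)
        cal = gi.calibration if gi.calibration else np.nan
        for j, probe in enumerate(targets):
            records.append(
                (gi.gene, probe, beta[j], beta[j] / cal if cal else np.nan,
                 se[j], t[j], p[j], z[j])
            )
    out = pd.DataFrame(
        records,
        columns=["gene", "probe", "phi", "phi_expr", "se", "t", "p_raw", "z"],
    )
    for flag in STAGE_FLAGS:
        out[flag] = False
    out["p_corrected"] = np.nan
    return out


# ---------------------------------------------------------------------------
# bias / inflation correction of the z ensemble
# ---------------------------------------------------------------------------

@dataclass
class ScanCalibration:
    """Null-component location (bias) and scale (inflation) of the z ensemble."""

    bias: float
    inflation: float
    pi0: float
    n_tests: int
    converged: bool = True
    fallback: bool = False

    def correct_z(self, z: np.ndarray | pd.Series) -> np.ndarray:
        return (np.asarray(z, dtype=float) - self.bias) / self.inflation

    def corrected_p(self, z: np.ndarray | pd.Series) -> np.ndarray:
        zc = self.correct_z(z)
        return np.clip(2.0 * stats.norm.sf(np.abs(zc)), np.nextafter(0, 1), 1.0)


def _em_three_component(
    z: np.ndarray, max_iter: int = 1000, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """EM for a 3-component Gaussian mixture with a dominant central
    component. Returns (weights, means, sds, converged)."""
    med = float(np.median(z))
    mad = float(stats.median_abs_deviation(z, scale="normal"))
    if mad <= 0:
        mad = float(np.std(z)) or 1.0
    pis = np.array([0.90, 0.05, 0.05])
    mus = np.array([med, med - 4.0 * mad, med + 4.0 * mad])
    sds = np.array([mad, 2.0 * mad, 2.0 * mad])
    ll_old = -np.inf
    converged = False
    n = z.size
    for _ in range(max_iter):
        logp = np.stack(
            [np.log(pis[k]) + stats.norm.logpdf(z, mus[k], sds[k]) for k in range(3)]
        )
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.mean())
        resp = np.exp(logp - lse)
        nk = resp.sum(axis=1)
        pis = np.maximum(nk / n, 1e-12)
        pis /= pis.sum()
        mus = (resp @ z) / np.maximum(nk, 1e-12)
        for k in range(3):
            var = float(resp[k] @ (z - mus[k]) ** 2) / max(nk[k], 1e-12)
            sds[k] = np.sqrt(max(var, 1e-8))
        # keep the side components in the tails and at least as wide as the
        # null (alternatives are effect distributions convolved with the
        # null noise) so they cannot absorb the null's shoulders
        mus[1] = min(mus[1], mus[0] - 3.0 * sds[0])
        mus[2] = max(mus[2], mus[0] + 3.0 * sds[0])
        sds[1] = max(sds[1], sds[0])
        sds[2] = max(sds[2], sds[0])
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    return pis, mus, sds, converged


def correct_bias_inflation(
    z: np.ndarray | pd.Series,
    min_n: int = 10_000,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> ScanCalibration:
    """Estimate bias and inflation of the null component of a z ensemble.

    Fits the three-component mixture by EM; the central component's mean and
    standard deviation are the bias and inflation. On EM non-convergence the
    median/MAD estimates are used and flagged.
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < min_n:
        raise ValueError(
            f"need at least {min_n} finite z values for stable estimation, got {z.size}"
        )
    pis, mus, sds, converged = _em_three_component(z, max_iter=max_iter, tol=tol)
    if converged:
        k0 = int(np.argmax(pis))
        bias, inflation, pi0 = float(mus[k0]), float(sds[k0]), float(pis[k0])
        fallback = False
    else:
        logger.warning("EM did not converge; falling back to median/MAD estimates")
        bias = float(np.median(z))
        inflation = float(stats.median_abs_deviation(z, scale="normal"))
        pi0 = 1.0
        fallback = True
    return ScanCalibration(
        bias=bias,
        inflation=inflation,
        pi0=pi0,
        n_tests=int(z.size),
        converged=converged,
        fallback=fallback,
    )


def apply_calibration(records: pd.DataFrame, cal: ScanCalibration) -> pd.DataFrame:
    """Attach corrected z and p columns to a scan record table."""
    out = records.copy()
    out["z_corrected"] = cal.correct_z(out["z"].to_numpy())
    out["p_corrected"] = cal.corrected_p(out["z"].to_numpy())
    return out
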