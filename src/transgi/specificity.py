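"""LD/pleiotropy specificity cascade.

Turns directed marginal associations into gene-specific ones through four
stages, each reusing the scan-wide calibration and significance threshold:

1. neighbor conditioning — refit each significant pair adding the pruned
   genetic instruments of genes within 1 Mb as covariates; index genes whose
   GI correlates with any neighbor GI above 0.95 are excluded outright;
2. residual pleiotropy — drop genes whose GI still predicts (F > 5) the
   expression of a neighboring significant gene with overlapping gene-level
   target CpGs;
3. long-range joint models — for CpGs hit by several genes from one
   chromosome, refit all those instruments jointly;
4. white-blood-cell variants — refit with a supplied SNP-dosage list as
   additional covariates.

Record flags are cumulative and mutually exclusive among the ``dropped_*``
columns; survivors of the last stage are flagged ``final``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, linalg

from .instruments import GeneticInstrument, predict_gi
from .scan import ScanCalibration, z_from_t

__all__ = [
    "NeighborContext",
    "prune_correlated",
    "build_neighbor_contexts",
    "conditional_scan",
    "residual_pleiotropy_filter",
    "long_range_filter",
    "wbc_filter",
    "stage_accounting",
    "gi_matrix",
]

logger = logging.getLogger(__name__)

NEIGHBOR_WINDOW = 1_000_000
CORR_EXCLUDE = 0.95
PLEIOTROPY_F = 5.0
GENE_LEVEL_ALPHA = 0.05


@dataclass
class NeighborContext:
    gene: str
    neighbors: list[str] = field(default_factory=list)
    pruned: list[str] = field(default_factory=list)
    max_abs_r: float = 0.0


def _prune_from_corr(corr: np.ndarray, cutoff: float) -> list[int]:
    """Greedy pruning on a correlation matrix; returns retained indices.

    While any off-diagonal |r| exceeds the cutoff, consider the worst pair
    and drop the member with the larger mean absolute correlation to the
    other remaining columns (ties keep the earlier column).
    """
    keep = list(range(corr.shape[0]))
    a = np.abs(np.asarray(corr, dtype=float)).copy()
    np.fill_diagonal(a, 0.0)
    while len(keep) > 1:
        sub = a[np.ix_(keep, keep)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= cutoff:
            break
        mean_i = sub[i].sum() / (len(keep) - 1)
        mean_j = sub[j].sum() / (len(keep) - 1)
        drop = i if mean_i > mean_j else j if mean_j > mean_i else max(i, j)
        keep.pop(drop)
    return keep


def prune_correlated(gi: pd.DataFrame, cutoff: float = CORR_EXCLUDE) -> list[str]:
    """Greedily drop columns until all pairwise |r| <= cutoff; deterministic
    given the column order."""
    if gi.shape[1] == 0:
        raise ValueError("need at least one column")
    if gi.shape[1] == 1:
        return list(gi.columns)
    corr = np.corrcoef(gi.to_numpy(float), rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    keep = _prune_from_corr(corr, cutoff)
    return [gi.columns[i] for i in keep]


def gi_matrix(
    instruments: list[GeneticInstrument], dosages: pd.DataFrame
) -> pd.DataFrame:
    """Samples x genes matrix of GI values for all valid instruments."""
    cols = {gi.gene: predict_gi(gi, dosages) for gi in instruments if gi.valid}
    return pd.DataFrame(cols, index=dosages.index)


def build_neighbor_contexts(
    genes: pd.DataFrame,
    gis: pd.DataFrame,
    window: int = NEIGHBOR_WINDOW,
    cutoff: float = CORR_EXCLUDE,
) -> dict[str, NeighborContext]:
    """Neighbor sets (valid-GI genes whose TSS/TES lie within ``window`` of
    the index gene's TSS/TES, same chromosome, inclusive), their pruned
    subsets, and the max |r| between index GI and any unpruned neighbor GI.

    GI-GI correlations are Pearson, computed over all scan samples.
    """
    contexts: dict[str, NeighborContext] = {}
    have = [g for g in gis.columns if g in genes.index]
    ann = genes.loc[have]
    corr = (
        gis[have].corr().abs() if len(have) > 1 else pd.DataFrame(index=have, columns=have)
    )
    for gene in have:
        row = ann.loc[gene]
        lo = min(row["tss"], row["tes"]) - window
        hi = max(row["tss"], row["tes"]) + window
        nb = [
            other
            for other in have
            if other != gene
            and ann.loc[other, "chrom"] == row["chrom"]
            and (
                lo <= ann.loc[other, "tss"] <= hi or lo <= ann.loc[other, "tes"] <= hi
            )
        ]
        ctx = NeighborContext(gene=gene, neighbors=nb)
        if nb:
            ctx.max_abs_r = float(corr.loc[gene, nb].max())
            ctx.pruned = prune_correlated(gis[nb], cutoff) if len(nb) > 1 else list(nb)
        contexts[gene] = ctx
    return contexts


# ---------------------------------------------------------------------------
# shared refit machinery
# ---------------------------------------------------------------------------

def _drop_collinear(x: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop trailing-pivot columns until full rank (pivoted QR)."""
    if np.linalg.matrix_rank(x) == x.shape[1]:
        return x, names
    q, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = x.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    keep_piv = sorted(piv[: int((diag > tol).sum())])
    dropped = [names[i] for i in range(x.shape[1]) if i not in keep_piv]
    logger.info("dropping collinear columns: %s", dropped)
    return x[:, keep_piv], [names[i] for i in keep_piv]


def _refit_pairs(
    g: np.ndarray,
    meth: pd.DataFrame,
    probes: list[str],
    base: np.ndarray,
    base_names: list[str],
) -> pd.DataFrame:
    """Regress each probe on the GI given a base design (intercept included
    in ``base``); vectorized over probes. Returns phi/se/t/p/z per probe."""
    design, _ = _drop_collinear(base, base_names)
    q, _ = np.linalg.qr(design)
    g_r = g - q @ (q.T @ g)
    g_ss = float(g_r @ g_r)
    n = len(g)
    df = n - design.shape[1] - 1
    m = meth.loc[:, probes].to_numpy(float)
    m_r = m - q @ (q.T @ m)
    if g_ss <= 1e-12:
        # GI fully explained by the conditioning design
        return pd.DataFrame(
            {"probe": probes, "phi": 0.0, "se": np.nan, "t": 0.0, "p": 1.0, "z": 0.0}
        )
    xty = m_r.T @ g_r
    beta = xty / g_ss
    rss = np.maximum((m_r**2).sum(axis=0) - beta * xty, 0.0)
    se = np.sqrt(rss / df / g_ss)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), np.nextafter(0, 1), 1.0)
    z = z_from_t(t, df)
    return pd.DataFrame({"probe": probes, "phi": beta, "se": se, "t": t, "p": p, "z": z})


def _base_design(covariates: pd.DataFrame, extra: pd.DataFrame | None = None
                 ) -> tuple[np.ndarray, list[str]]:
    n = len(covariates)
    parts = [np.ones((n, 1)), covariates.to_numpy(float)]
    names = ["const"] + list(covariates.columns)
    if extra is not None and extra.shape[1] > 0:
        parts.append(extra.to_numpy(float))
        names += list(extra.columns)
    return np.column_stack(parts), names


# ---------------------------------------------------------------------------
# cascade stages
# ---------------------------------------------------------------------------

def conditional_scan(
    records: pd.DataFrame,
    gis: pd.DataFrame,
    methylation: pd.DataFrame,
    covariates: pd.DataFrame,
    contexts: dict[str, NeighborContext],
    calibration: ScanCalibration,
    threshold: float,
    corr_cutoff: float = CORR_EXCLUDE,
) -> pd.DataFrame:
    """Refit every marginally significant pair conditioning on the pruned
    neighbor GIs. Index genes whose GI correlates above ``corr_cutoff`` with
    any (unpruned) neighbor GI are flagged ``dropped_corr95``.

    Conditional significance reuses the scan-wide threshold on calibrated
    p-values; the calibration itself is not re-estimated.
    """
    out = records.copy()
    out["phi_cond"] = np.nan
    out["p_cond"] = np.nan
    out["z_cond"] = np.nan
    for gene, grp in out[out["marginal_sig"]].groupby("gene", sort=True):
        ctx = contexts.get(gene, NeighborContext(gene=gene))
        if ctx.max_abs_r > corr_cutoff:
            out.loc[grp.index, "dropped_corr95"] = True
            continue
        extra = gis[ctx.pruned] if ctx.pruned else None
        base, names = _base_design(covariates, extra)
        res = _refit_pairs(
            gis[gene].to_numpy(float), methylation, list(grp["probe"]), base, names
        )
        res.index = grp.index
        out.loc[grp.index, "phi_cond"] = res["phi"]
        out.loc[grp.index, "z_cond"] = res["z"]
        p_cal = calibration.corrected_p(res["z"].to_numpy())
        out.loc[grp.index, "p_cond"] = p_cal
        out.loc[grp.index, "conditional_sig"] = p_cal < threshold
    return out


def _added_f(
    y: np.ndarray, g: np.ndarray, base: np.ndarray, base_names: list[str]
) -> float:
    """ANOVA F for the added explanatory power of ``g`` over ``base``."""
    design, _ = _drop_collinear(base, base_names)
    q, _ = np.linalg.qr(design)
    y_r = y - q @ (q.T @ y)
    g_r = g - q @ (q.T @ g)
    g_ss = float(g_r @ g_r)
    if g_ss <= 1e-12:
        return 0.0
    beta = float(y_r @ g_r) / g_ss
    rss0 = float(y_r @ y_r)
    rss1 = rss0 - beta * beta * g_ss
    df = len(y) - design.shape[1] - 1
    if rss1 <= 0:
        return np.inf
    return ((rss0 - rss1) / 1.0) / (rss1 / df)


def residual_pleiotropy_filter(
    records: pd.DataFrame,
    gis: pd.DataFrame,
    expression: pd.DataFrame,
    covariates: pd.DataFrame,
    contexts: dict[str, NeighborContext],
    gene_level_threshold: float,
    f_cut: float = PLEIOTROPY_F,
) -> pd.DataFrame:
    """Flag genes whose GI shares gene-level target CpGs with a neighboring
    significant gene while remaining predictive (F > ``f_cut``) of that
    neighbor's expression over covariates and the neighbor's pruned GIs."""
    out = records.copy()
    alive = out[out["conditional_sig"] & ~out["dropped_corr95"]]
    # gene-level target sets from conditional p-values
    targets: dict[str, set[str]] = {}
    for gene, grp in out[out["p_cond"].notna()].groupby("gene"):
        hit = set(grp.loc[grp["p_cond"] < gene_level_threshold, "probe"])
        if hit:
            targets[gene] = hit
    for gene in sorted(alive["gene"].unique()):
        ctx = contexts.get(gene, NeighborContext(gene=gene))
        my_targets = targets.get(gene, set())
        drop = False
        for nb in ctx.neighbors:
            if nb not in targets or nb not in expression.columns:
                continue
            if not (my_targets & targets[nb]):
                continue
            nb_ctx = contexts.get(nb, NeighborContext(gene=nb))
            cond = [g for g in nb_ctx.pruned if g != gene and g in gis.columns]
            extra = gis[cond] if cond else None
            base, names = _base_design(covariates, extra)
            f = _added_f(
                expression[nb].to_numpy(float), gis[gene].to_numpy(float), base, names
            )
            if f > f_cut:
                logger.info(
                    "gene %s dropped: residual pleiotropy on %s (F=%.2f)", gene, nb, f
                )
                drop = True
                break
        if drop:
            idx = out.index[(out["gene"] == gene) & out["conditional_sig"]]
            out.loc[idx, "dropped_residual_pleiotropy"] = True
    return out


def _surviving(records: pd.DataFrame) -> pd.Series:
    return (
        records["conditional_sig"]
        & ~records["dropped_corr95"]
        & ~records["dropped_residual_pleiotropy"]
        & ~records["dropped_longrange"]
        & ~records["dropped_wbc"]
    )


def long_range_filter(
    records: pd.DataFrame,
    gis: pd.DataFrame,
    methylation: pd.DataFrame,
    covariates: pd.DataFrame,
    contexts: dict[str, NeighborContext],
    genes: pd.DataFrame,
    calibration: ScanCalibration,
    threshold: float,
) -> pd.DataFrame:
    """For each CpG associated with two or more genes from one chromosome,
    refit each association including all those genes' GIs (plus each index
    gene's pruned neighbors) jointly; flag losses ``dropped_longrange``."""
    out = records.copy()
    alive = out[_surviving(out)]
    for probe, grp in alive.groupby("probe", sort=True):
        glist = sorted(grp["gene"].unique())
        if len(glist) < 2:
            continue
        chroms = genes.loc[glist, "chrom"]
        for chrom in sorted(chroms.unique()):
            same = [g for g in glist if genes.loc[g, "chrom"] == chrom]
            if len(same) < 2:
                continue
            for gene in same:
                ctx = contexts.get(gene, NeighborContext(gene=gene))
                cond = [g for g in same if g != gene]
                cond += [g for g in ctx.pruned if g not in cond and g != gene]
                base, names = _base_design(covariates, gis[cond])
                res = _refit_pairs(
                    gis[gene].to_numpy(float), methylation, [probe], base, names
                )
                p_cal = float(calibration.corrected_p(res["z"].to_numpy())[0])
                if p_cal >= threshold:
                    idx = out.index[(out["gene"] == gene) & (out["probe"] == probe)]
                    out.loc[idx, "dropped_longrange"] = True
    return out


def wbc_filter(
    records: pd.DataFrame,
    wbc_snps: list[str],
    dosages: pd.DataFrame,
    gis: pd.DataFrame,
    methylation: pd.DataFrame,
    covariates: pd.DataFrame,
    contexts: dict[str, NeighborContext],
    calibration: ScanCalibration,
    threshold: float,
) -> pd.DataFrame:
    """Refit surviving records with the listed SNP dosages as extra
    covariates; flag losses ``dropped_wbc`` and survivors ``final``.

    SNPs absent from the dosage matrix are skipped with a warning. An empty
    list leaves results untouched (all survivors become final).
    """
    out = records.copy()
    present = []
    for sid in wbc_snps:
        if sid in dosages.columns:
            present.append(sid)
        else:
            logger.warning("WBC SNP %s absent from dosage matrix; skipped", sid)
    alive_mask = _surviving(out)
    if not present:
        out.loc[alive_mask, "final"] = True
        return out
    snp_block = dosages[present]
    for gene, grp in out[alive_mask].groupby("gene", sort=True):
        ctx = contexts.get(gene, NeighborContext(gene=gene))
        extra = pd.concat(
            [gis[ctx.pruned] if ctx.pruned else pd.DataFrame(index=gis.index), snp_block],
            axis=1,
        )
        base, names = _base_design(covariates, extra)
        res = _refit_pairs(
            gis[gene].to_numpy(float), methylation, list(grp["probe"]), base, names
        )
        res.index = grp.index
        p_cal = calibration.corrected_p(res["z"].to_numpy())
        lost = p_cal >= threshold
        out.loc[grp.index[lost], "dropped_wbc"] = True
        out.loc[grp.index[~lost], "final"] = True
    return out


def stage_accounting(records: pd.DataFrame) -> pd.DataFrame:
    """Per-stage genes/CpGs removed and retained (a conservation check:
    marginal_sig = final + all dropped + conditionally insignificant)."""
    rows = []

    def count(mask: pd.Series, stage: str) -> None:
        sub = records[mask]
        rows.append(
            {
                "stage": stage,
                "n_records": int(mask.sum()),
                "n_genes": sub["gene"].nunique(),
                "n_probes": sub["probe"].nunique(),
            }
        )

    count(records["marginal_sig"], "marginal_sig")
    count(records["dropped_corr95"], "dropped_corr95")
    count(
        records["marginal_sig"]
        & ~records["conditional_sig"]
        & ~records["dropped_corr95"],
        "not_conditional_sig",
    )
    count(records["conditional_sig"], "conditional_sig")
    count(records["dropped_residual_pleiotropy"], "dropped_residual_pleiotropy")
    count(records["dropped_longrange"], "dropped_longrange")
    count(records["dropped_wbc"], "dropped_wbc")
    count(records["final"], "final")
    return pd.DataFrame(rows)
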