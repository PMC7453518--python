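"""Downstream characterization of final genes and their target CpGs.

Direction-of-effect skew, region collapsing and co-localization, generic
Fisher enrichments, transcription-factor binding-site enrichment against a
GC-matched background with Simes/Benjamini-Hochberg multiplicity control,
chromatin-state annotation, and cis expression links near target CpGs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scan import correct_bias_inflation, bonferroni_threshold, linear_assoc

__all__ = [
    "EnrichmentResult",
    "direction_skew",
    "collapse_regions",
    "fisher_enrichment",
    "gc_matched_background",
    "tfbs_enrichment",
    "simes_combine",
    "bh_adjust",
    "chromatin_state_annotation",
    "cis_expression_links",
    "ROADMAP_STATE_ORDER",
]

logger = logging.getLogger(__name__)

ROADMAP_STATE_ORDER = [
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
]


@dataclass
class EnrichmentResult:
    label: str
    a: int  # hit & annotated
    b: int  # hit & not annotated
    c: int  # not hit & annotated
    d: int  # not hit & not annotated
    odds_ratio: float
    p: float
    p_adjusted: float = np.nan
    method: str = "fisher"


# ---------------------------------------------------------------------------
# direction skew
# ---------------------------------------------------------------------------

def direction_skew(
    counts: pd.DataFrame, alpha_fdr: float = 0.05, min_cpgs: int = 10
) -> pd.DataFrame:
    """Two-sided exact binomial test of positive vs negative effect counts
    per gene (null probability 0.5), BH-adjusted across eligible genes.

    ``counts`` needs columns ``gene``, ``n_pos``, ``n_neg``. Genes with fewer
    than ``min_cpgs`` targets are ineligible and omitted.
    """
    rows = []
    for _, r in counts.iterrows():
        n_pos, n_neg = int(r["n_pos"]), int(r["n_neg"])
        total = n_pos + n_neg
        if total < min_cpgs:
            continue
        p = stats.binomtest(n_pos, total, 0.5, alternative="two-sided").pvalue
        rows.append(
            {
                "gene": r["gene"],
                "n_pos": n_pos,
                "n_neg": n_neg,
                "p": float(p),
                "skew": "+" if n_pos > n_neg else ("-" if n_neg > n_pos else "="),
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "n_pos", "n_neg", "p", "skew"])
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p"].tolist())
        out["significant"] = out["p_adjusted"] < alpha_fdr
    else:
        out["p_adjusted"] = []
        out["significant"] = []
    return out


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

def collapse_regions(
    positions: pd.DataFrame, gap: int = 1000
) -> tuple[pd.DataFrame, float]:
    """Chain consecutive probes less than ``gap`` bp apart into regions.

    ``positions`` needs ``chrom`` and ``pos`` columns. Returns the region
    table and the co-localization fraction: the share of probes with at
    least one other probe within < ``gap`` bp on the same chromosome.
    Order-invariant and idempotent at the region level.
    """
    if len(positions) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_probes"]), 0.0
    df = positions[["chrom", "pos"]].sort_values(["chrom", "pos"]).reset_index(drop=True)
    regions = []
    coloc = 0
    for chrom, grp in df.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        diffs = np.diff(pos)
        near = np.zeros(pos.size, dtype=bool)
        near[:-1] |= diffs < gap
        near[1:] |= diffs < gap
        coloc += int(near.sum())
        start_idx = 0
        for i in range(1, pos.size + 1):
            if i == pos.size or pos[i] - pos[i - 1] >= gap:
                regions.append(
                    {
                        "chrom": chrom,
                        "start": int(pos[start_idx]),
                        "end": int(pos[i - 1]),
                        "n_probes": i - start_idx,
                    }
                )
                start_idx = i
    frac = coloc / len(df)
    return pd.DataFrame(regions), float(frac)


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(
    hits: set | list,
    annotation: set | list,
    universe: set | list,
    label: str = "",
) -> EnrichmentResult:
    """Two-sided Fisher's exact test of hit membership against annotation
    membership within the universe. Odds ratio is ``ad/bc`` with the
    Haldane-Anscombe +0.5 correction when any cell is zero (the p-value
    stays exact)."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits) & universe
    annotation = set(annotation) & universe
    a = len(hits & annotation)
    b = len(hits - annotation)
    c = len(annotation - hits)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return EnrichmentResult(label=label, a=a, b=b, c=c, d=d,
                            odds_ratio=float(orr), p=float(p))


# ---------------------------------------------------------------------------
# GC-matched background
# ---------------------------------------------------------------------------

def gc_matched_background(
    target_gc: pd.Series,
    universe_gc: pd.Series,
    n_background: int = 100_000,
    bin_width: float = 0.05,
    seed: int = 0,
) -> pd.Index:
    """Sample (with replacement) probe ids from the universe so the
    background's GC-bin histogram matches the targets' histogram.

    When a populated target bin is empty in the universe, the nearest
    non-empty bin is borrowed, with a warning. Deterministic under ``seed``.
    """
    if ((target_gc < 0) | (target_gc > 1)).any() or ((universe_gc < 0) | (universe_gc > 1)).any():
        raise ValueError("GC fractions must lie in [0, 1]")
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    n_bins = len(edges) - 1
    t_bins = np.clip(np.digitize(target_gc.to_numpy(float), edges) - 1, 0, n_bins - 1)
    u_bins = np.clip(np.digitize(universe_gc.to_numpy(float), edges) - 1, 0, n_bins - 1)
    rng = np.random.default_rng(seed)
    counts = np.bincount(t_bins, minlength=n_bins)
    # largest-remainder allocation of n_background across populated bins
    quota = counts / counts.sum() * n_background
    alloc = np.floor(quota).astype(int)
    rem = n_background - alloc.sum()
    order = np.argsort(-(quota - alloc), kind="stable")
    alloc[order[:rem]] += 1
    chosen: list[np.ndarray] = []
    universe_ids = universe_gc.index.to_numpy()
    by_bin = {b: np.flatnonzero(u_bins == b) for b in range(n_bins)}
    for b in range(n_bins):
        k = alloc[b]
        if k == 0:
            continue
        pool = by_bin.get(b, np.array([], dtype=int))
        if pool.size == 0:
            candidates = [bb for bb in range(n_bins) if by_bin.get(bb, np.array([])).size]
            if not candidates:
                raise ValueError("universe has no probes at all")
            nearest = min(candidates, key=lambda bb: (abs(bb - b), bb))
            warnings.warn(
                f"GC bin {b} empty in universe; borrowing from bin {nearest}"
            )
            pool = by_bin[nearest]
        chosen.append(universe_ids[pool[rng.integers(0, pool.size, size=k)]])
    return pd.Index(np.concatenate(chosen) if chosen else [])


# ---------------------------------------------------------------------------
# Simes / BH
# ---------------------------------------------------------------------------

def simes_combine(pvalues: list[float]) -> float:
    """Simes combination: ``min_i m * p_(i) / i`` over sorted p-values."""
    if len(pvalues) == 0:
        raise ValueError("empty p-value list")
    p = np.sort(np.asarray(pvalues, dtype=float))
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    return float(np.min(m * p / np.arange(1, m + 1)))


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()


# ---------------------------------------------------------------------------
# peak / segment overlap helpers
# ---------------------------------------------------------------------------

def _point_in_intervals(
    chrom: str, pos: np.ndarray, intervals: pd.DataFrame
) -> np.ndarray:
    """Boolean overlap of 1-bp points with half-open [start, end) intervals."""
    sub = intervals[intervals["chrom"] == chrom]
    if len(sub) == 0:
        return np.zeros(pos.size, dtype=bool)
    sub = sub.sort_values("start")
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    # merge to guarantee sortedness of ends for searchsorted logic
    merged_s, merged_e = [], []
    for s, e in zip(starts, ends):
        if merged_e and s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    ms = np.asarray(merged_s)
    me = np.asarray(merged_e)
    idx = np.searchsorted(ms, pos, side="right") - 1
    ok = idx >= 0
    ok[ok] &= pos[ok] < me[idx[ok]]
    return ok


def _overlap_mask(probes: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    # positional (the background is sampled with replacement, so probe ids
    # may repeat)
    out = np.zeros(len(probes), dtype=bool)
    chroms = probes["chrom"].to_numpy()
    pos = probes["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        m = chroms == chrom
        out[m] = _point_in_intervals(chrom, pos[m], peaks)
    return out


def tfbs_enrichment(
    target_sets: dict[str, list[str]],
    peak_experiments: dict[str, list[pd.DataFrame]],
    probes: pd.DataFrame,
    n_background: int = 100_000,
    alpha_fdr: float = 0.05,
    min_targets: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-TF binding-site enrichment of target CpGs.

    For each TF with at least ``min_targets`` target CpGs and at least one
    peak experiment: a GC-matched background is sampled, each experiment is
    tested with Fisher's exact test (target vs background overlap with the
    peaks), experiments are combined per TF with Simes, and TFs are adjusted
    with Benjamini-Hochberg. ``probes`` must carry chrom, pos and gc columns.
    TFs without peak data are reported with ``tested=False``.
    """
    rows = []
    for tf in sorted(target_sets):
        targets = [t for t in target_sets[tf] if t in probes.index]
        if len(targets) < min_targets:
            continue
        experiments = peak_experiments.get(tf, [])
        if not experiments:
            rows.append(
                {"tf": tf, "n_targets": len(targets), "n_experiments": 0,
                 "odds_ratio": np.nan, "p": np.nan, "tested": False}
            )
            continue
        tset = probes.loc[targets]
        bg_ids = gc_matched_background(
            tset["gc"], probes["gc"], n_background=n_background, seed=seed
        )
        bg = probes.loc[bg_ids]
        pvals, ors = [], []
        for peaks in experiments:
            t_in = int(_overlap_mask(tset, peaks).sum())
            b_in = int(_overlap_mask(bg, peaks).sum())
            table = [[t_in, len(tset) - t_in], [b_in, len(bg) - b_in]]
            _, p = stats.fisher_exact(table, alternative="two-sided")
            if min(t_in, len(tset) - t_in, b_in, len(bg) - b_in) == 0:
                orr = ((t_in + 0.5) * (len(bg) - b_in + 0.5)) / (
                    (len(tset) - t_in + 0.5) * (b_in + 0.5)
                )
            else:
                orr = (t_in * (len(bg) - b_in)) / ((len(tset) - t_in) * b_in)
            pvals.append(float(p))
            ors.append(float(orr))
        rows.append(
            {
                "tf": tf,
                "n_targets": len(targets),
                "n_experiments": len(experiments),
                "odds_ratio": float(np.median(ors)),
                "p": simes_combine(pvals),
                "tested": True,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["tf", "n_targets", "n_experiments", "odds_ratio", "p", "tested"],
    )
    tested = out["tested"] & out["p"].notna()
    out["p_adjusted"] = np.nan
    if tested.any():
        out.loc[tested, "p_adjusted"] = bh_adjust(out.loc[tested, "p"].tolist())
    out["significant"] = out["p_adjusted"] < alpha_fdr
    return out


# ---------------------------------------------------------------------------
# chromatin states
# ---------------------------------------------------------------------------

def chromatin_state_annotation(
    chrom: str,
    pos: int,
    segments_by_celltype: dict[str, pd.DataFrame],
    state_order: list[str] | None = None,
) -> tuple[str, bool]:
    """Modal chromatin state across cell types at one position.

    Each segment table needs chrom/start/end/state columns (half-open
    intervals). Ties are broken by the canonical state order and flagged.
    Positions outside all segments get ``("unannotated", False)``.
    """
    order = state_order or ROADMAP_STATE_ORDER
    states = []
    for ct in sorted(segments_by_celltype):
        seg = segments_by_celltype[ct]
        sub = seg[
            (seg["chrom"] == chrom) & (seg["start"] <= pos) & (pos < seg["end"])
        ]
        if len(sub):
            states.append(sub.iloc[0]["state"])
    if not states:
        return "unannotated", False
    counts = pd.Series(states).value_counts()
    top = counts.max()
    winners = list(counts.index[counts == top])
    tie = len(winners) > 1
    if tie:
        winners.sort(key=lambda s: order.index(s) if s in order else len(order))
    return winners[0], tie


# ---------------------------------------------------------------------------
# cis expression links near target CpGs
# ---------------------------------------------------------------------------

def cis_expression_links(
    target_probes: list[str],
    expression: pd.DataFrame,
    methylation: pd.DataFrame,
    covariates: pd.DataFrame,
    genes: pd.DataFrame,
    probes: pd.DataFrame,
    window: int = 250_000,
    gi: pd.Series | None = None,
    alpha: float = 0.05,
    min_n_calibration: int = 10_000,
) -> pd.DataFrame:
    """Associations between target CpGs (or an index GI) and the expression
    of genes within ``window`` bp of each CpG.

    With ``gi`` given, the GI replaces methylation as the predictor. Pairs
    are tested with OLS given ``covariates`` (pass the PC-augmented design
    for the CpG variant and the base design for the GI variant), then
    bias/inflation-corrected when enough tests are available and
    Bonferroni-thresholded.
    """
    rows = []
    for probe in target_probes:
        if probe not in probes.index:
            continue
        prow = probes.loc[probe]
        near = genes[
            (genes["chrom"] == prow["chrom"])
            & (
                (np.minimum(abs(genes["tss"] - prow["pos"]),
                            abs(genes["tes"] - prow["pos"])) < window)
                | ((np.minimum(genes["tss"], genes["tes"]) <= prow["pos"])
                   & (prow["pos"] <= np.maximum(genes["tss"], genes["tes"])))
            )
        ]
        for gene in near.index:
            if gene not in expression.columns:
                continue
            x = gi if gi is not None else methylation[probe]
            b, se, t, p = linear_assoc(expression[gene], x, covariates)
            rows.append(
                {"probe": probe, "gene": gene, "beta": b, "se": se, "t": t, "p": p}
            )
    out = pd.DataFrame(rows, columns=["probe", "gene", "beta", "se", "t", "p"])
    if len(out) == 0:
        out["p_corrected"] = []
        out["significant"] = []
        return out
    z = stats.norm.isf(np.clip(out["p"] / 2.0, 1e-300, 1.0)) * np.sign(out["t"])
    if len(out) >= min_n_calibration:
        cal = correct_bias_inflation(z, min_n=min_n_calibration)
        out["p_corrected"] = cal.corrected_p(z)
    else:
        out["p_corrected"] = out["p"]
    thr = bonferroni_threshold(alpha, len(out))
    out["significant"] = out["p_corrected"] < thr
    return out
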