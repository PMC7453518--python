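"""End-to-end orchestration: preprocessing, instruments, scan, specificity
cascade, characterization and power, with TSV outputs and a JSON-lines log.

Stage order: expression filter -> rank-INT -> PCs -> split -> instruments ->
validation -> trans scan -> calibration -> Bonferroni threshold ->
neighbor conditioning -> residual pleiotropy -> long-range joint models ->
WBC-variant correction -> characterization -> power.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .characterize import collapse_regions, direction_skew
from .instruments import (
    fit_instrument,
    instruments_to_frames,
    select_cis_snps,
    split_train_test,
    validate_instrument,
)
from .io import JsonlLogger, write_stage_tsv
from .power import power_profile
from .preprocess import build_design, filter_expressed, fit_pcs, rank_inverse_normal
from .scan import (
    ScanCalibration,
    apply_calibration,
    bonferroni_threshold,
    correct_bias_inflation,
    run_scan,
)
from .sim import CohortDataset
from .specificity import (
    build_neighbor_contexts,
    conditional_scan,
    gi_matrix,
    long_range_filter,
    residual_pleiotropy_filter,
    stage_accounting,
    wbc_filter,
    _base_design,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cis_window: int = 100_000
    trans_distance: int = 10_000_000
    neighbor_window: int = 1_000_000
    corr_cutoff: float = 0.95
    f_pleiotropy: float = 5.0
    alpha: float = 0.05
    split_ratio: float = 1.0 / 3.0
    seed: int = 0
    min_median_cpm: float = 1.0
    n_pcs: int = 5
    scan_pc_source: str = "methylation"  # "methylation" | "expression" | "none"
    calibration: str = "auto"  # "auto" | "em" | "none"
    calibration_min_n: int = 10_000
    wbc_snps: list[str] = field(default_factory=list)
    do_conditional: bool = True
    do_pleiotropy: bool = True
    do_longrange: bool = True
    do_wbc: bool = True
    do_characterize: bool = True
    do_power: bool = True
    power_effects: tuple[float, ...] = (0.25, 0.5, 1.0)

    def validate(self) -> None:
        for name in ("cis_window", "trans_distance", "neighbor_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.split_ratio < 1):
            raise ValueError("split_ratio must be in (0, 1)")
        if self.scan_pc_source not in ("methylation", "expression", "none"):
            raise ValueError("scan_pc_source must be methylation/expression/none")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "power_effects" in data:
            data["power_effects"] = tuple(data["power_effects"])
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _partial_r2_given(
    y: np.ndarray, g: np.ndarray, covariates: pd.DataFrame, extra: pd.DataFrame | None
) -> float:
    base, names = _base_design(covariates, extra)
    q, _ = np.linalg.qr(base)
    y_r = y - q @ (q.T @ y)
    g_r = g - q @ (q.T @ g)
    g_ss = float(g_r @ g_r)
    rss0 = float(y_r @ y_r)
    if g_ss <= 1e-12 or rss0 <= 0:
        return 0.0
    beta = float(y_r @ g_r) / g_ss
    rss1 = rss0 - beta * beta * g_ss
    return float((rss0 - rss1) / rss0)


def run_cascade(
    dataset: CohortDataset,
    seed: int = 0,
    wbc_snps: tuple[str, ...] = (),
    threshold: float = 1.4e-11,
    gene_level_threshold: float | None = None,
    calibration: ScanCalibration | None = None,
) -> tuple[pd.DataFrame, list]:
    """Instruments + scan + full specificity cascade on raw (latent-scale)
    matrices with base covariates, identity calibration by default, and an
    explicit significance threshold.

    A lean path for simulation batteries and power checks where the
    preprocessing stages (CPM filter, rank-INT, PCs) are not under study;
    returns (records, instruments).
    """
    cov = build_design(dataset.covariates, add_intercept=False)
    split = split_train_test(
        dataset.covariates.index,
        dataset.covariates["cohort"],
        dataset.covariates["sex"],
        seed=seed,
    )
    instruments = []
    for gene in dataset.expression.columns:
        cis = select_cis_snps(gene, dataset.genes, dataset.snps)
        gi = fit_instrument(
            dataset.dosages.loc[split.train],
            dataset.expression.loc[split.train, gene],
            cov.loc[split.train],
            cis,
            seed=seed,
            gene=gene,
        )
        if gi is None:
            continue
        instruments.append(
            validate_instrument(
                dataset.dosages.loc[split.test],
                dataset.expression.loc[split.test, gene],
                cov.loc[split.test],
                gi,
            )
        )
    valid = [gi for gi in instruments if gi.valid]
    records = run_scan(
        valid, dataset.dosages, dataset.methylation, cov, dataset.genes,
        dataset.probes,
    )
    cal = calibration or ScanCalibration(0.0, 1.0, 1.0, max(len(records), 1))
    records = apply_calibration(records, cal)
    records["marginal_sig"] = records["p_corrected"] < threshold
    gis = gi_matrix(valid, dataset.dosages)
    if gis.shape[1] == 0 or not records["marginal_sig"].any():
        return records, instruments
    contexts = build_neighbor_contexts(dataset.genes, gis)
    records = conditional_scan(
        records, gis, dataset.methylation, cov, contexts, cal, threshold
    )
    records = residual_pleiotropy_filter(
        records, gis, dataset.expression, cov, contexts,
        gene_level_threshold or bonferroni_threshold(0.05, dataset.probes.shape[0]),
    )
    records = long_range_filter(
        records, gis, dataset.methylation, cov, contexts, dataset.genes, cal,
        threshold,
    )
    records = wbc_filter(
        records, list(wbc_snps), dataset.dosages, gis, dataset.methylation, cov,
        contexts, cal, threshold,
    )
    return records, instruments


def run_pipeline(
    dataset: CohortDataset, config: PipelineConfig, outdir: str
) -> dict[str, object]:
    """Run all stages on an in-memory dataset, writing stage TSVs to
    ``outdir``; returns the main in-memory results keyed by stage name.

    Re-running with identical inputs and config produces byte-identical
    outputs.
    """
    config.validate()
    dataset.check_alignment()
    os.makedirs(outdir, exist_ok=True)
    log = JsonlLogger(os.path.join(outdir, "run_log.jsonl"))
    meta = f"transgi {__version__} seed={config.seed}"
    log.log("start", version=__version__, seed=config.seed,
            config=dataclasses.asdict(config))
    results: dict[str, object] = {}

    # ---- expression filter ------------------------------------------------
    genes_all = list(dataset.expression.columns)
    if dataset.expression_counts is not None:
        kept = filter_expressed(dataset.expression_counts, config.min_median_cpm)
        kept = [g for g in genes_all if g in set(kept)]
    else:
        kept = genes_all
    log.log("filter_expressed", n_in=len(genes_all), n_kept=len(kept))
    if not kept:
        raise RuntimeError("filter_expressed: no genes passed the CPM filter")

    # ---- rank-INT ---------------------------------------------------------
    cohort = dataset.covariates["cohort"]
    expr = rank_inverse_normal(dataset.expression[kept], cohort)
    meth = rank_inverse_normal(dataset.methylation, cohort)

    # ---- split + expression PCs ------------------------------------------
    split = split_train_test(
        expr.index, cohort, dataset.covariates["sex"],
        ratio=config.split_ratio, seed=config.seed,
    )
    if config.n_pcs > 0:
        pc_model = fit_pcs(expr.loc[split.train], config.n_pcs)
        expr_pcs = pc_model.transform(expr)
        expr_pcs.columns = [f"ePC{i + 1}" for i in range(expr_pcs.shape[1])]
    else:
        expr_pcs = None
    cov_instr = build_design(dataset.covariates, expr_pcs, add_intercept=False)
    log.log("split", n_train=len(split.train), n_test=len(split.test))

    # ---- instruments ------------------------------------------------------
    instruments = []
    for gene in kept:
        cis = select_cis_snps(gene, dataset.genes, dataset.snps, config.cis_window)
        gi = fit_instrument(
            dataset.dosages.loc[split.train],
            expr.loc[split.train, gene],
            cov_instr.loc[split.train],
            cis,
            seed=config.seed,
            gene=gene,
        )
        if gi is None:
            continue
        gi = validate_instrument(
            dataset.dosages.loc[split.test],
            expr.loc[split.test, gene],
            cov_instr.loc[split.test],
            gi,
        )
        instruments.append(gi)
    weights, summary = instruments_to_frames(instruments)
    write_stage_tsv(weights, os.path.join(outdir, "instruments.tsv"),
                    f"{meta} stage=instruments")
    write_stage_tsv(summary, os.path.join(outdir, "instrument_summary.tsv"),
                    f"{meta} stage=instrument_summary")
    valid = [gi for gi in instruments if gi.valid]
    log.log("instruments", n_fit=len(instruments), n_valid=len(valid))
    results["instruments"] = instruments
    if not valid:
        raise RuntimeError("instruments: no valid genetic instruments")

    # ---- scan covariates --------------------------------------------------
    if config.n_pcs <= 0:
        scan_pcs = None
    elif config.scan_pc_source == "methylation":
        scan_pcs = fit_pcs(meth, config.n_pcs).transform(meth)
        scan_pcs.columns = [f"mPC{i + 1}" for i in range(scan_pcs.shape[1])]
    elif config.scan_pc_source == "expression":
        scan_pcs = expr_pcs
    else:
        scan_pcs = None
    cov_scan = build_design(dataset.covariates, scan_pcs, add_intercept=False)

    # ---- trans scan + calibration ----------------------------------------
    records = run_scan(
        valid, dataset.dosages, meth, cov_scan, dataset.genes, dataset.probes,
        min_distance=config.trans_distance,
    )
    n_tests = len(valid) * dataset.probes.shape[0]
    use_em = config.calibration == "em" or (
        config.calibration == "auto" and len(records) >= config.calibration_min_n
    )
    if use_em:
        cal = correct_bias_inflation(records["z"], min_n=min(config.calibration_min_n,
                                                            len(records)))
    else:
        cal = ScanCalibration(bias=0.0, inflation=1.0, pi0=1.0,
                              n_tests=len(records), converged=True, fallback=True)
        logger.info("calibration skipped (%d tests); using identity", len(records))
    records = apply_calibration(records, cal)
    threshold = bonferroni_threshold(config.alpha, n_tests)
    records["marginal_sig"] = records["p_corrected"] < threshold
    write_stage_tsv(
        pd.DataFrame([dataclasses.asdict(cal) | {"threshold": threshold}]),
        os.path.join(outdir, "calibration.tsv"), f"{meta} stage=calibration",
    )
    log.log("scan", n_records=len(records), n_tests=n_tests,
            bias=cal.bias, inflation=cal.inflation,
            n_marginal=int(records["marginal_sig"].sum()))
    results["calibration"] = cal
    results["threshold"] = threshold

    # ---- specificity cascade ---------------------------------------------
    gis = gi_matrix(valid, dataset.dosages)
    contexts = build_neighbor_contexts(
        dataset.genes, gis, window=config.neighbor_window, cutoff=config.corr_cutoff
    )
    gene_level = bonferroni_threshold(config.alpha, dataset.probes.shape[0])
    if config.do_conditional:
        records = conditional_scan(
            records, gis, meth, cov_scan, contexts, cal, threshold,
            corr_cutoff=config.corr_cutoff,
        )
        if config.do_pleiotropy:
            records = residual_pleiotropy_filter(
                records, gis, expr, cov_scan, contexts, gene_level,
                f_cut=config.f_pleiotropy,
            )
        if config.do_longrange:
            records = long_range_filter(
                records, gis, meth, cov_scan, contexts, dataset.genes, cal, threshold
            )
        if config.do_wbc:
            records = wbc_filter(
                records, config.wbc_snps, dataset.dosages, gis, meth, cov_scan,
                contexts, cal, threshold,
            )
        else:
            from .specificity import _surviving

            records.loc[_surviving(records), "final"] = True
    else:
        records.loc[records["marginal_sig"], "final"] = True
    write_stage_tsv(records, os.path.join(outdir, "scan_records.tsv"),
                    f"{meta} stage=scan_records")
    accounting = stage_accounting(records)
    write_stage_tsv(accounting, os.path.join(outdir, "stage_accounting.tsv"),
                    f"{meta} stage=stage_accounting")
    log.log("cascade", n_final=int(records["final"].sum()))
    results["records"] = records
    results["accounting"] = accounting
    results["contexts"] = contexts

    # ---- characterization -------------------------------------------------
    final = records[records["final"]]
    if config.do_characterize:
        counts = (
            final.assign(pos_eff=final["phi_cond"].fillna(final["phi"]) > 0)
            .groupby("gene")["pos_eff"]
            .agg(n_pos="sum", n_total="count")
            .reset_index()
        )
        counts["n_neg"] = counts["n_total"] - counts["n_pos"]
        skew = direction_skew(counts[["gene", "n_pos", "n_neg"]])
        write_stage_tsv(skew, os.path.join(outdir, "direction_skew.tsv"),
                        f"{meta} stage=direction_skew")
        target_pos = dataset.probes.loc[
            dataset.probes.index.intersection(final["probe"].unique())
        ]
        regions, coloc = collapse_regions(target_pos)
        write_stage_tsv(regions, os.path.join(outdir, "regions.tsv"),
                        f"{meta} stage=regions coloc_fraction={coloc:.6g}")
        gene_table = (
            final.groupby("gene")
            .agg(n_cpgs=("probe", "nunique"))
            .reset_index()
            .sort_values("gene")
        )
        write_stage_tsv(gene_table, os.path.join(outdir, "final_genes.tsv"),
                        f"{meta} stage=final_genes")
        results["skew"] = skew
        results["regions"] = regions
        results["coloc_fraction"] = coloc
        log.log("characterize", n_final_genes=len(gene_table),
                n_regions=len(regions), coloc_fraction=coloc)

    # ---- power ------------------------------------------------------------
    if config.do_power:
        rows = []
        test_idx = split.test
        for gi in valid:
            ctx = contexts.get(gi.gene)
            nbrs = [g for g in (ctx.pruned if ctx else []) if g in gis.columns]
            extra = gis.loc[test_idx, nbrs] if nbrs else None
            r2p = _partial_r2_given(
                expr.loc[test_idx, gi.gene].to_numpy(float),
                gis.loc[test_idx, gi.gene].to_numpy(float),
                cov_instr.loc[test_idx],
                extra,
            )
            rows.append(
                {"gene": gi.gene, "r2_marginal": gi.partial_r2, "r2_partial": r2p}
            )
        prof = power_profile(
            pd.DataFrame(rows), n=len(dataset.dosages),
            effect_grid=config.power_effects, alpha=threshold,
        )
        write_stage_tsv(prof, os.path.join(outdir, "power.tsv"),
                        f"{meta} stage=power")
        results["power"] = prof
        log.log("power", n_genes=len(rows))

    log.log("done")
    return results
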