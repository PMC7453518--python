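"""Specificity cascade: pruning, conditioning, residual pleiotropy,
long-range joint models, WBC-variant correction, cascade invariants."""

import numpy as np
import pandas as pd
import pytest

from transgi.pipeline import run_cascade
from transgi.scan import ScanCalibration
from transgi.sim import (
    GeneSpec,
    ScenarioSpec,
    SimConfig,
    SnpSpec,
    TransEffect,
    cell_confounder_config,
    shared_eqtl_config,
    simulate,
)
from transgi.specificity import (
    NeighborContext,
    _added_f,
    _base_design,
    build_neighbor_contexts,
    conditional_scan,
    prune_correlated,
    residual_pleiotropy_filter,
    wbc_filter,
)

from conftest import exact_corr_columns


class TestPrune:
    def test_no_op_below_cutoff(self):
        corr = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.1], [0.2, 0.1, 1.0]])
        df = exact_corr_columns(200, corr, seed=0)
        assert prune_correlated(df) == ["v1", "v2", "v3"]

    def test_hand_traced_greedy_rule(self):
        # r(1,2)=0.99, r(1,3)=0.30, r(2,3)=0.10: column 1 has the larger
        # mean |r| and is removed (checked on the correlation matrix itself,
        # which is what prune_correlated computes from its input columns)
        from transgi.specificity import _prune_from_corr

        corr = np.array([[1.0, 0.99, 0.30], [0.99, 1.0, 0.10], [0.30, 0.10, 1.0]])
        assert _prune_from_corr(corr, 0.95) == [1, 2]

    def test_hand_traced_greedy_rule_on_columns(self):
        corr = np.array([[1.0, 0.96, 0.30], [0.96, 1.0, 0.15], [0.30, 0.15, 1.0]])
        df = exact_corr_columns(500, corr, seed=1)
        assert prune_correlated(df) == ["v2", "v3"]

    def test_duplicated_column(self, rng):
        x = rng.standard_normal(100)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(100)})
        kept = prune_correlated(df)
        assert len([k for k in kept if k in ("a", "b")]) == 1
        assert "c" in kept

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            prune_correlated(pd.DataFrame(index=range(5)))

    def test_postcondition_all_below_cutoff(self, rng):
        m = rng.standard_normal((300, 6))
        m[:, 1] = m[:, 0] + 0.05 * rng.standard_normal(300)
        m[:, 3] = m[:, 2] + 0.05 * rng.standard_normal(300)
        df = pd.DataFrame(m, columns=list("abcdef"))
        kept = prune_correlated(df, cutoff=0.95)
        sub = df[kept].corr().abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        assert sub.max() <= 0.95


class TestNeighborContexts:
    def test_window_and_pruning(self, rng):
        genes = pd.DataFrame(
            {
                "chrom": ["1", "1", "1", "2"],
                "tss": [1_000_000, 1_500_000, 5_000_000, 1_200_000],
                "tes": [1_010_000, 1_510_000, 5_010_000, 1_210_000],
            },
            index=pd.Index(["a", "b", "far", "otherchrom"], name="gene"),
        )
        gis = pd.DataFrame(rng.standard_normal((200, 4)),
                           columns=["a", "b", "far", "otherchrom"])
        ctx = build_neighbor_contexts(genes, gis)
        assert ctx["a"].neighbors == ["b"]
        assert ctx["b"].neighbors == ["a"]
        assert ctx["far"].neighbors == []
        assert ctx["otherchrom"].neighbors == []
        assert set(ctx["a"].pruned) <= set(ctx["a"].neighbors)


def _mk_records(genes_probes, sig=True):
    rows = []
    for g, p in genes_probes:
        rows.append({"gene": g, "probe": p, "phi": 1.0, "phi_expr": 1.0,
                     "se": 0.1, "t": 10.0, "p_raw": 1e-20, "z": 10.0})
    rec = pd.DataFrame(rows)
    from transgi.scan import STAGE_FLAGS

    for f in STAGE_FLAGS:
        rec[f] = False
    rec["p_corrected"] = np.nan
    rec["marginal_sig"] = sig
    return rec


class TestConditionalScan:
    def test_orthogonal_neighbors_leave_phi_unchanged(self, rng):
        n = 400
        basis = rng.standard_normal((n, 4))
        basis -= basis.mean(axis=0)
        q, _ = np.linalg.qr(basis)
        gis = pd.DataFrame(q[:, :2] , columns=["idx", "nbr"])
        meth = pd.DataFrame({"p1": 0.8 * q[:, 0] + 0.05 * q[:, 2]})
        cov = pd.DataFrame({"c": q[:, 3]})
        rec = _mk_records([("idx", "p1")])
        cal = ScanCalibration(0.0, 1.0, 1.0, 1)
        ctx = {"idx": NeighborContext("idx", ["nbr"], ["nbr"], 0.0)}
        out = conditional_scan(rec, gis, meth, cov, ctx, cal, 0.05)
        # marginal phi for orthonormal design is just the projection
        expected = float(meth["p1"] @ gis["idx"]) / float(gis["idx"] @ gis["idx"])
        assert out.loc[0, "phi_cond"] == pytest.approx(expected, rel=1e-8)

    def test_duplicate_gi_dropped_corr95(self, rng):
        x = rng.standard_normal(300)
        gis = pd.DataFrame({"idx": x, "twin": x.copy()})
        meth = pd.DataFrame({"p1": x + rng.standard_normal(300)})
        cov = pd.DataFrame({"c": rng.standard_normal(300)})
        genes = pd.DataFrame(
            {"chrom": ["1", "1"], "tss": [1_000_000, 1_100_000],
             "tes": [1_010_000, 1_110_000]},
            index=pd.Index(["idx", "twin"], name="gene"),
        )
        ctx = build_neighbor_contexts(genes, gis)
        rec = _mk_records([("idx", "p1"), ("twin", "p1")])
        out = conditional_scan(rec, gis, meth, cov, ctx, ScanCalibration(0, 1, 1, 1), 0.05)
        assert out["dropped_corr95"].all()
        assert not out["conditional_sig"].any()


class TestResidualPleiotropy:
    def _setup(self, rng, f_strength):
        n = 500
        z = rng.standard_normal((n, 3))
        gis = pd.DataFrame({"a": z[:, 0], "b": z[:, 1]})
        # expression of b predicted by GI a with controllable strength
        expr_b = f_strength * z[:, 0] + z[:, 2]
        expression = pd.DataFrame({"a": z[:, 0], "b": expr_b})
        cov = pd.DataFrame({"c": rng.standard_normal(n)})
        ctx = {
            "a": NeighborContext("a", ["b"], ["b"], 0.5),
            "b": NeighborContext("b", ["a"], ["a"], 0.5),
        }
        rec = _mk_records([("a", "p1"), ("b", "p1")])
        rec["conditional_sig"] = True
        rec["p_cond"] = 1e-20
        return rec, gis, expression, cov, ctx

    def test_shared_cpg_strong_f_excluded(self, rng):
        rec, gis, expression, cov, ctx = self._setup(rng, f_strength=0.5)
        out = residual_pleiotropy_filter(rec, gis, expression, cov, ctx, 1e-7)
        assert out.loc[out["gene"] == "a", "dropped_residual_pleiotropy"].all()

    def test_shared_cpg_weak_f_retained(self, rng):
        rec, gis, expression, cov, ctx = self._setup(rng, f_strength=0.0)
        out = residual_pleiotropy_filter(rec, gis, expression, cov, ctx, 1e-7)
        assert not out.loc[out["gene"] == "a", "dropped_residual_pleiotropy"].any()

    def test_no_significant_neighbor_vacuous(self, rng):
        rec, gis, expression, cov, ctx = self._setup(rng, f_strength=0.9)
        rec.loc[rec["gene"] == "b", "p_cond"] = 0.5  # b has no gene-level targets
        rec.loc[rec["gene"] == "b", "conditional_sig"] = False
        out = residual_pleiotropy_filter(rec, gis, expression, cov, ctx, 1e-7)
        assert not out["dropped_residual_pleiotropy"].any()

    def test_added_f_matches_anova(self, rng):
        n = 200
        y = rng.standard_normal(n)
        g = rng.standard_normal(n)
        cov = pd.DataFrame({"c": rng.standard_normal(n)})
        base, names = _base_design(cov)
        f = _added_f(y, g, base, names)
        x0 = base
        x1 = np.column_stack([base, g])
        rss0 = float(((y - x0 @ np.linalg.lstsq(x0, y, rcond=None)[0]) ** 2).sum())
        rss1 = float(((y - x1 @ np.linalg.lstsq(x1, y, rcond=None)[0]) ** 2).sum())
        expected = (rss0 - rss1) / (rss1 / (n - x1.shape[1]))
        assert f == pytest.approx(expected, rel=1e-8)


class TestLongRange:
    def test_single_gene_cpg_untouched(self):
        ds = simulate(shared_eqtl_config(n_samples=1200, seed=60))
        records, _ = run_cascade(ds, seed=60, gene_level_threshold=1.2e-7)
        # cascade ran; no same-chromosome multi-gene CpG -> no longrange drops
        assert not records["dropped_longrange"].any()

    def test_bystander_on_same_chromosome_dropped(self):
        # two genes 20 Mb apart in LD (shared block), one causal: the
        # long-range joint model should remove the bystander
        dropped, eligible = 0, 0
        for seed in range(8):
            snps = [
                SnpSpec("rs_a", "1", 10_000_000, 0.3, "lr"),
                SnpSpec("rs_b", "1", 30_000_000, 0.3, "lr"),
            ]
            genes = [
                GeneSpec("gA", "1", 10_005_000, 10_010_000, ("rs_a",), (1.0,), 0.2),
                GeneSpec("gB", "1", 30_005_000, 30_010_000, ("rs_b",), (1.0,), 0.2),
            ]
            cfg = SimConfig(
                n_samples=2500, snps=snps, genes=genes,
                probes=[("p1", "9", 1_000_000)],
                trans_effects=[TransEffect("gA", "p1", 1.0)],
                ld_block_r={"lr": 0.6}, seed=seed,
            )
            rec, _ = run_cascade(simulate(cfg), seed=seed, gene_level_threshold=1.2e-7)
            m = rec.set_index(["gene", "probe"])
            if not bool(m.loc[("gB", "p1"), "marginal_sig"]):
                continue
            if not bool(m.loc[("gB", "p1"), "conditional_sig"]):
                continue  # genes are > 1 Mb apart: not neighbors, stays sig
            eligible += 1
            if bool(m.loc[("gB", "p1"), "dropped_longrange"]):
                dropped += 1
        if eligible:
            assert dropped / eligible >= 0.9

    def test_different_chromosomes_not_retested(self, rng):
        ds = simulate(shared_eqtl_config(n_samples=800, seed=61))
        records, _ = run_cascade(ds, seed=61, gene_level_threshold=1.2e-7)
        # geneA (chr1) hits cpg_t (chr2); no other chr1 gene hits it jointly
        assert not records["dropped_longrange"].any()


class TestWbcFilter:
    def test_empty_snp_list_no_op(self, rng):
        x = rng.standard_normal(300)
        gis = pd.DataFrame({"g": x})
        meth = pd.DataFrame({"p1": x + 0.1 * rng.standard_normal(300)})
        cov = pd.DataFrame({"c": rng.standard_normal(300)})
        dosages = pd.DataFrame({"rs1": rng.integers(0, 3, 300).astype(float)})
        rec = _mk_records([("g", "p1")])
        rec["conditional_sig"] = True
        cal = ScanCalibration(0, 1, 1, 1)
        out = wbc_filter(rec, [], dosages, gis, meth, cov, {}, cal, 1e-5)
        assert out["final"].all() and not out["dropped_wbc"].any()

    def test_absent_snp_warns_and_skips(self, rng, caplog):
        x = rng.standard_normal(300)
        gis = pd.DataFrame({"g": x})
        meth = pd.DataFrame({"p1": x})
        cov = pd.DataFrame({"c": rng.standard_normal(300)})
        dosages = pd.DataFrame({"rs1": rng.integers(0, 3, 300).astype(float)})
        rec = _mk_records([("g", "p1")])
        rec["conditional_sig"] = True
        with caplog.at_level("WARNING"):
            out = wbc_filter(rec, ["missing_snp"], dosages, gis, meth, cov, {},
                             ScanCalibration(0, 1, 1, 1), 1e-5)
        assert "missing_snp" in caplog.text
        assert out["final"].all()

    def test_confounder_scenario_removed(self):
        removed, sig = 0, 0
        for seed in range(10):
            ds = simulate(cell_confounder_config(n_samples=1500, seed=seed))
            rec, _ = run_cascade(ds, seed=seed, wbc_snps=("rs_drv",),
                                 gene_level_threshold=1.2e-7)
            if not rec["marginal_sig"].any():
                continue
            sig += 1
            if rec["dropped_wbc"].any():
                removed += 1
        assert sig >= 5
        assert removed / sig >= 0.8


class TestCascadeInvariants:
    def test_monotone_flag_sets_and_conservation(self):
        ds = simulate(shared_eqtl_config(n_samples=1500, seed=70))
        rec, _ = run_cascade(ds, seed=70, gene_level_threshold=1.2e-7)
        final = rec["final"]
        cond = rec["conditional_sig"]
        marg = rec["marginal_sig"]
        assert (final <= cond).all() and (cond <= marg).all()
        dropped = (
            rec["dropped_corr95"]
            | rec["dropped_residual_pleiotropy"]
            | rec["dropped_longrange"]
            | rec["dropped_wbc"]
        )
        # at most one dropped flag each
        n_flags = (
            rec[["dropped_corr95", "dropped_residual_pleiotropy",
                 "dropped_longrange", "dropped_wbc"]].sum(axis=1)
        )
        assert (n_flags <= 1).all()
        # conservation: every marginal record is final, dropped, or lost
        # conditional significance
        lost = marg & ~cond & ~dropped
        assert (marg == (final | dropped | lost)).all()
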