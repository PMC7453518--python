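"""Characterization statistics: skew, regions, Fisher, GC background,
TFBS enrichment, Simes/BH, chromatin states, cis links."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from transgi.characterize import (
    ROADMAP_STATE_ORDER,
    bh_adjust,
    chromatin_state_annotation,
    cis_expression_links,
    collapse_regions,
    direction_skew,
    fisher_enrichment,
    gc_matched_background,
    simes_combine,
    tfbs_enrichment,
)


def hypergeom_two_sided(a, b, c, d):
    """Exhaustive enumeration oracle for the two-sided Fisher p-value."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    probs = {k: stats.hypergeom.pmf(k, n, row1, col1) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


class TestDirectionSkew:
    def test_all_positive_exact_binomial(self):
        counts = pd.DataFrame([{"gene": "g", "n_pos": 19, "n_neg": 0}])
        out = direction_skew(counts)
        assert out.loc[0, "p"] == pytest.approx(2 * 0.5**19, rel=1e-9)
        assert out.loc[0, "p"] == pytest.approx(3.8e-6, abs=2e-7)
        assert out.loc[0, "skew"] == "+"

    def test_balanced_p_one(self):
        counts = pd.DataFrame([{"gene": "g", "n_pos": 5, "n_neg": 5}])
        out = direction_skew(counts)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_below_min_cpgs_skipped(self):
        counts = pd.DataFrame([{"gene": "g", "n_pos": 9, "n_neg": 0}])
        assert len(direction_skew(counts, min_cpgs=10)) == 0

    def test_bh_across_eligible(self):
        counts = pd.DataFrame(
            [
                {"gene": "a", "n_pos": 20, "n_neg": 0},
                {"gene": "b", "n_pos": 6, "n_neg": 5},
            ]
        )
        out = direction_skew(counts)
        ps = out.set_index("gene")["p"].tolist()
        np.testing.assert_allclose(
            sorted(out["p_adjusted"]), sorted(bh_adjust(ps)), rtol=1e-12
        )


class TestCollapseRegions:
    def test_singleton(self):
        regions, frac = collapse_regions(pd.DataFrame({"chrom": ["1"], "pos": [100]}))
        assert len(regions) == 1 and frac == 0.0

    def test_chaining_two_regions(self):
        df = pd.DataFrame({"chrom": ["1"] * 3, "pos": [100, 900, 2500]})
        regions, frac = collapse_regions(df)
        assert len(regions) == 2
        assert frac == pytest.approx(2 / 3)

    def test_exact_gap_splits(self):
        df = pd.DataFrame({"chrom": ["1", "1"], "pos": [0, 1000]})
        regions, frac = collapse_regions(df)
        assert len(regions) == 2 and frac == 0.0

    def test_order_invariance_and_idempotence(self, rng):
        pos = rng.integers(0, 100_000, 40)
        df = pd.DataFrame({"chrom": "1", "pos": pos})
        shuffled = df.sample(frac=1.0, random_state=1)
        r1, f1 = collapse_regions(df)
        r2, f2 = collapse_regions(shuffled)
        pd.testing.assert_frame_equal(
            r1.reset_index(drop=True), r2.reset_index(drop=True)
        )
        assert f1 == f2
        # idempotence at region level: collapsing region starts again yields
        # the same number of regions
        starts = r1.rename(columns={"start": "pos"})[["chrom", "pos"]]
        r3, _ = collapse_regions(starts)
        assert len(r3) == len(r1)


class TestFisher:
    def test_example_table(self):
        universe = [f"u{i}" for i in range(1000)]
        hits = universe[:100]
        annotation = universe[:10] + universe[100:110]
        res = fisher_enrichment(hits, annotation, universe)
        assert (res.a, res.b, res.c, res.d) == (10, 90, 10, 890)
        assert res.odds_ratio == pytest.approx(9.888, abs=0.01)
        assert res.p == pytest.approx(hypergeom_two_sided(10, 90, 10, 890), rel=1e-6)

    def test_independence_or_one(self):
        universe = [f"u{i}" for i in range(200)]
        hits = universe[:100]
        annotation = universe[:50] + universe[100:150]
        res = fisher_enrichment(hits, annotation, universe)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_zero_cell_haldane(self):
        universe = [f"u{i}" for i in range(100)]
        hits = universe[:10]
        annotation = universe[:10]
        res = fisher_enrichment(hits, annotation, universe)
        assert res.a == 10 and res.c == 0
        assert np.isfinite(res.odds_ratio)
        assert 0 < res.p <= 1

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_enrichment([], [], [])

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b == 0 or a + c == 0 or (a + b + c + d) == 0:
            return
        universe = [f"u{i}" for i in range(a + b + c + d)]
        hits = universe[: a + b]
        annotation = universe[:a] + universe[a + b : a + b + c]
        res = fisher_enrichment(hits, annotation, universe)
        assert res.p == pytest.approx(hypergeom_two_sided(a, b, c, d), rel=1e-6)


class TestSimesBH:
    def test_simes_identity(self):
        assert simes_combine([0.37]) == pytest.approx(0.37)

    def test_simes_hand_traces(self):
        assert simes_combine([0.01, 0.02, 0.03]) == pytest.approx(0.03)
        assert simes_combine([0.04, 0.5]) == pytest.approx(0.08)

    def test_simes_bounds(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 8)).tolist()
            s = simes_combine(p)
            assert min(p) <= s <= len(p) * min(p) + 1e-12

    def test_simes_empty_errors(self):
        with pytest.raises(ValueError):
            simes_combine([])

    def test_bh_hand_trace(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04], rtol=1e-12
        )

    def test_bh_single_and_cap(self):
        assert bh_adjust([0.2]) == [pytest.approx(0.2)]
        assert bh_adjust([1.0, 1.0]) == [1.0, 1.0]

    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 30)
        ours = bh_adjust(p.tolist())
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, rtol=1e-10)

    def test_bh_preserves_discovery_order(self, rng):
        p = np.sort(rng.uniform(0, 1, 15))
        adj = bh_adjust(p.tolist())
        assert np.all(np.diff(adj) >= -1e-12)


class TestGCBackground:
    def test_degenerate_single_bin(self):
        targets = pd.Series([0.42, 0.44], index=["t1", "t2"])
        universe = pd.Series(
            [0.41, 0.43, 0.81, 0.91], index=["a", "b", "c", "d"]
        )
        bg = gc_matched_background(targets, universe, n_background=100, seed=0)
        assert set(bg) <= {"a", "b"}
        assert len(bg) == 100

    def test_two_equal_bins_split_evenly(self):
        targets = pd.Series([0.12, 0.87], index=["t1", "t2"])
        universe = pd.Series(
            np.r_[np.full(50, 0.12), np.full(50, 0.87)],
            index=[f"u{i}" for i in range(100)],
        )
        bg = gc_matched_background(targets, universe, n_background=1000, seed=1)
        low = sum(universe[b] < 0.5 for b in bg)
        assert low == 500  # largest-remainder allocation is exact here

    def test_deterministic_under_seed(self):
        targets = pd.Series([0.3, 0.5, 0.7], index=["a", "b", "c"])
        universe = pd.Series(np.linspace(0.2, 0.8, 50),
                             index=[f"u{i}" for i in range(50)])
        b1 = gc_matched_background(targets, universe, 200, seed=5)
        b2 = gc_matched_background(targets, universe, 200, seed=5)
        assert list(b1) == list(b2)

    def test_empty_universe_bin_borrows(self):
        targets = pd.Series([0.95], index=["t"])
        universe = pd.Series([0.10, 0.12], index=["a", "b"])
        with pytest.warns(UserWarning, match="borrow"):
            bg = gc_matched_background(targets, universe, 10, seed=2)
        assert len(bg) == 10

    def test_bad_gc_rejected(self):
        with pytest.raises(ValueError):
            gc_matched_background(
                pd.Series([1.2], index=["t"]), pd.Series([0.5], index=["u"]), 10
            )


def _probe_frame(n, rng, chrom="1"):
    pos = np.sort(rng.choice(np.arange(1_000, 10_000_000, 500), n, replace=False))
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "gc": rng.uniform(0.3, 0.7, n)},
        index=pd.Index([f"cg{i}" for i in range(n)], name="probe"),
    )


class TestTfbs:
    def test_single_experiment_equals_fisher(self, rng):
        probes = _probe_frame(400, rng)
        targets = list(probes.index[:20])
        peaks = pd.DataFrame(
            {"chrom": "1", "start": probes.loc[targets, "pos"] - 1,
             "end": probes.loc[targets, "pos"] + 1}
        )
        out = tfbs_enrichment({"TF1": targets}, {"TF1": [peaks]}, probes, 500, seed=3)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["n_experiments"] == 1 and bool(row["tested"])
        # Simes over one experiment is that experiment's Fisher p
        assert row["p"] < 1e-6  # planted full overlap

    def test_planted_enrichment_detected(self, rng):
        probes = _probe_frame(600, rng)
        targets = list(probes.index[:30])
        cover = probes.loc[targets, "pos"]
        peaks1 = pd.DataFrame({"chrom": "1", "start": cover - 5, "end": cover + 5})
        # second experiment covering targets plus 10% of the universe
        extra = probes["pos"].iloc[::10]
        peaks2 = pd.DataFrame(
            {"chrom": "1", "start": np.r_[cover - 5, extra - 5],
             "end": np.r_[cover + 5, extra + 5]}
        )
        out = tfbs_enrichment(
            {"TF1": targets}, {"TF1": [peaks1, peaks2]}, probes, 2000, seed=4
        )
        assert bool(out.iloc[0]["significant"])
        assert out.iloc[0]["odds_ratio"] > 5

    def test_simes_applied_over_experiments(self, rng):
        # experiments with no overlap difference: p near 1; the combined p
        # must obey the Simes bounds relative to per-experiment p-values
        probes = _probe_frame(300, rng)
        targets = list(probes.index[:10])
        null_peaks = pd.DataFrame(
            {"chrom": "1", "start": probes["pos"] - 1, "end": probes["pos"] + 1}
        )  # covers everything: no enrichment signal
        out = tfbs_enrichment(
            {"TF1": targets}, {"TF1": [null_peaks, null_peaks]}, probes, 500, seed=5
        )
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_tf_without_peaks_untested(self, rng):
        probes = _probe_frame(100, rng)
        out = tfbs_enrichment({"TF1": list(probes.index[:5])}, {}, probes, 100)
        assert not bool(out.iloc[0]["tested"])

    def test_min_targets_gate(self, rng):
        probes = _probe_frame(100, rng)
        out = tfbs_enrichment({"TF1": [probes.index[0]]}, {}, probes, 100)
        assert len(out) == 0


class TestChromatinStates:
    def _segments(self, state):
        return pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [10_000], "state": [state]}
        )

    def test_unanimous(self):
        segs = {f"ct{i}": self._segments("Quies") for i in range(3)}
        assert chromatin_state_annotation("1", 500, segs) == ("Quies", False)

    def test_mode(self):
        segs = {
            "ct1": self._segments("Enh"),
            "ct2": self._segments("Enh"),
            "ct3": self._segments("TssA"),
        }
        assert chromatin_state_annotation("1", 500, segs) == ("Enh", False)

    def test_tie_canonical_order(self):
        segs = {"ct1": self._segments("Enh"), "ct2": self._segments("TssA")}
        state, tie = chromatin_state_annotation("1", 500, segs)
        assert tie is True
        assert state == "TssA"  # earlier in the canonical 15-state order
        assert ROADMAP_STATE_ORDER.index("TssA") < ROADMAP_STATE_ORDER.index("Enh")

    def test_outside_segments_unannotated(self):
        segs = {"ct1": self._segments("Enh")}
        assert chromatin_state_annotation("2", 500, segs) == ("unannotated", False)


class TestCisLinks:
    def test_driven_link_detected_and_window_respected(self, rng):
        n = 500
        genes = pd.DataFrame(
            {"chrom": ["3", "3"], "tss": [1_000_000, 1_400_000],
             "tes": [1_010_000, 1_410_000]},
            index=pd.Index(["near", "far"], name="gene"),
        )
        probes = pd.DataFrame(
            {"chrom": ["3"], "pos": [1_100_000]},
            index=pd.Index(["cg1"], name="probe"),
        )
        e_near = rng.standard_normal(n)
        expression = pd.DataFrame(
            {"near": e_near, "far": rng.standard_normal(n)}
        )
        methylation = pd.DataFrame({"cg1": 0.7 * e_near + rng.standard_normal(n)})
        cov = pd.DataFrame({"c": rng.standard_normal(n)})
        out = cis_expression_links(
            ["cg1"], expression, methylation, cov, genes, probes
        )
        # gene 'far' is 300 kb away: untested
        assert set(out["gene"]) == {"near"}
        assert bool(out.iloc[0]["significant"])
        assert out.iloc[0]["beta"] > 0

    def test_null_links_uniform(self, rng):
        n, m = 300, 60
        genes = pd.DataFrame(
            {"chrom": ["3"] * m, "tss": np.arange(m) * 1_000_000 + 1_000_000,
             "tes": np.arange(m) * 1_000_000 + 1_010_000},
            index=pd.Index([f"g{i}" for i in range(m)], name="gene"),
        )
        probes = pd.DataFrame(
            {"chrom": ["3"] * m, "pos": np.arange(m) * 1_000_000 + 1_050_000},
            index=pd.Index([f"cg{i}" for i in range(m)], name="probe"),
        )
        expression = pd.DataFrame(
            rng.standard_normal((n, m)), columns=genes.index
        )
        methylation = pd.DataFrame(
            rng.standard_normal((n, m)), columns=probes.index
        )
        cov = pd.DataFrame({"c": rng.standard_normal(n)})
        out = cis_expression_links(
            list(probes.index), expression, methylation, cov, genes, probes
        )
        assert stats.kstest(out["p"], "uniform").pvalue > 0.01

    def test_no_genes_in_window_empty(self, rng):
        genes = pd.DataFrame(
            {"chrom": ["5"], "tss": [1], "tes": [10]},
            index=pd.Index(["g"], name="gene"),
        )
        probes = pd.DataFrame(
            {"chrom": ["3"], "pos": [100]}, index=pd.Index(["cg"], name="probe")
        )
        out = cis_expression_links(
            ["cg"], pd.DataFrame({"g": rng.standard_normal(50)}),
            pd.DataFrame({"cg": rng.standard_normal(50)}),
            pd.DataFrame({"c": rng.standard_normal(50)}), genes, probes,
        )
        assert len(out) == 0
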