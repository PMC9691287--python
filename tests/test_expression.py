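"""Normalization, DE, BH, enrichment and PCA against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from bsplice.containers import CountMatrix, NormalizationError
from bsplice.expression import (
    bh_adjust,
    de_test,
    geneset_direction_summary,
    go_enrichment,
    pca_projection,
    size_factors,
)
from bsplice.synthetic import SimulationConfig, generate_counts


def brute_force_bh(p):
    """Independent BH step-up: literal definition, O(n^2)-ish."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(1.0, p[i] * n / rank_from_top)
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj


def hypergeom_tail(k, M, n, N):
    """Exhaustive upper-tail P(X >= k) by summation of the pmf."""
    total = 0.0
    for x in range(k, min(n, N) + 1):
        total += math.comb(n, x) * math.comb(M - n, N - x) / math.comb(M, N)
    return total


class TestSizeFactors:
    def test_identical_columns_get_unit_factors(self):
        counts = pd.DataFrame({"s1": [5, 10, 3], "s2": [5, 10, 3]}, index=list("abc"))
        cm = CountMatrix(counts, {"s1": "x", "s2": "x"})
        assert np.allclose(size_factors(cm), [1.0, 1.0])

    def test_doubled_column_gives_sqrt2_split(self):
        counts = pd.DataFrame({"s1": [5, 10, 3], "s2": [10, 20, 6]}, index=list("abc"))
        cm = CountMatrix(counts, {"s1": "x", "s2": "x"})
        sf = size_factors(cm)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])
        assert np.isclose(np.exp(np.log(sf).mean()), 1.0)

    def test_single_sample_gets_factor_one(self):
        cm = CountMatrix(pd.DataFrame({"s1": [4, 2]}, index=list("ab")), {"s1": "x"})
        assert size_factors(cm).iloc[0] == pytest.approx(1.0)

    def test_all_zero_matrix_raises(self):
        cm = CountMatrix(pd.DataFrame({"s1": [0, 0]}, index=list("ab")), {"s1": "x"})
        with pytest.raises(NormalizationError):
            size_factors(cm)


class TestBhAdjust:
    def test_hand_computed_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_degenerate_inputs(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert bh_adjust([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_and_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(1, 40)
            p = rng.uniform(size=n)
            if rng.random() < 0.3:  # inject ties
                p[: n // 2] = p[0]
            ours = bh_adjust(p)
            assert np.allclose(ours, brute_force_bh(p), atol=1e-12)
            assert np.allclose(ours, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestDeTest:
    def test_identical_groups_are_ns(self, small_matrix):
        res = de_test(small_matrix, "A", "B")
        assert (res["status"] == "ns").all()
        # handmade matrix has near-identical groups; exact-zero gene is exact
        assert res.loc["g_zero", "log2fc"] == 0.0
        assert res.loc["g_zero", "pvalue"] == 1.0

    def test_status_respects_both_gates(self, default_panel):
        panel, _ = default_panel
        res = de_test(panel, "PC", "MBC", alpha=0.05, lfc_cut=0.5)
        up = res[res["status"] == "up"]
        dn = res[res["status"] == "down"]
        assert (up["padj"] < 0.05).all() and (up["log2fc"] > 0.5).all()
        assert (dn["padj"] < 0.05).all() and (dn["log2fc"] < -0.5).all()
        ns = res[res["status"] == "ns"]
        assert ((ns["padj"] >= 0.05) | (ns["log2fc"].abs() <= 0.5)).all()

    def test_unknown_condition_raises(self, small_matrix):
        with pytest.raises(KeyError):
            de_test(small_matrix, "A", "nope")

    def test_invariant_to_column_order_and_common_scaling(self):
        panel, _ = generate_counts(SimulationConfig(seed=13, n_genes=500))
        res = de_test(panel, "PC", "MBC", alpha=0.05)
        shuffled = panel.subset_samples(panel.sample_ids[::-1])
        res2 = de_test(shuffled, "PC", "MBC", alpha=0.05)
        pd.testing.assert_frame_equal(res, res2)
        # common scaling is absorbed by the size factors; the +1 pseudocount
        # makes the invariance approximate at finite counts
        scaled = CountMatrix(panel.counts * 3, panel.condition_of)
        res3 = de_test(scaled, "PC", "MBC", alpha=0.05)
        assert np.allclose(res["pvalue"], res3["pvalue"], atol=1e-3)
        assert (res["status"] == res3["status"]).all()

    def test_recovery_of_planted_genes(self):
        """Sensitivity >= 0.9 and empirical FDR <= 0.05 over 20 seeds at the
        FDR-0.05 operating point (planted effect 2, triplicates)."""
        sens, fdr = [], []
        for seed in range(20):
            panel, truth = generate_counts(SimulationConfig(seed=seed))
            res = de_test(panel, "PC", "MBC", alpha=0.05)
            up = set(res.index[res["status"] == "up"])
            dn = set(res.index[res["status"] == "down"])
            true_up = {g for g, l in truth.de_genes.items() if l > 0}
            true_dn = {g for g, l in truth.de_genes.items() if l < 0}
            tp = len(up & true_up) + len(dn & true_dn)
            called = len(up) + len(dn)
            sens.append(tp / len(truth.de_genes))
            fdr.append((called - tp) / max(called, 1))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdr) <= 0.05


class TestGenesetDirectionSummary:
    def _de(self):
        return pd.DataFrame(
            {"status": ["up", "up", "up", "down", "ns", "ns"]},
            index=[f"g{i}" for i in range(6)],
        )

    def test_counts_by_direction(self):
        n_up, n_down, n_in = geneset_direction_summary(
            self._de(), {"g0", "g1", "g2", "g3", "g4"}
        )
        assert (n_up, n_down, n_in) == (3, 1, 5)

    def test_empty_and_disjoint_sets(self):
        assert geneset_direction_summary(self._de(), set()) == (0, 0, 0)
        assert geneset_direction_summary(self._de(), {"zz"}) == (0, 0, 0)


class TestGoEnrichment:
    def test_zero_overlap_has_p_one(self):
        out = go_enrichment({"a"}, {"a", "b", "c", "d"}, {"s": {"b", "c"}})
        assert out.loc["s", "pvalue"] == 1.0

    def test_set_equal_to_universe_has_p_one(self):
        uni = {f"g{i}" for i in range(30)}
        hits = {f"g{i}" for i in range(5)}
        out = go_enrichment(hits, uni, {"s": set(uni)})
        assert out.loc["s", "pvalue"] == pytest.approx(1.0)

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment({"x"}, {"a"}, {})

    def test_matches_exhaustive_tail_sum(self):
        """Hypergeometric p equals brute-force tail summation on small sets."""
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(60)]
        for _ in range(200):
            hits = set(rng.choice(universe, size=rng.integers(1, 20), replace=False))
            gs = set(rng.choice(universe, size=rng.integers(1, 25), replace=False))
            out = go_enrichment(hits, set(universe), {"s": gs})
            k = len(gs & hits)
            expect = hypergeom_tail(k, 60, len(gs), len(hits)) if k else 1.0
            assert out.loc["s", "pvalue"] == pytest.approx(expect, abs=1e-12)


class TestPca:
    def test_duplicated_sample_projects_identically(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 200, size=(50, 3))
        counts = pd.DataFrame(
            np.column_stack([base, base[:, 0]]),
            index=[f"g{i}" for i in range(50)],
            columns=["s1", "s2", "s3", "s1b"],
        )
        cm = CountMatrix(counts, {c: "x" for c in counts.columns})
        proj = pca_projection(cm)
        assert np.allclose(proj.loc["s1"], proj.loc["s1b"], atol=1e-8)

    def test_pc1_separates_two_planted_clusters(self, default_panel):
        panel, _ = default_panel
        proj = pca_projection(panel)
        mbc = [s for s in proj.index if s.startswith("MBC")]
        rest = [s for s in proj.index if not s.startswith("MBC")]
        lo, hi = proj.loc[mbc, "PC1"], proj.loc[rest, "PC1"]
        # planted MBC effects separate MBC from the rest on PC1
        assert (hi.min() > lo.max()) or (lo.min() > hi.max())
        ev = proj.attrs["explained_variance"]
        assert ev[0] >= ev[1]

    def test_too_many_components_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            pca_projection(small_matrix, n_components=9)
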