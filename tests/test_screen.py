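"""Pooled-screen statistics: normalization, z-scores, bootstrap p, FDR."""

import numpy as np
import pandas as pd
import pytest

from pdarkit.screen import (
    NONTARGETING,
    GuideCountTable,
    bh_fdr,
    bootstrap_empiric_p,
    call_hits,
    filter_low_count_guides,
    gene_median_collapse,
    guide_log2fc,
    median_of_ratios_normalize,
    run_screen,
    zscore_to_nontargeting,
)
from pdarkit.simulate import SimConfig, simulate_screen_counts


def toy_table(counts: dict, genes=None) -> GuideCountTable:
    n = len(next(iter(counts.values())))
    genes = genes or [f"G{i}" for i in range(n)]
    df = pd.DataFrame({"guide_id": [f"sg{i}" for i in range(n)], "gene": genes, **counts})
    return GuideCountTable.from_frame(df)


class TestMedianOfRatios:
    def test_identical_columns_unit_factors(self):
        t = toy_table({"a": [10.0, 20, 30], "b": [10.0, 20, 30]})
        norm = median_of_ratios_normalize(t)
        np.testing.assert_allclose(norm.size_factors, [1.0, 1.0])

    def test_doubled_column_factor_two(self):
        t = toy_table({"a": [10.0, 20, 30], "b": [20.0, 40, 60]})
        norm = median_of_ratios_normalize(t)
        # geometric-mean reference: factors sqrt(1/2) and sqrt(2)
        assert norm.size_factors["b"] / norm.size_factors["a"] == pytest.approx(2.0)
        pd.testing.assert_series_equal(norm.counts["a"], norm.counts["b"], check_names=False)

    def test_depth_distortion_removed(self):
        """Per-sample depth scalings cancel: fold changes between samples
        are invariant to multiplying any column by a constant."""
        t = toy_table({"a": [10.0, 25, 33], "b": [14.0, 21, 40]})
        distorted = toy_table({"a": [50.0, 125, 165], "b": [7.0, 10.5, 20]})
        r1 = median_of_ratios_normalize(t)
        r2 = median_of_ratios_normalize(distorted)
        fc1 = r1.counts["a"] / r1.counts["b"]
        fc2 = r2.counts["a"] / r2.counts["b"]
        np.testing.assert_allclose(fc1, fc2)

    def test_zero_guides_excluded_from_reference(self):
        t = toy_table({"a": [0.0, 20, 30], "b": [15.0, 20, 30]})
        norm = median_of_ratios_normalize(t)
        assert np.all(norm.size_factors > 0)

    def test_all_zero_rows_rejected(self):
        t = toy_table({"a": [0.0, 0.0], "b": [1.0, 0.0]})
        with pytest.raises(ValueError):
            median_of_ratios_normalize(t)


class TestLowCountFilter:
    def test_bottom_guides_removed(self):
        counts = {"a": [100.0] * 100 + [0.5, 0.2], "b": [100.0] * 100 + [0.4, 0.1]}
        t = toy_table(counts)
        out = filter_low_count_guides(t, quantile=0.02)
        assert len(out.counts) == 100
        assert not out.guides["guide_id"].str.startswith("sg10").iloc[-1]

    def test_quantile_zero_is_identity(self):
        t = toy_table({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        out = filter_low_count_guides(t, quantile=0)
        assert len(out.counts) == 3

    def test_all_equal_counts_nothing_removed(self):
        t = toy_table({"a": [5.0] * 50, "b": [5.0] * 50})
        out = filter_low_count_guides(t, quantile=0.02)
        assert len(out.counts) == 50  # ties at the cutoff are kept


class TestLog2FC:
    def test_equal_counts_zero(self):
        t = toy_table({"a": [10.0, 20], "b": [10.0, 20]})
        np.testing.assert_allclose(guide_log2fc(t, ("a", "b")), 0.0)

    def test_doubling_near_one(self):
        t = toy_table({"a": [2000.0], "b": [1000.0]})
        assert guide_log2fc(t, ("a", "b")).iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_both_zero_pseudocount_symmetry(self):
        t = toy_table({"a": [0.0], "b": [0.0]})
        assert guide_log2fc(t, ("a", "b")).iloc[0] == 0.0

    def test_missing_sample_rejected(self):
        t = toy_table({"a": [1.0], "b": [1.0]})
        with pytest.raises(ValueError):
            guide_log2fc(t, ("a", "c"))


class TestZScore:
    def test_hand_values(self):
        nt = np.array([-1.0, 1.0, -1.0, 1.0, -1.0, 1.0])  # mean 0, sd ~1.095
        s = pd.Series([2.0])
        got = zscore_to_nontargeting(s, nt)
        assert got.iloc[0] == pytest.approx(2.0 / nt.std(ddof=1))

    def test_shifted_scaled(self):
        nt = np.array([0.0, 2.0, 0.0, 2.0])  # mean 1
        s = pd.Series([5.0, 1.0])
        got = zscore_to_nontargeting(s, nt)
        assert got.iloc[0] == pytest.approx(4.0 / nt.std(ddof=1))
        assert got.iloc[1] == 0.0

    def test_nontargeting_self_standardized(self):
        rng = np.random.default_rng(2)
        nt = pd.Series(rng.normal(3, 2, 142))
        z = zscore_to_nontargeting(nt, nt.to_numpy())
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ValueError):
            zscore_to_nontargeting(pd.Series([1.0]), [2.0, 2.0, 2.0])


class TestGeneCollapse:
    def test_even_count_median(self):
        z = pd.Series([1.0, 2.0, 3.0, 4.0])
        genes = pd.Series(["g"] * 4)
        assert gene_median_collapse(z, genes).loc["g"] == 2.5

    def test_hand_median(self):
        z = pd.Series([-3.0, -2.0, 5.0, 6.0])
        genes = pd.Series(["g"] * 4)
        assert gene_median_collapse(z, genes).loc["g"] == 1.5

    def test_single_guide(self):
        out = gene_median_collapse(pd.Series([0.7]), pd.Series(["g"]))
        assert out.loc["g"] == 0.7

    def test_nontargeting_excluded(self):
        z = pd.Series([1.0, 2.0, 100.0])
        genes = pd.Series(["g", "g", NONTARGETING])
        out = gene_median_collapse(z, genes)
        assert NONTARGETING not in out.index


class TestBootstrapP:
    def test_extreme_observation_floor(self):
        rng = np.random.default_rng(0)
        pool = rng.normal(0, 1, 400)
        med = pd.Series({"g": 50.0})
        p = bootstrap_empiric_p(med, pool, 4, B=1000, seed=1)
        assert p.loc["g"] == pytest.approx(1 / 1001)

    def test_central_observation_near_one(self):
        rng = np.random.default_rng(0)
        pool = rng.normal(0, 1, 400)
        med = pd.Series({"g": 0.0})
        p = bootstrap_empiric_p(med, pool, 4, B=2000, seed=1)
        assert p.loc["g"] > 0.9

    def test_monte_carlo_stability_in_B(self):
        rng = np.random.default_rng(0)
        pool = rng.normal(0, 1, 400)
        med = pd.Series({"g": 0.8})
        p1 = bootstrap_empiric_p(med, pool, 4, B=5000, seed=1).loc["g"]
        p2 = bootstrap_empiric_p(med, pool, 4, B=10000, seed=2).loc["g"]
        assert abs(p1 - p2) < 2 / np.sqrt(5000)

    def test_small_B_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_empiric_p(pd.Series({"g": 1.0}), np.zeros(10), 4, B=10, seed=0)


class TestBH:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 50)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestHitCalls:
    def test_threshold_strict(self):
        df = pd.DataFrame({"median_z": [2.0, -3.0], "q": [0.05, 0.10]})
        out = call_hits(df)
        assert out["hit"].tolist() == [True, False]
        assert out["direction"].tolist() == ["enriched", "depleted"]


class TestEndToEnd:
    def test_null_screen_controls_type_one_error(self):
        cfg = SimConfig(seed=11, n_genes=300)
        table = simulate_screen_counts(cfg)
        res = run_screen(table, contrast=("dead", "live"), B=2000, seed=11)
        assert res["hit"].mean() <= 0.02

    def test_effect_genes_recovered(self):
        effects = {f"GENE{i:04d}": 4.0 for i in range(10)}
        cfg = SimConfig(seed=21, n_genes=300, effects=effects)
        table = simulate_screen_counts(cfg)
        res = run_screen(table, contrast=("dead", "live"), B=2000, seed=21)
        hits = set(res[res["hit"]]["gene"])
        assert len(hits & set(effects)) >= 9

    def test_seed_reproducibility(self):
        cfg = SimConfig(seed=5, n_genes=100)
        t1 = simulate_screen_counts(cfg)
        r1 = run_screen(t1, contrast=("dead", "live"), B=1000, seed=5)
        r2 = run_screen(t1, contrast=("dead", "live"), B=1000, seed=5)
        pd.testing.assert_frame_equal(r1, r2)
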