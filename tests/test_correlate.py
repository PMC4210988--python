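"""Correlation graph construction, thresholding, and threshold selection."""

import logging

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from glomnet import (
    BlockSpec,
    CorrelationGraph,
    DataMatrix,
    apply_threshold,
    correlation_matrix,
    generate_block_data,
    select_threshold,
    threshold_profile,
    zscore_normalize,
)

from conftest import random_data_matrix


def make_cg(ids, pairs, method="pearson", n_obs=50):
    """CorrelationGraph from a {(a, b): r} dict; unspecified pairs are 0."""
    p = len(ids)
    w = np.zeros((p, p))
    np.fill_diagonal(w, 1.0)
    idx = {v: i for i, v in enumerate(ids)}
    for (a, b), r in pairs.items():
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = r
    return CorrelationGraph(list(ids), w, method, np.full((p, p), n_obs))


class TestCorrelationMatrix:
    def test_product_moment_example(self):
        dm = DataMatrix(
            ["u1", "u2", "u3", "u4"], ["x", "y"],
            np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0], [4.0, 3.0]]),
        )
        cg = correlation_matrix(dm, min_overlap=2)
        assert cg.r("x", "y") == pytest.approx(0.6)
        assert cg.r("x", "x") == 1.0

    def test_perfect_anticorrelation(self):
        x = np.arange(5.0)
        dm = DataMatrix([f"u{i}" for i in range(5)], ["x", "negx"],
                        np.column_stack([x, -x]))
        cg = correlation_matrix(dm, min_overlap=2)
        assert cg.r("x", "negx") == pytest.approx(-1.0)

    def test_spearman_monotone_pair(self):
        dm = DataMatrix(["u1", "u2", "u3"], ["x", "y"],
                        np.array([[1.0, 1.0], [2.0, 4.0], [3.0, 9.0]]))
        cg = correlation_matrix(dm, method="spearman", min_overlap=2)
        assert cg.r("x", "y") == pytest.approx(1.0)

    def test_spearman_equals_pearson_on_ranks(self, rng):
        dm = random_data_matrix(rng, n_units=30, n_vars=6)
        sp = correlation_matrix(dm, method="spearman", min_overlap=3).weights
        ranked = DataMatrix(dm.unit_ids, dm.variable_ids, rankdata(dm.values, axis=0))
        pe = correlation_matrix(ranked, method="pearson", min_overlap=3).weights
        assert np.allclose(sp, pe, atol=1e-10)

    def test_min_overlap_marks_missing(self, rng):
        dm = random_data_matrix(rng, n_units=12, n_vars=3)
        dm.values[:8, 0] = np.nan  # only 4 complete obs against others
        cg = correlation_matrix(dm, min_overlap=5)
        assert np.isnan(cg.r("x0", "x1"))
        assert not np.isnan(cg.r("x1", "x2"))
        assert cg.n_obs[0, 1] == 4

    def test_degenerate_pair_logged_not_raised(self, rng, caplog):
        dm = random_data_matrix(rng, n_units=15, n_vars=3)
        dm.values[:, 1] = 2.0  # constant: zero variance on any subset
        with caplog.at_level(logging.INFO):
            cg = correlation_matrix(dm, min_overlap=3)
        assert np.isnan(cg.r("x0", "x1"))
        assert not np.isnan(cg.r("x0", "x2"))

    def test_rejected_and_unknown_methods(self, tiny_matrix):
        with pytest.raises(ValueError, match="not supported"):
            correlation_matrix(tiny_matrix, method="mutual_information")
        with pytest.raises(ValueError, match="unknown"):
            correlation_matrix(tiny_matrix, method="kendall")

    def test_pairwise_complete_matches_pandas(self, rng):
        dm = random_data_matrix(rng, n_units=40, n_vars=5, missing_rate=0.2)
        cg = correlation_matrix(dm, min_overlap=3)
        ref = dm.to_dataframe().corr(min_periods=3).to_numpy()
        assert np.allclose(cg.weights, ref, atol=1e-12, equal_nan=True)


class TestCorrelationGraphInvariants:
    def test_symmetry_and_diagonal_enforced(self):
        w = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            CorrelationGraph(["a", "b"], w, "pearson", np.full((2, 2), 9))
        w2 = np.array([[0.9, 0.5], [0.5, 1.0]])
        with pytest.raises(ValueError, match="diagonal"):
            CorrelationGraph(["a", "b"], w2, "pearson", np.full((2, 2), 9))

    def test_out_of_range_rejected(self):
        w = np.array([[1.0, 1.5], [1.5, 1.0]])
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            CorrelationGraph(["a", "b"], w, "pearson", np.full((2, 2), 9))

    def test_subset_preserves_structure(self, rng):
        dm = random_data_matrix(rng, n_units=20, n_vars=6)
        cg = correlation_matrix(dm, min_overlap=3)
        sub = cg.subset(["x1", "x3", "x5"])
        assert sub.variable_ids == ["x1", "x3", "x5"]
        assert sub.r("x1", "x3") == cg.r("x1", "x3")


class TestApplyThreshold:
    def test_absolute_rule_keeps_negative_edge(self):
        cg = make_cg("abc", {("a", "b"): 0.9, ("a", "c"): 0.5, ("b", "c"): -0.7})
        g = apply_threshold(cg, 0.6, absolute=True)
        assert set(map(frozenset, g.edges())) == {frozenset("ab"), frozenset("bc")}
        assert g.n_vertices == 3  # c kept as an isolated-ish vertex

    def test_signed_rule_drops_negative_edge(self):
        cg = make_cg("abc", {("a", "b"): 0.9, ("a", "c"): 0.5, ("b", "c"): -0.7})
        g = apply_threshold(cg, 0.6, absolute=False)
        assert set(map(frozenset, g.edges())) == {frozenset("ab")}

    def test_boundaries(self):
        cg = make_cg("abc", {("a", "b"): 1.0, ("a", "c"): 0.5, ("b", "c"): 0.2})
        assert apply_threshold(cg, 0.0).n_edges == 3  # complete at t=0
        assert set(map(frozenset, apply_threshold(cg, 1.0).edges())) == {frozenset("ab")}
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            apply_threshold(cg, 1.0 + 1e-9)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            apply_threshold(cg, -0.1)

    def test_missing_entries_never_edges(self):
        cg = make_cg("abc", {("a", "b"): 0.9})
        cg.weights[0, 2] = cg.weights[2, 0] = np.nan
        g = apply_threshold(cg, 0.0)
        assert not g.has_edge("a", "c")

    def test_antitone_in_t(self, rng):
        dm = random_data_matrix(rng, n_units=10, n_vars=8)
        cg = correlation_matrix(dm, min_overlap=3)
        grid = [0.1, 0.3, 0.5, 0.7, 0.9]
        edge_sets = [set(apply_threshold(cg, t).edges()) for t in grid]
        for lo, hi in zip(edge_sets, edge_sets[1:]):
            assert hi <= lo


class TestThresholdProfile:
    def test_monotone_columns_on_random_inputs(self, rng):
        for _ in range(5):
            dm = random_data_matrix(rng, n_units=12, n_vars=10)
            cg = correlation_matrix(dm, min_overlap=3)
            prof = threshold_profile(cg, [0.1 * k for k in range(10)])
            assert (np.diff(prof["n_edges"]) <= 0).all()
            assert (np.diff(prof["lambda1"]) <= 1e-8).all()

    def test_all_missing_gives_zero_edges(self):
        w = np.full((3, 3), np.nan)
        np.fill_diagonal(w, 1.0)
        cg = CorrelationGraph(["a", "b", "c"], w, "pearson", np.zeros((3, 3), int))
        prof = threshold_profile(cg, [0.0, 0.5, 0.9])
        assert (prof["n_edges"] == 0).all()
        assert (prof["lambda1"] == 0).all()

    def test_grid_validation(self, rng):
        cg = correlation_matrix(random_data_matrix(rng, 10, 4), min_overlap=3)
        with pytest.raises(ValueError, match="increasing"):
            threshold_profile(cg, [0.5, 0.5, 0.6])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            threshold_profile(cg, [0.2, 1.2])

    def test_planted_blocks_drop_location(self):
        """With two planted blocks at within-block |r| ~ 0.8 and noisy
        background, the largest relative drop in lambda1 falls strictly
        between the background and block regimes."""
        blocks = [BlockSpec("P1", 10, 0.9), BlockSpec("P2", 10, 0.9)]
        dm, _ = generate_block_data(n_units=50, blocks=blocks, n_background=40,
                                    seed=11)
        cg = correlation_matrix(zscore_normalize(dm), min_overlap=5)
        # the grid ends below the blocks' own dissolution (within |r| ~ 0.81)
        grid = [round(0.05 * k, 2) for k in range(4, 16)]  # 0.20 .. 0.75
        prof = threshold_profile(cg, grid)
        l1 = prof["lambda1"].to_numpy()
        drops = (l1[:-1] - l1[1:]) / np.where(l1[:-1] > 0, l1[:-1], 1.0)
        t_at_max_drop = grid[int(np.argmax(drops)) + 1]
        assert 0.2 < t_at_max_drop < 0.8


class TestSelectThreshold:
    def test_worked_profile_example(self):
        prof = pd.DataFrame({"t": [0.3, 0.4, 0.5, 0.6],
                             "lambda1": [10.0, 9.8, 4.0, 3.9]})
        assert select_threshold(prof, "spectral_drop") == pytest.approx(0.5)

    def test_constant_column_falls_back_with_warning(self, caplog):
        prof = pd.DataFrame({"t": [0.3, 0.4, 0.5], "lambda1": [5.0, 5.0, 5.0]})
        with caplog.at_level(logging.WARNING):
            t = select_threshold(prof, "spectral_drop")
        assert t == pytest.approx(0.3)
        assert any("no inflection" in r.message for r in caplog.records)

    def test_clique_criterion_uses_clique_column(self):
        prof = pd.DataFrame({"t": [0.3, 0.4, 0.5, 0.6],
                             "max_clique": [20.0, 19.5, 8.0, 7.9]})
        assert select_threshold(prof, "clique_drop") == pytest.approx(0.5)
        with pytest.raises(ValueError, match="max_clique"):
            select_threshold(prof.drop(columns=["max_clique"]).assign(lambda1=1.0)
                             .drop(columns=["lambda1"]), "clique_drop")

    def test_requires_three_grid_points_and_known_criterion(self):
        prof = pd.DataFrame({"t": [0.3, 0.4], "lambda1": [5.0, 4.0]})
        with pytest.raises(ValueError, match="3 grid points"):
            select_threshold(prof)
        with pytest.raises(ValueError, match="unknown criterion"):
            select_threshold(prof, "magic")

    def test_separates_planted_blocks_from_background(self):
        """On planted-block data the selected threshold keeps the blocks as
        dense components and admits almost no background pairs."""
        blocks = [BlockSpec("P1", 12, 0.9), BlockSpec("P2", 12, 0.9)]
        dm, truth = generate_block_data(n_units=60, blocks=blocks,
                                        n_background=60, seed=4)
        cg = correlation_matrix(zscore_normalize(dm), min_overlap=5)
        grid = [round(0.2 + 0.05 * k, 2) for k in range(14)]
        prof = threshold_profile(cg, grid)
        t = select_threshold(prof, "spectral_drop")
        g = apply_threshold(cg, t)
        bg = [v for v, b in truth.membership.items() if b == "background"]
        bg_pairs = sum(
            1 for i, u in enumerate(bg) for v in bg[i + 1:] if g.has_edge(u, v)
        )
        possible_bg = len(bg) * (len(bg) - 1) // 2
        assert bg_pairs / possible_bg < 0.05
        for bid in ("P1", "P2"):
            mem = sorted(truth.block_members(bid))
            within = sum(
                1 for i, u in enumerate(mem) for v in mem[i + 1:] if g.has_edge(u, v)
            )
            possible = len(mem) * (len(mem) - 1) // 2
            assert within / possible > 0.8
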