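"""Outcome ranking, coarsened graph construction, and density matching."""

import numpy as np
import pytest

from glomnet import (
    CoarsenedGraph,
    Paraclique,
    coarsen,
    match_relative_densities,
    rank_paracliques_by_outcome,
)
from glomnet.coarsen import apply_coarse_threshold, read_coarsened_edge_list

from test_correlate import make_cg


def pc(members, index=0):
    members = list(members)
    return Paraclique(core=frozenset(members), glommed=frozenset(),
                      glom_factor=0, extraction_index=index)


def coarsened(n_nodes, edge_weights, seed_nodes="N"):
    """CoarsenedGraph over N0..N{n-1} from {(i, j): (w, pol)} index pairs."""
    ids = tuple(f"{seed_nodes}{i}" for i in range(n_nodes))
    edges = {}
    for (i, j), val in edge_weights.items():
        w, pol = val if isinstance(val, tuple) else (val, 1)
        a, b = sorted((ids[i], ids[j]))
        edges[(a, b)] = (float(w), pol)
    return CoarsenedGraph(ids, {n: frozenset() for n in ids}, edges)


class TestRanking:
    def test_median_and_selection(self):
        cg = make_cg(
            ["y", "a", "b", "c"],
            {("y", "a"): 0.5, ("y", "b"): 0.4, ("y", "c"): 0.3,
             ("a", "b"): 0.9, ("a", "c"): 0.9, ("b", "c"): 0.9},
        )
        out = rank_paracliques_by_outcome(cg, [pc("abc")], "y", cutoff=0.38)
        assert out[0].median_abs_r_to_outcome == pytest.approx(0.4)
        assert out[0].selected

    def test_absolute_values_then_even_count_mean(self):
        cg = make_cg(["y", "a", "b"],
                     {("y", "a"): 0.2, ("y", "b"): -0.9, ("a", "b"): 0.9})
        out = rank_paracliques_by_outcome(cg, [pc("ab")], "y", cutoff=0.38)
        assert out[0].median_abs_r_to_outcome == pytest.approx(0.55)

    def test_cutoff_zero_selects_all_and_sorting(self):
        cg = make_cg(
            ["y", "a", "b", "c", "d"],
            {("y", "a"): 0.1, ("y", "b"): 0.1, ("y", "c"): 0.8, ("y", "d"): 0.8},
        )
        out = rank_paracliques_by_outcome(
            cg, [pc("ab", 0), pc("cd", 1)], "y", cutoff=0.0)
        assert all(rp.selected for rp in out)
        assert [rp.index for rp in out] == [1, 0]  # descending median

    def test_outcome_inside_paraclique_is_circular(self):
        cg = make_cg(["y", "a"], {("y", "a"): 0.5})
        with pytest.raises(ValueError, match="circular"):
            rank_paracliques_by_outcome(cg, [pc(["y", "a"])], "y")

    def test_missing_correlations_excluded_from_median(self):
        cg = make_cg(["y", "a", "b", "c"],
                     {("y", "a"): 0.6, ("y", "b"): 0.4})
        cg.weights[0, 3] = cg.weights[3, 0] = np.nan
        out = rank_paracliques_by_outcome(cg, [pc("abc")], "y")
        assert out[0].median_abs_r_to_outcome == pytest.approx(0.5)


class TestCoarsen:
    def test_median_weight_and_positive_majority(self):
        cg = make_cg(
            ["a1", "a2", "b1", "b2", "b3"],
            {("a1", "a2"): 0.9, ("b1", "b2"): 0.9, ("b1", "b3"): 0.9,
             ("b2", "b3"): 0.9,
             # cross pairs from a1 only; a2's cross entries stay 0
             ("a1", "b1"): 0.6, ("a1", "b2"): 0.7, ("a1", "b3"): 0.8},
        )
        co = coarsen(cg, [pc(["a1"], 0), pc(["b1", "b2", "b3"], 1)])
        (w, pol), = co.edges.values()
        assert w == pytest.approx(0.7)
        assert pol == 1

    def test_negative_majority_with_absolute_median(self):
        cg = make_cg(
            ["a1", "b1", "b2", "b3"],
            {("a1", "b1"): -0.5, ("a1", "b2"): -0.6, ("a1", "b3"): 0.1},
        )
        co = coarsen(cg, [pc(["a1"], 0), pc(["b1", "b2", "b3"], 1)])
        (w, pol), = co.edges.values()
        assert w == pytest.approx(0.5)  # median of |{0.5, 0.6, 0.1}|
        assert pol == -1

    def test_all_zero_cross_pairs(self):
        cg = make_cg(["a1", "b1"], {})
        co = coarsen(cg, [pc(["a1"], 0), pc(["b1"], 1)])
        (w, pol), = co.edges.values()
        assert w == 0.0 and pol == 1

    def test_sign_tie_falls_back_to_signed_median(self):
        cg = make_cg(["a1", "b1", "b2"],
                     {("a1", "b1"): 0.5, ("a1", "b2"): -0.6})
        co = coarsen(cg, [pc(["a1"], 0), pc(["b1", "b2"], 1)])
        (_, pol), = co.edges.values()
        assert pol == -1  # signed median (0.5 - 0.6)/2 < 0

    def test_missing_pair_edge_absent(self):
        cg = make_cg(["a1", "b1", "c1"], {("a1", "b1"): 0.5})
        cg.weights[0, 2] = cg.weights[2, 0] = np.nan
        cg.weights[1, 2] = cg.weights[2, 1] = np.nan
        co = coarsen(cg, [pc(["a1"], 0), pc(["b1"], 1), pc(["c1"], 2)])
        assert len(co.edges) == 1  # only the (P0, P1) edge exists

    def test_weight_is_recomputable_from_source(self, rng):
        """Spot-check: every coarsened weight equals the median |r| of the
        underlying cross-pair correlations, recomputed independently."""
        ids = [f"v{i}" for i in range(9)]
        w = np.clip((rng.random((9, 9)) * 2 - 1), -0.99, 0.99)
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        cg = make_cg(ids, {})
        cg.weights[:] = w
        groups = [ids[:3], ids[3:6], ids[6:]]
        co = coarsen(cg, [pc(g, i) for i, g in enumerate(groups)])
        for (na, nb), (weight, _) in co.edges.items():
            ga = groups[int(na[1:])]
            gb = groups[int(nb[1:])]
            vals = [abs(cg.r(u, v)) for u in ga for v in gb]
            assert weight == pytest.approx(np.median(vals))

    def test_needs_two_paracliques(self):
        cg = make_cg(["a1"], {})
        with pytest.raises(ValueError, match="at least 2"):
            coarsen(cg, [pc(["a1"])])


class TestDensityMatching:
    def test_identical_graphs_unchanged(self):
        g = coarsened(5, {(0, 1): 0.9, (1, 2): 0.7, (2, 3): 0.5})
        a, b = match_relative_densities(g, g)
        assert a.edges == g.edges and b.edges == g.edges

    def test_denser_graph_pruned_to_sparser(self):
        full = coarsened(5, {(i, j): 0.5 + 0.05 * (i + j)
                             for i in range(5) for j in range(i + 1, 5)})
        sparse = coarsened(5, {(0, 1): 0.9, (1, 2): 0.8, (2, 3): 0.7, (3, 4): 0.6},
                           seed_nodes="M")
        a, b = match_relative_densities(full, sparse)
        assert a.n_edges == 4 and b.n_edges == 4
        # the survivors are the heaviest edges
        assert min(w for w, _ in a.edges.values()) >= max(
            w for (k, (w, _)) in full.edges.items() if k not in a.edges)

    def test_rounding_rule(self):
        # A: 3 nodes, 3 edges (density 1); B: 5 nodes, 4/10 edges
        a = coarsened(3, {(0, 1): 0.9, (1, 2): 0.8, (0, 2): 0.7})
        b = coarsened(5, {(0, 1): 0.9, (1, 2): 0.8, (2, 3): 0.7, (3, 4): 0.6},
                      seed_nodes="M")
        ma, mb = match_relative_densities(a, b)
        assert ma.n_edges == 1  # round(0.4 * 3) = 1
        assert mb.n_edges == 4

    def test_density_gap_within_one_edge_on_random_pairs(self, rng):
        for _ in range(25):
            na, nb = int(rng.integers(3, 9)), int(rng.integers(3, 9))
            ga = coarsened(na, {
                (i, j): float(rng.random())
                for i in range(na) for j in range(i + 1, na)
                if rng.random() < 0.7})
            gb = coarsened(nb, {
                (i, j): float(rng.random())
                for i in range(nb) for j in range(i + 1, nb)
                if rng.random() < 0.7}, seed_nodes="M")
            ma, mb = match_relative_densities(ga, gb)
            gap = abs(ma.density() - mb.density())
            assert gap <= 1.0 / min(ma.possible_edges, mb.possible_edges) + 1e-12

    def test_zero_target_warns(self, caplog):
        import logging

        a = coarsened(3, {})
        b = coarsened(3, {(0, 1): 0.9}, seed_nodes="M")
        with caplog.at_level(logging.WARNING):
            ma, mb = match_relative_densities(a, b)
        assert ma.n_edges == 0 and mb.n_edges == 0

    def test_base_thresholds_applied_first(self):
        g = coarsened(4, {(0, 1): 0.9, (1, 2): 0.4, (2, 3): 0.2})
        assert apply_coarse_threshold(g, 0.5).n_edges == 1
        a, b = match_relative_densities(g, g, base_threshold_a=0.5,
                                        base_threshold_b=0.0)
        assert a.n_edges == 1 and b.n_edges == 1


class TestCoarsenedGraphIO:
    def test_edge_list_round_trip(self, tmp_path):
        g = coarsened(4, {(0, 1): (0.9, 1), (1, 2): (0.5, -1)})
        path = tmp_path / "coarse.tsv"
        g.write_edge_list(path)
        back = read_coarsened_edge_list(path)
        assert back.edges == g.edges

    def test_validation(self):
        with pytest.raises(ValueError, match="polarity"):
            CoarsenedGraph(("A", "B"), {"A": frozenset(), "B": frozenset()},
                           {("A", "B"): (0.5, 0)})
        with pytest.raises(ValueError, match="ordered"):
            CoarsenedGraph(("A", "B"), {"A": frozenset(), "B": frozenset()},
                           {("B", "A"): (0.5, 1)})
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            CoarsenedGraph(("A", "B"), {"A": frozenset(), "B": frozenset()},
                           {("A", "B"): (1.5, 1)})
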