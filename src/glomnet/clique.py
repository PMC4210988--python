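"""Exact maximum clique via the vertex-cover complementary dual.

A maximum clique of G is the complement of a minimum vertex cover of the
complement graph: |max_clique(G)| + |min_vertex_cover(complement(G))| = |V|.
Vertex cover is solved exactly with a bounded search tree — kernelization
(degree-0 removal, degree-1 forced neighbour, high-degree rule against the
current budget), a greedy initial upper bound, and a maximal-matching lower
bound for pruning.  Branching picks the highest-degree vertex (ties by vertex
index), so results are deterministic for a fixed vertex order.

The clique search decomposes the input into connected components first: a
maximum clique lives inside one component, and solving the vertex-cover dual
on the complement of each (small) component is far cheaper than on the
complement of the whole graph.

Brute-force oracles (exhaustive search, independent of the solver above) and
a pivoting Bron-Kerbosch maximal-clique enumerator are included for testing
and as building blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

from .graphs import SimpleGraph, _bits

__all__ = [
    "is_clique",
    "minimum_vertex_cover",
    "maximum_clique",
    "maximum_clique_with_status",
    "enumerate_maximal_cliques",
    "brute_force_maximum_clique",
    "brute_force_minimum_vertex_cover",
    "is_vertex_cover",
]

log = logging.getLogger(__name__)

DEFAULT_ENUMERATION_GUARD = 2000


def is_clique(g: SimpleGraph, members: Iterable[str]) -> bool:
    """True iff every unordered pair of ``members`` is an edge of ``g``.

    Sets of size <= 1 are vacuously cliques.  Unknown vertex ids raise
    ``KeyError`` naming the offender.
    """
    idx = [g.index_of(v) for v in members]
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate vertex in candidate clique")
    mask = 0
    for i in idx:
        mask |= 1 << i
    adj = g.adjacency_bitsets()
    return all(adj[i] & (mask & ~(1 << i)) == (mask & ~(1 << i)) for i in idx)


def is_vertex_cover(g: SimpleGraph, cover: Iterable[str]) -> bool:
    """True iff ``cover`` touches every edge of ``g``."""
    mask = 0
    for v in cover:
        mask |= 1 << g.index_of(v)
    return all(mask >> i & 1 or adj & ~mask == 0 for i, adj in enumerate(g.adjacency_bitsets()))


# ---------------------------------------------------------------------------
# Exact vertex cover: bounded search tree on bitsets
# ---------------------------------------------------------------------------


class _Budget:
    """Shared node counter; when exhausted the search keeps its incumbent."""

    __slots__ = ("remaining", "exhausted")

    def __init__(self, nodes: int | None):
        self.remaining = nodes if nodes is not None else -1  # -1 = unlimited
        self.exhausted = False

    def tick(self) -> bool:
        if self.remaining < 0:
            return True
        if self.remaining == 0:
            self.exhausted = True
            return False
        self.remaining -= 1
        return True


def _greedy_cover(adj: list[int], alive: int) -> int:
    """Greedy vertex cover (repeatedly take the max-degree vertex); upper bound."""
    cover = 0
    while True:
        best_v, best_d = -1, 0
        for i in _bits(alive):
            d = (adj[i] & alive).bit_count()
            if d > best_d:
                best_v, best_d = i, d
        if best_d == 0:
            return cover
        cover |= 1 << best_v
        alive &= ~(1 << best_v)


def _matching_lower_bound(adj: list[int], alive: int) -> int:
    """Size of a greedy maximal matching; any cover needs one vertex per edge."""
    m = 0
    avail = alive
    for v in _bits(alive):
        if avail >> v & 1:
            nb = adj[v] & avail & ~(1 << v)
            if nb:
                u = (nb & -nb).bit_length() - 1
                avail &= ~((1 << v) | (1 << u))
                m += 1
    return m


def _vc_search(
    adj: list[int],
    alive: int,
    cover: int,
    size: int,
    best: list,
    budget: _Budget,
) -> None:
    if not budget.tick():
        return
    # --- kernelization against the current budget -------------------------
    while True:
        changed = False
        k = best[0] - 1 - size  # must beat the incumbent
        if k < 0:
            return
        deg1_seen = False
        for v in _bits(alive):
            nb = adj[v] & alive
            d = nb.bit_count()
            if d == 0:
                alive &= ~(1 << v)
            elif d > k:
                # high-degree rule: v is in every cover small enough to matter
                cover |= 1 << v
                size += 1
                alive &= ~(1 << v)
                changed = True
                break
            elif d == 1 and not deg1_seen:
                # degree-1 rule: take the single neighbour
                u = (nb & -nb).bit_length() - 1
                cover |= 1 << u
                size += 1
                alive &= ~((1 << v) | (1 << u))
                changed = True
                deg1_seen = True
                break
        if not changed:
            break
    if size >= best[0]:
        return
    # any edges left?
    pick, pick_d = -1, 0
    for v in _bits(alive):
        d = (adj[v] & alive).bit_count()
        if d > pick_d:
            pick, pick_d = v, d
    if pick_d == 0:
        best[0] = size
        best[1] = cover
        return
    if size + _matching_lower_bound(adj, alive) >= best[0]:
        return
    # branch 1: pick in the cover
    _vc_search(adj, alive & ~(1 << pick), cover | (1 << pick), size + 1, best, budget)
    # branch 2: all neighbours of pick in the cover
    nb = adj[pick] & alive
    _vc_search(
        adj,
        alive & ~nb & ~(1 << pick),
        cover | nb,
        size + nb.bit_count(),
        best,
        budget,
    )


def _solve_vc_mask(adj: list[int], alive: int, budget: _Budget) -> int:
    """Exact (budget permitting) minimum vertex cover of the graph induced on
    ``alive``, returned as a bitmask."""
    greedy = _greedy_cover(adj, alive)
    best = [greedy.bit_count(), greedy]
    _vc_search(adj, alive, 0, 0, best, budget)
    return best[1]


def minimum_vertex_cover(g: SimpleGraph, node_budget: int | None = None) -> frozenset[str]:
    """A smallest vertex set touching every edge of ``g``.

    Solved per connected component (the cover of a disjoint union is the
    union of the component covers).  With a ``node_budget`` the search may
    return a valid but unproven cover; a warning is logged in that case.
    """
    cover, proven = _minimum_vertex_cover_status(g, node_budget)
    if not proven:
        log.warning("vertex-cover search budget exhausted; result not proven optimal")
    return cover


def _minimum_vertex_cover_status(
    g: SimpleGraph, node_budget: int | None = None
) -> tuple[frozenset[str], bool]:
    adj = g.adjacency_bitsets()
    budget = _Budget(node_budget)
    out: set[str] = set()
    for comp in g.connected_components():
        alive = 0
        for v in comp:
            alive |= 1 << g.index_of(v)
        mask = _solve_vc_mask(adj, alive, budget)
        out.update(g.vertex_ids[i] for i in _bits(mask))
    return frozenset(out), not budget.exhausted


# ---------------------------------------------------------------------------
# Maximum clique through the complementary dual
# ---------------------------------------------------------------------------


def maximum_clique_with_status(
    g: SimpleGraph, node_budget: int | None = None
) -> tuple[frozenset[str], bool]:
    """Maximum clique and whether optimality was proven within the budget.

    Per component, a minimum vertex cover of the component's complement is
    computed and complemented.  Ties between equal-sized component optima are
    broken toward the lexicographically smallest member tuple.
    """
    if g.n_vertices == 0:
        return frozenset(), True
    budget = _Budget(node_budget)
    best: tuple[int, tuple[str, ...]] | None = None
    for comp in g.connected_components():
        comp_n = len(comp)
        if best is not None and comp_n < best[0]:
            continue  # component too small to beat or tie the incumbent
        sub = g.subgraph(comp)
        cadj = sub.complement().adjacency_bitsets()
        alive = (1 << comp_n) - 1
        cover = _solve_vc_mask(cadj, alive, budget)
        clique = sorted(
            sub.vertex_ids[i] for i in _bits(alive & ~cover)
        )
        key = (len(clique), tuple(clique))
        if best is None or key[0] > best[0] or (key[0] == best[0] and key[1] < best[1]):
            best = key
    assert best is not None
    members = frozenset(best[1])
    assert is_clique(g, members), "solver returned a non-clique"
    return members, not budget.exhausted


def maximum_clique(g: SimpleGraph, node_budget: int | None = None) -> frozenset[str]:
    """A clique of maximum cardinality (deterministic for fixed vertex order)."""
    members, proven = maximum_clique_with_status(g, node_budget)
    if not proven:
        log.warning("clique search budget exhausted; best clique found so far returned")
    return members


# ---------------------------------------------------------------------------
# Maximal clique enumeration (Bron-Kerbosch with pivoting)
# ---------------------------------------------------------------------------


def enumerate_maximal_cliques(
    g: SimpleGraph,
    min_size: int = 1,
    max_vertices: int = DEFAULT_ENUMERATION_GUARD,
    force: bool = False,
) -> list[frozenset[str]]:
    """All maximal cliques of size >= ``min_size``, deterministically ordered.

    Refuses graphs above ``max_vertices`` unless ``force`` is set, since the
    output can be exponential.
    """
    if g.n_vertices > max_vertices and not force:
        raise ValueError(
            f"graph has {g.n_vertices} vertices, above the enumeration guard "
            f"({max_vertices}); pass force=True to override"
        )
    adj = g.adjacency_bitsets()
    out: list[frozenset[str]] = []

    def bk(r: int, p: int, x: int) -> None:
        if p == 0 and x == 0:
            if r.bit_count() >= min_size:
                out.append(frozenset(g.vertex_ids[i] for i in _bits(r)))
            return
        # pivot: vertex of P|X covering the most of P (ties: lowest index)
        pivot, pivot_cov = -1, -1
        for u in _bits(p | x):
            cov = (adj[u] & p).bit_count()
            if cov > pivot_cov:
                pivot, pivot_cov = u, cov
        for v in _bits(p & ~adj[pivot]):
            bit = 1 << v
            bk(r | bit, p & adj[v], x & adj[v])
            p &= ~bit
            x |= bit

    bk(0, (1 << g.n_vertices) - 1, 0)
    out.sort(key=lambda s: (-len(s), tuple(sorted(s))))
    return out


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the solvers above; for testing)
# ---------------------------------------------------------------------------


def brute_force_maximum_clique(g: SimpleGraph, max_vertices: int = 32) -> frozenset[str]:
    """Exhaustive include/exclude search over all vertex subsets.

    Intentionally naive (no kernelization, no duality, no pivoting) so that it
    is an independent check of :func:`maximum_clique`.  Guarded to small
    graphs.
    """
    n = g.n_vertices
    if n > max_vertices:
        raise ValueError(f"brute force limited to {max_vertices} vertices, got {n}")
    adj = g.adjacency_bitsets()
    best = [0, 0]  # size, mask

    def rec(chosen: int, size: int, cand: int) -> None:
        if cand == 0:
            if size > best[0]:
                best[0], best[1] = size, chosen
            return
        v = (cand & -cand).bit_length() - 1
        bit = 1 << v
        rec(chosen | bit, size + 1, cand & ~bit & adj[v])
        rec(chosen, size, cand & ~bit)

    rec(0, 0, (1 << n) - 1)
    return frozenset(g.vertex_ids[i] for i in _bits(best[1]))


def brute_force_minimum_vertex_cover(g: SimpleGraph, max_vertices: int = 20) -> frozenset[str]:
    """Smallest cover by exhaustive subset enumeration in increasing size."""
    n = g.n_vertices
    if n > max_vertices:
        raise ValueError(f"brute force limited to {max_vertices} vertices, got {n}")
    edge_pairs = list(g.edges())
    for k in range(n + 1):
        for combo in combinations(g.vertex_ids, k):
            s = set(combo)
            if all(u in s or v in s for u, v in edge_pairs):
                return frozenset(s)
    raise AssertionError("unreachable: V itself is always a cover")


@dataclass(frozen=True)
class CliqueResult:
    """CLI-facing result record."""

    size: int
    members: tuple[str, ...]
    proven_optimal: bool
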