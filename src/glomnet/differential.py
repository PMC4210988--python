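"""Differential comparison of two graphs from case/control cohorts.

Vertex, edge and topological differences between cohort graphs are often
the most informative product of the toolchain.  The comparison here is
purely structural and descriptive: shared and cohort-specific vertices and
edges, per-vertex degree differences, densities, and — for coarsened inputs
— edges whose polarity flips between cohorts.  Edge arithmetic is restricted
to the shared vertex set, so that differences in variable availability are
reported separately from differences in structure.

Accepts either :class:`~glomnet.graphs.SimpleGraph` or
:class:`~glomnet.coarsen.CoarsenedGraph` inputs (vertex identity is string
equality of ids/labels).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .coarsen import CoarsenedGraph
from .graphs import SimpleGraph

__all__ = ["DifferentialSummary", "differential_summary"]

log = logging.getLogger(__name__)

Edge = tuple[str, str]


def _normalize(g) -> tuple[list[str], set[Edge], dict[Edge, int] | None]:
    """(vertex ids, edge set with sorted pairs, polarity map or None)."""
    if isinstance(g, SimpleGraph):
        edges = {tuple(sorted(e)) for e in g.edges()}
        return list(g.vertex_ids), edges, None
    if isinstance(g, CoarsenedGraph):
        pol = {k: p for k, (_, p) in g.edges.items()}
        return list(g.node_ids), set(g.edges.keys()), pol
    raise TypeError(f"cannot compare object of type {type(g).__name__}")


@dataclass(frozen=True)
class DifferentialSummary:
    """Structural differences between graphs A and B.

    Edge fields are computed over the shared vertex set;
    ``degree_delta[v] = deg_A(v) - deg_B(v)`` (degrees within the shared
    vertex set); ``polarity_flips`` is nonempty only for coarsened inputs.
    """

    shared_vertices: frozenset[str]
    a_only_vertices: frozenset[str]
    b_only_vertices: frozenset[str]
    shared_edges: frozenset[Edge]
    a_only_edges: frozenset[Edge]
    b_only_edges: frozenset[Edge]
    degree_delta: dict[str, int] = field(hash=False)
    polarity_flips: frozenset[Edge] = frozenset()
    density_a: float = 0.0
    density_b: float = 0.0

    def is_identical(self) -> bool:
        return (
            not self.a_only_vertices
            and not self.b_only_vertices
            and not self.a_only_edges
            and not self.b_only_edges
            and not self.polarity_flips
            and all(d == 0 for d in self.degree_delta.values())
        )

    def to_dict(self) -> dict:
        return {
            "shared_vertices": sorted(self.shared_vertices),
            "a_only_vertices": sorted(self.a_only_vertices),
            "b_only_vertices": sorted(self.b_only_vertices),
            "shared_edges": sorted(map(list, self.shared_edges)),
            "a_only_edges": sorted(map(list, self.a_only_edges)),
            "b_only_edges": sorted(map(list, self.b_only_edges)),
            "degree_delta": {v: self.degree_delta[v] for v in sorted(self.degree_delta)},
            "polarity_flips": sorted(map(list, self.polarity_flips)),
            "density_a": self.density_a,
            "density_b": self.density_b,
        }

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _density(n_vertices: int, n_edges: int) -> float:
    possible = n_vertices * (n_vertices - 1) // 2
    return n_edges / possible if possible else 0.0


def differential_summary(a, b) -> DifferentialSummary:
    """Compare two graphs drawn from a common vertex naming scheme.

    Identity gives an empty summary; swapping the inputs swaps the a/b
    fields and negates ``degree_delta``.  Disjoint vertex sets yield empty
    shared sections with a warning.
    """
    va, ea, pa = _normalize(a)
    vb, eb, pb = _normalize(b)
    sa, sb = set(va), set(vb)
    shared = sa & sb
    if not shared:
        log.warning("differential_summary: the two graphs share no vertices")
    ea_shared = {e for e in ea if e[0] in shared and e[1] in shared}
    eb_shared = {e for e in eb if e[0] in shared and e[1] in shared}
    shared_edges = ea_shared & eb_shared
    degree: dict[str, int] = {v: 0 for v in shared}
    for u, v in ea_shared:
        degree[u] += 1
        degree[v] += 1
    for u, v in eb_shared:
        degree[u] -= 1
        degree[v] -= 1
    flips = frozenset(
        e for e in shared_edges
        if pa is not None and pb is not None and pa[e] != pb[e]
    )
    return DifferentialSummary(
        shared_vertices=frozenset(shared),
        a_only_vertices=frozenset(sa - sb),
        b_only_vertices=frozenset(sb - sa),
        shared_edges=frozenset(shared_edges),
        a_only_edges=frozenset(ea_shared - eb_shared),
        b_only_edges=frozenset(eb_shared - ea_shared),
        degree_delta=degree,
        polarity_flips=flips,
        density_a=_density(len(va), len(ea)),
        density_b=_density(len(vb), len(eb)),
    )
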