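"""Outcome ranking of paracliques and coarsened paraclique-level graphs.

Two post-extraction steps:

* **Ranking** — for each paraclique, the median of |r(outcome, v)| over its
  members; paracliques whose median meets the cutoff (default 0.38) are
  selected for further study.  Absolute values are the default, consistent
  with the absolute-correlation thresholding convention; a signed mode
  exists.

* **Coarsening** — paracliques become nodes of a coarsened graph whose edge
  between P and Q carries the median |r(u, v)| over all cross pairs
  u in P, v in Q (u != v) as weight, and the majority sign of the signed
  cross correlations as polarity (+1 / -1).  Ties in the sign count fall
  back to the sign of the median signed value, then to +1.  Cross pairs
  include glommed members, not cores only.

* **Density matching** — two coarsened graphs (e.g. from case and control
  cohorts) are pruned to a common relative density by top-k edge-weight
  retention toward the sparser graph's density, so that their structures are
  comparable edge-for-edge.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .correlate import CorrelationGraph
from .paraclique import Paraclique

__all__ = [
    "RankedParaclique",
    "CoarsenedGraph",
    "rank_paracliques_by_outcome",
    "coarsen",
    "match_relative_densities",
    "DEFAULT_OUTCOME_CUTOFF",
]

log = logging.getLogger(__name__)

DEFAULT_OUTCOME_CUTOFF = 0.38


@dataclass(frozen=True)
class RankedParaclique:
    """A paraclique with its median outcome-correlation score."""

    paraclique: Paraclique
    median_abs_r_to_outcome: float
    selected: bool

    @property
    def index(self) -> int:
        return self.paraclique.extraction_index


def rank_paracliques_by_outcome(
    cg: CorrelationGraph,
    paracliques: Sequence[Paraclique],
    outcome: str,
    cutoff: float = DEFAULT_OUTCOME_CUTOFF,
    absolute: bool = True,
) -> list[RankedParaclique]:
    """Median |r(outcome, member)| per paraclique, sorted descending.

    Missing outcome correlations are excluded from the median; an even count
    yields the mean of the two central values (numpy convention).  The
    outcome must not itself belong to any paraclique (circularity).
    """
    oi = cg.index_of(outcome)
    out: list[RankedParaclique] = []
    for pc in paracliques:
        if outcome in pc.members:
            raise ValueError(
                f"outcome {outcome!r} is a member of paraclique "
                f"{pc.extraction_index}; ranking would be circular"
            )
        rs = []
        for v in sorted(pc.members):
            r = cg.weights[oi, cg.index_of(v)]
            if not np.isnan(r):
                rs.append(abs(float(r)) if absolute else float(r))
        med = float(np.median(rs)) if rs else float("nan")
        selected = bool(rs) and med >= cutoff
        out.append(RankedParaclique(pc, med, selected))
    out.sort(key=lambda rp: (-rp.median_abs_r_to_outcome, rp.index))
    return out


@dataclass(frozen=True)
class CoarsenedGraph:
    """Paracliques as nodes; signed weighted inter-paraclique edges.

    ``edges`` maps an (i, j) node-id pair with i < j (lexicographic) to a
    (weight, polarity) tuple, weight in [0, 1] and polarity +-1.  Node pairs
    with no usable cross correlations are absent (marked missing upstream).
    """

    node_ids: tuple[str, ...]
    members: dict[str, frozenset[str]] = field(hash=False)
    edges: dict[tuple[str, str], tuple[float, int]] = field(hash=False)

    def __post_init__(self) -> None:
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate coarsened node ids")
        for (i, j), (w, pol) in self.edges.items():
            if i not in self.node_ids or j not in self.node_ids:
                raise ValueError(f"edge ({i}, {j}) references an unknown node")
            if i >= j:
                raise ValueError(f"edge key ({i}, {j}) must be ordered i < j")
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"edge weight {w} outside [0, 1]")
            if pol not in (-1, 1):
                raise ValueError(f"polarity must be +-1, got {pol}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def possible_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    def density(self) -> float:
        return self.n_edges / self.possible_edges if self.possible_edges else 0.0

    def write_edge_list(self, path) -> None:
        """TSV ``node_i node_j weight polarity`` in deterministic order."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("node_i\tnode_j\tweight\tpolarity\n")
            for (i, j) in sorted(self.edges):
                w, pol = self.edges[(i, j)]
                fh.write(f"{i}\t{j}\t{w!r}\t{pol:+d}\n")

    def write_node_map(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {n: sorted(self.members.get(n, ())) for n in self.node_ids},
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")


def read_coarsened_edge_list(path) -> CoarsenedGraph:
    """Read the TSV written by :meth:`CoarsenedGraph.write_edge_list`.

    Member maps are not stored in the edge list; the returned graph carries
    empty member sets and is suitable for structural comparison only.
    """
    edges: dict[tuple[str, str], tuple[float, int]] = {}
    nodes: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("node_i"):
            raise ValueError(f"{path}: missing coarsened edge-list header")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            i, j, w, pol = line.split("\t")
            edges[_edge_key(i, j)] = (float(w), int(pol))
            for n in (i, j):
                if n not in seen:
                    seen.add(n)
                    nodes.append(n)
    return CoarsenedGraph(tuple(nodes), {n: frozenset() for n in nodes}, edges)


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def coarsen(
    cg: CorrelationGraph,
    paracliques: Sequence[Paraclique],
    labels: Sequence[str] | None = None,
) -> CoarsenedGraph:
    """Build the complete coarsened graph over ``paracliques``.

    Edge weight between P and Q is the median of |r(u, v)| over cross pairs
    (u in P, v in Q, u != v, r non-missing); polarity is the strict-majority
    sign of the signed values, falling back to the sign of the median signed
    value, then to +1.  Thresholding is a separate, later step
    (:func:`match_relative_densities` or a fixed cut).  Node pairs with zero
    usable cross correlations are left out and logged.
    """
    if len(paracliques) < 2:
        raise ValueError("coarsening needs at least 2 paracliques")
    if labels is None:
        labels = [f"P{pc.extraction_index}" for pc in paracliques]
    if len(labels) != len(paracliques):
        raise ValueError("labels must match paracliques one-to-one")
    members = {lab: pc.members for lab, pc in zip(labels, paracliques)}
    for lab, mem in members.items():
        if not mem:
            raise ValueError(f"paraclique {lab} has no members")
    idx = {lab: [cg.index_of(v) for v in sorted(mem)] for lab, mem in members.items()}
    edges: dict[tuple[str, str], tuple[float, int]] = {}
    for a_pos in range(len(labels)):
        for b_pos in range(a_pos + 1, len(labels)):
            la, lb = labels[a_pos], labels[b_pos]
            ia, ib = idx[la], idx[lb]
            block = cg.weights[np.ix_(ia, ib)]
            # exclude u == v (possible under overlap) and missing entries
            shared = set(ia) & set(ib)
            if shared:
                for r_pos, gi in enumerate(ia):
                    for c_pos, gj in enumerate(ib):
                        if gi == gj:
                            block[r_pos, c_pos] = np.nan
            vals = block[~np.isnan(block)]
            if vals.size == 0:
                log.info("coarsen: no usable cross correlations between %s and %s; "
                         "edge marked missing", la, lb)
                continue
            weight = float(np.median(np.abs(vals)))
            pos, neg = int((vals > 0).sum()), int((vals < 0).sum())
            if pos > neg:
                pol = 1
            elif neg > pos:
                pol = -1
            else:
                med_signed = float(np.median(vals))
                pol = -1 if med_signed < 0 else 1
            edges[_edge_key(la, lb)] = (weight, pol)
    return CoarsenedGraph(tuple(labels), members, edges)


def _top_k_edges(
    g: CoarsenedGraph, k: int
) -> dict[tuple[str, str], tuple[float, int]]:
    ranked = sorted(g.edges.items(), key=lambda kv: (-kv[1][0], kv[0]))
    return dict(ranked[:k])


def apply_coarse_threshold(g: CoarsenedGraph, t: float) -> CoarsenedGraph:
    """Drop coarsened edges with weight below ``t`` (base thresholding)."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    kept = {k: v for k, v in g.edges.items() if v[0] >= t}
    return replace(g, edges=kept)


def match_relative_densities(
    a: CoarsenedGraph,
    b: CoarsenedGraph,
    base_threshold_a: float = 0.0,
    base_threshold_b: float = 0.0,
) -> tuple[CoarsenedGraph, CoarsenedGraph]:
    """Threshold two coarsened graphs to a common relative density.

    After optional base thresholds, the target density d* is the smaller of
    the two graphs' densities; each graph keeps its top
    k = round(d* * n(n-1)/2) edges by weight (ties at the cut broken by
    weight descending, then lexicographic node pair).  The returned graphs'
    densities agree within one edge's worth of the smaller graph.
    """
    if a.possible_edges < 1 or b.possible_edges < 1:
        raise ValueError("each coarsened graph needs at least one possible edge")
    a = apply_coarse_threshold(a, base_threshold_a)
    b = apply_coarse_threshold(b, base_threshold_b)
    d_star = min(a.density(), b.density())
    out = []
    for g in (a, b):
        k = math.floor(d_star * g.possible_edges + 0.5)
        if k == 0:
            log.warning("match_relative_densities: target density %.4f keeps no "
                        "edges in a graph with %d node(s)", d_star, g.n_nodes)
        out.append(replace(g, edges=_top_k_edges(g, k)))
    return out[0], out[1]
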