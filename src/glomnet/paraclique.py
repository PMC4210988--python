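"""Paraclique extraction: a maximum-clique core plus glommed near-members.

A paraclique is built from a maximum clique C by adding ("glomming") every
non-member adjacent to at least |C| - g members of C, where g is the glom
factor.  Glomming is evaluated in a single pass against the original core,
not against the growing paraclique (a fixpoint variant that re-evaluates
against the grown set is available behind a flag and is not the default).

Iterated extraction removes each paraclique's members (or, with overlap
enabled, only its core) before recomputing the next maximum clique, so that
with overlap two paracliques may share glommed vertices but never cores.

Anchoring extracts the correlation neighbourhood of a designated variable of
established significance at a caller-chosen floor, a lighter-weight
alternative when a variable fails to reach clique-level correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .clique import maximum_clique
from .correlate import CorrelationGraph
from .graphs import SimpleGraph

import numpy as np

__all__ = [
    "Paraclique",
    "extract_paraclique",
    "extract_all_paracliques",
    "anchored_subgraph",
    "AnchoredSubgraph",
    "DEFAULT_GLOM",
    "DEFAULT_MIN_CORE",
]

log = logging.getLogger(__name__)

# Defaults: small glom factor and a nontrivial core floor keep extracted
# subgraphs at the "few tens of vertices" scale the method targets.
DEFAULT_GLOM = 1
DEFAULT_MIN_CORE = 5


@dataclass(frozen=True)
class Paraclique:
    """A maximum-clique core plus glommed vertices (disjoint from the core)."""

    core: frozenset[str]
    glommed: frozenset[str]
    glom_factor: int
    extraction_index: int = 0

    def __post_init__(self) -> None:
        if self.core & self.glommed:
            raise ValueError("core and glommed vertex sets must be disjoint")
        if self.glom_factor < 0:
            raise ValueError("glom factor must be nonnegative")

    @property
    def members(self) -> frozenset[str]:
        return self.core | self.glommed

    @property
    def size(self) -> int:
        return len(self.core) + len(self.glommed)

    def check_membership(self, g: SimpleGraph) -> bool:
        """Contract check: core is a clique of ``g`` and every glommed vertex
        misses at most ``glom_factor`` core adjacencies."""
        from .clique import is_clique

        if not is_clique(g, self.core):
            return False
        need = len(self.core) - self.glom_factor
        for v in self.glommed:
            hits = sum(1 for u in self.core if g.has_edge(u, v))
            if hits < need:
                return False
        return True

    def to_dict(self) -> dict:
        return {
            "index": self.extraction_index,
            "core": sorted(self.core),
            "glommed": sorted(self.glommed),
            "size": self.size,
        }


def _glom_pass(g: SimpleGraph, core: frozenset[str], glom: int) -> frozenset[str]:
    """One pass: non-members adjacent to >= |core| - glom core vertices."""
    need = len(core) - glom
    core_mask = 0
    for v in core:
        core_mask |= 1 << g.index_of(v)
    adj = g.adjacency_bitsets()
    out = set()
    for i, vid in enumerate(g.vertex_ids):
        if vid in core:
            continue
        if (adj[i] & core_mask).bit_count() >= need:
            out.add(vid)
    return frozenset(out)


def extract_paraclique(
    g: SimpleGraph,
    glom: int = DEFAULT_GLOM,
    min_core: int = DEFAULT_MIN_CORE,
    fixpoint: bool = False,
    extraction_index: int = 0,
) -> Paraclique | None:
    """Extract one paraclique, or None when the maximum clique is below
    ``min_core``.

    With ``fixpoint`` (non-default), glomming is repeated with the admission
    test taken against the grown member set until no vertex qualifies.
    """
    if glom < 0:
        raise ValueError("glom must be nonnegative")
    if min_core < 2:
        raise ValueError("min_core must be at least 2")
    if g.n_vertices == 0:
        return None
    core = maximum_clique(g)
    if len(core) < min_core:
        return None
    glommed = _glom_pass(g, core, glom)
    if fixpoint:
        members = core | glommed
        while True:
            need = len(members) - glom
            adj = g.adjacency_bitsets()
            mask = 0
            for v in members:
                mask |= 1 << g.index_of(v)
            added = set()
            for i, vid in enumerate(g.vertex_ids):
                if vid in members:
                    continue
                if (adj[i] & mask).bit_count() >= need:
                    added.add(vid)
            if not added:
                break
            members = members | added
        glommed = frozenset(members - core)
    return Paraclique(core=core, glommed=glommed, glom_factor=glom,
                      extraction_index=extraction_index)


def extract_all_paracliques(
    g: SimpleGraph,
    glom: int = DEFAULT_GLOM,
    min_core: int = DEFAULT_MIN_CORE,
    overlap: bool = False,
    fixpoint: bool = False,
) -> list[Paraclique]:
    """Iteratively extract paracliques until the maximum clique falls below
    ``min_core``.

    After each extraction the paraclique's members (overlap off) or only its
    core (overlap on) are removed before the next maximum clique is
    recomputed.  ``extraction_index`` records the order.
    """
    out: list[Paraclique] = []
    work = g
    idx = 0
    while work.n_vertices:
        pc = extract_paraclique(work, glom=glom, min_core=min_core,
                                fixpoint=fixpoint, extraction_index=idx)
        if pc is None:
            break
        out.append(pc)
        removed = pc.core if overlap else pc.members
        work = work.subgraph([v for v in work.vertex_ids if v not in removed])
        idx += 1
    if len(out) > 1 and not overlap:
        seen: set[str] = set()
        for pc in out:
            assert not (pc.members & seen), "overlap-off paracliques must be disjoint"
            seen |= pc.members
    log.info("extracted %d paraclique(s) (glom=%d, min_core=%d, overlap=%s)",
             len(out), glom, min_core, overlap)
    return out


@dataclass(frozen=True)
class AnchoredSubgraph:
    """An anchor variable plus its correlates at or above a floor."""

    anchor: str
    members: frozenset[str]
    correlations: dict[str, float] = field(hash=False, default_factory=dict)


def anchored_subgraph(
    cg: CorrelationGraph,
    anchor: str,
    r_min: float,
    absolute: bool = True,
) -> AnchoredSubgraph:
    """The anchor plus all variables v with |r(anchor, v)| >= r_min
    (signed r >= r_min when ``absolute`` is off), with the signed
    correlations reported alongside."""
    if not 0.0 <= r_min <= 1.0:
        raise ValueError(f"r_min must lie in [0, 1], got {r_min}")
    ai = cg.index_of(anchor)
    row = cg.weights[ai]
    members = {anchor}
    corr: dict[str, float] = {}
    for j, v in enumerate(cg.variable_ids):
        if j == ai or np.isnan(row[j]):
            continue
        mag = abs(row[j]) if absolute else row[j]
        if mag >= r_min:
            members.add(v)
            corr[v] = float(row[j])
    return AnchoredSubgraph(anchor=anchor, members=frozenset(members), correlations=corr)
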