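"""Graph containers shared across the toolchain.

Two objects travel through the pipeline: the weighted complete correlation
graph over variables (kept as a dense symmetric matrix, see
:mod:`glomnet.correlate`) and the finite simple unweighted graph obtained from
it by thresholding.  :class:`SimpleGraph` is the latter.  Adjacency is stored
as one Python-integer bitset per vertex, which keeps the exact clique and
vertex-cover search in :mod:`glomnet.clique` fast without any compiled code.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["SimpleGraph", "read_edge_list", "write_edge_list"]


class SimpleGraph:
    """A finite, simple, undirected, unweighted graph.

    Vertices are identified by strings; isolated vertices are first-class
    (thresholding keeps every variable as a vertex even when all of its
    correlations fall below t).
    """

    __slots__ = ("vertex_ids", "_index", "_adj")

    def __init__(self, vertex_ids: Sequence[str], edges: Iterable[tuple[str, str]] = ()):
        self.vertex_ids: list[str] = [str(v) for v in vertex_ids]
        self._index: dict[str, int] = {v: i for i, v in enumerate(self.vertex_ids)}
        if len(self._index) != len(self.vertex_ids):
            seen: set[str] = set()
            for v in self.vertex_ids:
                if v in seen:
                    raise ValueError(f"duplicate vertex id: {v!r}")
                seen.add(v)
        self._adj: list[int] = [0] * len(self.vertex_ids)
        for u, v in edges:
            self.add_edge(u, v)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_adjacency(cls, vertex_ids: Sequence[str], adjacency: np.ndarray) -> "SimpleGraph":
        """Build from a boolean adjacency matrix (diagonal ignored)."""
        a = np.asarray(adjacency, dtype=bool)
        n = len(vertex_ids)
        if a.shape != (n, n):
            raise ValueError(f"adjacency shape {a.shape} does not match {n} vertices")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency matrix must be symmetric")
        g = cls(vertex_ids)
        iu, ju = np.nonzero(np.triu(a, k=1))
        for i, j in zip(iu.tolist(), ju.tolist()):
            g._adj[i] |= 1 << j
            g._adj[j] |= 1 << i
        return g

    def add_edge(self, u: str, v: str) -> None:
        i, j = self.index_of(u), self.index_of(v)
        if i == j:
            raise ValueError(f"self-loop not allowed: {u!r}")
        self._adj[i] |= 1 << j
        self._adj[j] |= 1 << i

    # -- basic queries -----------------------------------------------------

    def index_of(self, v: str) -> int:
        try:
            return self._index[v]
        except KeyError:
            raise KeyError(f"unknown vertex id: {v!r}") from None

    def __contains__(self, v: str) -> bool:
        return v in self._index

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)

    @property
    def n_edges(self) -> int:
        return sum(a.bit_count() for a in self._adj) // 2

    def has_edge(self, u: str, v: str) -> bool:
        return bool(self._adj[self.index_of(u)] >> self.index_of(v) & 1)

    def degree(self, v: str) -> int:
        return self._adj[self.index_of(v)].bit_count()

    def neighbors(self, v: str) -> list[str]:
        return [self.vertex_ids[j] for j in _bits(self._adj[self.index_of(v)])]

    def edges(self) -> Iterator[tuple[str, str]]:
        """Yield each edge once, as (u, v) with index(u) < index(v)."""
        for i, mask in enumerate(self._adj):
            for j in _bits(mask >> (i + 1)):
                yield self.vertex_ids[i], self.vertex_ids[i + 1 + j]

    def adjacency_bitsets(self) -> list[int]:
        """The internal per-vertex bitsets (copy); used by the clique solver."""
        return list(self._adj)

    def adjacency_matrix(self) -> np.ndarray:
        a = np.zeros((self.n_vertices, self.n_vertices), dtype=bool)
        for i, mask in enumerate(self._adj):
            for j in _bits(mask):
                a[i, j] = True
        return a

    # -- derived graphs ----------------------------------------------------

    def complement(self) -> "SimpleGraph":
        n = self.n_vertices
        full = (1 << n) - 1
        g = SimpleGraph(self.vertex_ids)
        for i, mask in enumerate(self._adj):
            g._adj[i] = full & ~mask & ~(1 << i)
        return g

    def subgraph(self, keep: Iterable[str]) -> "SimpleGraph":
        keep_ids = [v for v in self.vertex_ids if v in set(keep)]
        pos = {self._index[v]: k for k, v in enumerate(keep_ids)}
        g = SimpleGraph(keep_ids)
        for old_i, new_i in pos.items():
            m = 0
            for old_j in _bits(self._adj[old_i]):
                if old_j in pos:
                    m |= 1 << pos[old_j]
            g._adj[new_i] = m
        return g

    def connected_components(self) -> list[list[str]]:
        """Components as vertex-id lists, each in index order; deterministic."""
        n = self.n_vertices
        unseen = (1 << n) - 1
        out: list[list[str]] = []
        while unseen:
            start = (unseen & -unseen).bit_length() - 1
            comp = 1 << start
            frontier = comp
            while frontier:
                nxt = 0
                for i in _bits(frontier):
                    nxt |= self._adj[i]
                frontier = nxt & ~comp
                comp |= frontier
            out.append([self.vertex_ids[i] for i in _bits(comp)])
            unseen &= ~comp
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SimpleGraph(n_vertices={self.n_vertices}, n_edges={self.n_edges})"


def _bits(mask: int) -> Iterator[int]:
    """Indices of set bits, ascending."""
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def write_edge_list(g: SimpleGraph, edge_path, vertex_path=None) -> None:
    """Write a two-column TSV edge list, plus an optional vertex list file.

    The vertex file preserves isolated vertices, which an edge list alone
    cannot represent.
    """
    with open(edge_path, "w", encoding="utf-8") as fh:
        for u, v in g.edges():
            fh.write(f"{u}\t{v}\n")
    if vertex_path is not None:
        with open(vertex_path, "w", encoding="utf-8") as fh:
            for v in g.vertex_ids:
                fh.write(f"{v}\n")


def read_edge_list(edge_path, vertex_path=None) -> SimpleGraph:
    edges: list[tuple[str, str]] = []
    verts: list[str] = []
    seen: set[str] = set()
    with open(edge_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed edge-list line: {line!r}")
            u, v = parts[0], parts[1]
            edges.append((u, v))
            for w in (u, v):
                if w not in seen:
                    seen.add(w)
                    verts.append(w)
    if vertex_path is not None:
        verts = []
        with open(vertex_path, encoding="utf-8") as fh:
            verts = [line.strip() for line in fh if line.strip()]
    return SimpleGraph(verts, edges)
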