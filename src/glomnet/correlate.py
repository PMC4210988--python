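"""Correlation graphs and threshold selection.

The pre-processing abstraction: a units x variables matrix is reduced to a
symmetric correlation matrix M, viewed as the weighted adjacency matrix of
the complete correlation graph over variables.  Hard thresholding at t then
discards every edge with |M(i,j)| < t (absolute values by default, since
positive and negative relationships carry comparable information) and yields
the unweighted :class:`~glomnet.graphs.SimpleGraph` on which the clique
machinery operates.

Threshold selection is automated from a grid profile of per-threshold graph
statistics.  Two named heuristics are offered: an inflection in the largest
adjacency eigenvalue ("spectral_drop") and an inflection in maximum clique
size ("clique_drop").  The selection rule is described with
:func:`select_threshold`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc

from .datamatrix import DataMatrix
from .graphs import SimpleGraph

__all__ = [
    "CorrelationGraph",
    "correlation_matrix",
    "apply_threshold",
    "threshold_profile",
    "select_threshold",
    "default_grid",
]

log = logging.getLogger(__name__)

SUPPORTED_METHODS = ("pearson", "spearman")
REJECTED_METHODS = ("mutual_information", "euclidean")
DEFAULT_MIN_OVERLAP = 10

# default grid for threshold profiling: 0.30 .. 0.95 step 0.01
DEFAULT_GRID_START = 0.30
DEFAULT_GRID_STOP = 0.95
DEFAULT_GRID_STEP = 0.01

# auto-compute the max-clique profile column only for graphs this small
CLIQUE_PROFILE_VERTEX_LIMIT = 200


def default_grid(
    start: float = DEFAULT_GRID_START,
    stop: float = DEFAULT_GRID_STOP,
    step: float = DEFAULT_GRID_STEP,
) -> list[float]:
    n = int(round((stop - start) / step))
    return [round(start + k * step, 10) for k in range(n + 1)]


@dataclass
class CorrelationGraph:
    """Symmetric correlation matrix with unit diagonal over named variables.

    ``weights[i, j]`` is the correlation of variable i with variable j (NaN
    marks a missing entry: insufficient pairwise-complete overlap or a
    degenerate pairwise subset).  ``n_obs`` counts pairwise-complete
    observations.
    """

    variable_ids: list[str]
    weights: np.ndarray
    method: str
    n_obs: np.ndarray

    def __post_init__(self) -> None:
        self.variable_ids = [str(v) for v in self.variable_ids]
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.n_obs = np.asarray(self.n_obs, dtype=np.int64)
        p = len(self.variable_ids)
        if self.weights.shape != (p, p) or self.n_obs.shape != (p, p):
            raise ValueError("weights / n_obs must be square over variable_ids")
        if len(set(self.variable_ids)) != p:
            raise ValueError("duplicate variable ids")
        with np.errstate(invalid="ignore"):
            if not np.allclose(self.weights, self.weights.T, equal_nan=True):
                raise ValueError("weights must be symmetric")
        if not np.allclose(np.diag(self.weights), 1.0):
            raise ValueError("diagonal must be exactly 1")
        off = self.weights[~np.eye(p, dtype=bool)]
        finite = off[np.isfinite(off)]
        if finite.size and (finite.min() < -1 - 1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")

    @property
    def n_variables(self) -> int:
        return len(self.variable_ids)

    def index_of(self, v: str) -> int:
        try:
            return self.variable_ids.index(v)
        except ValueError:
            raise KeyError(f"unknown variable: {v!r}") from None

    def r(self, a: str, b: str) -> float:
        return float(self.weights[self.index_of(a), self.index_of(b)])

    def subset(self, keep: Sequence[str]) -> "CorrelationGraph":
        keep_set = set(keep)
        idx = [j for j, v in enumerate(self.variable_ids) if v in keep_set]
        return CorrelationGraph(
            [self.variable_ids[j] for j in idx],
            self.weights[np.ix_(idx, idx)].copy(),
            self.method,
            self.n_obs[np.ix_(idx, idx)].copy(),
        )

    def drop(self, remove: Sequence[str]) -> "CorrelationGraph":
        rm = set(remove)
        return self.subset([v for v in self.variable_ids if v not in rm])

    # -- I/O ---------------------------------------------------------------

    def write_edge_list(self, path, t: float = 0.0, absolute: bool = True) -> None:
        """TSV edge list ``var_i var_j r n_obs`` for entries at/above t."""
        mag = np.abs(self.weights) if absolute else self.weights
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("var_i\tvar_j\tr\tn_obs\n")
            p = self.n_variables
            for i in range(p):
                for j in range(i + 1, p):
                    w = self.weights[i, j]
                    if np.isnan(w) or mag[i, j] < t:
                        continue
                    fh.write(
                        f"{self.variable_ids[i]}\t{self.variable_ids[j]}\t"
                        f"{w!r}\t{self.n_obs[i, j]}\n"
                    )

    def write_matrix_csv(self, path) -> None:
        pd.DataFrame(
            self.weights, index=self.variable_ids, columns=self.variable_ids
        ).to_csv(path, na_rep="NA")


def correlation_matrix(
    dm: DataMatrix,
    method: str = "pearson",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> CorrelationGraph:
    """Pairwise-complete correlations between all variable pairs.

    Pairs with fewer than ``min_overlap`` complete observations, and pairs
    whose pairwise-complete subset leaves a variable with zero variance, are
    marked missing (NaN) and logged, never raised.
    """
    if method in REJECTED_METHODS:
        raise ValueError(
            f"method {method!r} is not supported by this toolkit; "
            f"use one of {SUPPORTED_METHODS}"
        )
    if method not in SUPPORTED_METHODS:
        raise ValueError(f"unknown correlation method {method!r}; use one of {SUPPORTED_METHODS}")
    if dm.n_variables < 2:
        raise ValueError("need at least 2 variables to correlate")
    if min_overlap < 1:
        raise ValueError("min_overlap must be a positive integer")
    values = dm.values
    valid = ~np.isnan(values)
    vf = valid.astype(np.float64)  # float matmul hits BLAS; counts are exact
    n_obs = np.rint(vf.T @ vf).astype(np.int64)
    if valid.all():
        # complete-data fast path: BLAS-backed product-moment computation
        x = values if method == "pearson" else _rank_columns(values)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(x, rowvar=False)
    else:
        df = dm.to_dataframe()
        r = df.corr(method=method, min_periods=min_overlap).to_numpy()
    r = np.asarray(r, dtype=np.float64)
    low = n_obs < min_overlap
    np.fill_diagonal(low, False)
    if low.any():
        log.info(
            "correlation_matrix: %d pair(s) below min_overlap=%d marked missing",
            int(low.sum()) // 2, min_overlap,
        )
        r[low] = np.nan
    degenerate = np.isnan(r) & ~low
    np.fill_diagonal(degenerate, False)
    if degenerate.any():
        log.info(
            "correlation_matrix: %d pair(s) degenerate (zero variance on the "
            "pairwise-complete subset) marked missing",
            int(degenerate.sum()) // 2,
        )
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return CorrelationGraph(list(dm.variable_ids), r, method, n_obs)


def _rank_columns(values: np.ndarray) -> np.ndarray:
    """Average ranks per column (complete data only)."""
    from scipy.stats import rankdata

    return rankdata(values, axis=0)


def apply_threshold(cg: CorrelationGraph, t: float, absolute: bool = True) -> SimpleGraph:
    """Edge (i, j) present iff |M(i,j)| >= t (signed M(i,j) >= t when
    ``absolute`` is off).  Missing entries never produce edges; every
    variable is kept as a vertex."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    return SimpleGraph.from_adjacency(cg.variable_ids, _adjacency_at(cg, t, absolute))


def _adjacency_at(cg: CorrelationGraph, t: float, absolute: bool = True) -> np.ndarray:
    w = cg.weights
    mag = np.abs(w) if absolute else w
    with np.errstate(invalid="ignore"):
        a = mag >= t
    a &= ~np.isnan(w)
    np.fill_diagonal(a, False)
    return a


def _lambda1(a: np.ndarray) -> float:
    """Largest adjacency eigenvalue of a boolean adjacency matrix."""
    if not a.any():
        return 0.0
    n = a.shape[0]
    if n <= 2000:
        return float(np.linalg.eigvalsh(a.astype(np.float64))[-1])
    from scipy.sparse.linalg import eigsh

    try:
        return float(eigsh(sp.csr_matrix(a, dtype=np.float64), k=1, which="LA",
                           return_eigenvectors=False)[0])
    except Exception:  # pragma: no cover - iterative solver fallback
        return float(np.linalg.eigvalsh(a.astype(np.float64))[-1])


def threshold_profile(
    cg: CorrelationGraph,
    grid: Sequence[float] | None = None,
    absolute: bool = True,
    with_cliques: bool | None = None,
) -> pd.DataFrame:
    """Per-threshold graph statistics along an increasing grid.

    Columns: ``t``, ``n_edges``, ``n_components`` (non-singleton),
    ``largest_component``, ``lambda1`` (largest adjacency eigenvalue) and,
    when enabled, ``max_clique``.  The max-clique column is computed
    automatically only for small graphs (CLIQUE_PROFILE_VERTEX_LIMIT
    vertices or fewer); pass ``with_cliques=True`` to force it.
    """
    if grid is None:
        grid = default_grid()
    grid = [float(t) for t in grid]
    if any(not 0.0 <= t <= 1.0 for t in grid):
        raise ValueError("grid values must lie in [0, 1]")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")
    if with_cliques is None:
        with_cliques = cg.n_variables <= CLIQUE_PROFILE_VERTEX_LIMIT
    from .clique import maximum_clique  # local import to avoid a cycle

    rows = []
    prev_row = None
    for t in grid:
        a = _adjacency_at(cg, t, absolute)
        n_edges = int(a.sum()) // 2
        if prev_row is not None and n_edges == prev_row["n_edges"]:
            # thresholded edge sets are nested along the grid, so an equal
            # edge count means the identical graph: reuse the statistics
            row = dict(prev_row, t=t)
            rows.append(row)
            prev_row = row
            continue
        if n_edges:
            _, labels = _cc(sp.csr_matrix(a), directed=False)
            sizes = np.bincount(labels)
            n_components = int((sizes > 1).sum())
            largest = int(sizes.max())
        else:
            n_components, largest = 0, 1 if cg.n_variables else 0
        l1 = _lambda1(a)
        row = {
            "t": t,
            "n_edges": n_edges,
            "n_components": n_components,
            "largest_component": largest,
            "lambda1": l1,
        }
        if with_cliques:
            g = SimpleGraph.from_adjacency(cg.variable_ids, a)
            row["max_clique"] = len(maximum_clique(g))
        # interlacing sanity: deleting edges cannot raise the top eigenvalue
        if prev_row is not None:
            assert n_edges <= prev_row["n_edges"], "edge count increased along the grid"
            assert l1 <= prev_row["lambda1"] + 1e-8, "lambda1 increased along the grid"
        rows.append(row)
        prev_row = row
    return pd.DataFrame(rows)


# a plateau step may lose at most this fraction of the statistic
PLATEAU_DROP_TOLERANCE = 0.03
# minimal non-trivial structure: lambda1 of a triangle / a clique of 3
PLATEAU_FLOOR = {"spectral_drop": 2.0, "clique_drop": 3.0}


def select_threshold(profile: pd.DataFrame, criterion: str = "spectral_drop") -> float:
    """Pick a threshold at the start of the profile's dominant stability
    plateau.

    The statistic column (``lambda1`` for ``spectral_drop``, ``max_clique``
    for ``clique_drop``) decreases along the grid in three regimes: a noise
    regime whose abundant weak edges collapse quickly, a stable regime where
    only the densely intercorrelated structure survives, and the eventual
    dissolution of that structure itself.  The inflection out of the noise
    regime is located by *plateaus*: maximal runs of consecutive grid points
    whose per-step relative drops stay within a tolerance (3%) while the
    statistic remains non-trivial (lambda1 >= 2, the level of a single
    triangle; clique size >= 3).  The longest plateau is the surviving dense
    structure; its first grid point is the selected threshold.  Ties in
    plateau length are broken toward the larger t (the sparser, more
    conservative graph).  When the longest plateau spans the whole grid
    (e.g. a constant column) or no point qualifies, the smallest grid point
    is returned with a "no inflection found" warning.
    """
    if criterion not in PLATEAU_FLOOR:
        raise ValueError(f"unknown criterion {criterion!r}")
    col = "lambda1" if criterion == "spectral_drop" else "max_clique"
    if col not in profile.columns:
        raise ValueError(f"profile lacks the {col!r} column required by {criterion!r}")
    if len(profile) < 3:
        raise ValueError("profile needs at least 3 grid points")
    t_grid = profile["t"].to_numpy(dtype=float)
    s = profile[col].to_numpy(dtype=float)
    floor = PLATEAU_FLOOR[criterion]
    runs: list[tuple[int, int]] = []  # [start, end] inclusive
    k = 0
    n = len(s)
    while k < n:
        if s[k] < floor:
            k += 1
            continue
        start = k
        while (
            k + 1 < n
            and s[k + 1] >= floor
            and s[k] > 0
            and (s[k] - s[k + 1]) / s[k] <= PLATEAU_DROP_TOLERANCE
        ):
            k += 1
        runs.append((start, k))
        k += 1
    if not runs:
        log.warning(
            "select_threshold(%s): no non-trivial structure anywhere on the "
            "grid; no inflection found, returning the smallest grid point t=%g",
            criterion, t_grid[0],
        )
        return float(t_grid[0])
    # longest plateau wins; ties toward larger t
    start, end = max(runs, key=lambda r: (r[1] - r[0], t_grid[r[0]]))
    if start == 0 and end == n - 1:
        log.warning(
            "select_threshold(%s): profile is one stable plateau; no inflection "
            "found, returning the smallest grid point t=%g", criterion, t_grid[0],
        )
        return float(t_grid[0])
    runners = sorted(
        ((r[1] - r[0] + 1, float(t_grid[r[0]])) for r in runs if r != (start, end)),
        reverse=True,
    )[:3]
    log.info(
        "select_threshold(%s): t=%g (plateau of %d grid points up to t=%g); "
        "runner-up plateaus (length, start t): %s",
        criterion, t_grid[start], end - start + 1, t_grid[end], runners,
    )
    return float(t_grid[start])
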