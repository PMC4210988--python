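"""Shared fixtures: small named graphs and random-graph factories."""

from __future__ import annotations

import numpy as np
import pytest

from glomnet import DataMatrix, SimpleGraph


def make_er_graph(n: int, p: float, rng: np.random.Generator) -> SimpleGraph:
    """Erdos-Renyi G(n, p) with vertices v00..v{n-1}."""
    ids = [f"v{i:02d}" for i in range(n)]
    g = SimpleGraph(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(ids[i], ids[j])
    return g


def complete_graph(ids) -> SimpleGraph:
    ids = list(ids)
    return SimpleGraph(ids, [(u, v) for k, u in enumerate(ids) for v in ids[k + 1:]])


@pytest.fixture
def er_graph():
    return make_er_graph


@pytest.fixture
def rng():
    return np.random.default_rng(20140419)


@pytest.fixture
def k5():
    return complete_graph("abcde")


@pytest.fixture
def c5():
    ids = list("abcde")
    return SimpleGraph(ids, list(zip(ids, ids[1:] + ids[:1])))


@pytest.fixture
def tiny_matrix():
    """4 units x 3 complete numeric variables."""
    values = np.array(
        [[1.0, 2.0, 1.0],
         [2.0, 1.0, 2.0],
         [3.0, 4.0, 2.5],
         [4.0, 3.0, 4.0]]
    )
    return DataMatrix(["u1", "u2", "u3", "u4"], ["x", "y", "z"], values)


def random_data_matrix(
    rng: np.random.Generator,
    n_units: int = 30,
    n_vars: int = 12,
    missing_rate: float = 0.0,
) -> DataMatrix:
    values = rng.standard_normal((n_units, n_vars))
    if missing_rate:
        values[rng.random(values.shape) < missing_rate] = np.nan
    return DataMatrix(
        [f"u{i}" for i in range(n_units)],
        [f"x{j}" for j in range(n_vars)],
        values,
    )
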