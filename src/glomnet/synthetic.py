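"""Synthetic county-like data with planted correlated blocks.

A Gaussian latent-factor model emulates the statistical structure the
toolchain targets: a few hundred to a few thousand observational units, a
few hundred variables organized into blocks of mutually high correlation
plus background noise, and an outcome linearly driven by a subset of the
latent factors.

Per unit, latent factors f ~ N(0, P) with P a factor correlation matrix.
A variable in block b with loading a is  x = a * f_b + sqrt(1 - a^2) * e,
e ~ N(0, 1) independent — so the expected within-block correlation is a^2
and the expected cross-block correlation between blocks i and j is
a_i * a_j * P_ij.  Background variables are pure unit noise.  An outcome is
y = sum_b w_b * f_b + N(0, sd^2), giving a theoretical outcome-variable
correlation of a * w_b / sqrt(w' P w + sd^2) for variables in block b
(independent factors: a * w_b / sqrt(sum w^2 + sd^2)).

Optional distortions (MCAR missingness, heavy outlier injection) exercise
the noisy, mis-measured character of real aggregate data.  All generation
is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamatrix import DataMatrix

__all__ = [
    "BlockSpec",
    "GroundTruth",
    "generate_block_data",
    "generate_outcome",
    "generate_two_cohorts",
    "default_county_blocks",
    "DEFAULT_N_UNITS",
    "DEFAULT_N_BACKGROUND",
    "DEFAULT_LOADING",
]

# Default scale: 10 blocks x 15 variables + 450 background ~ 600 variables
# over 1500 units, the county-level regime the generator emulates.
DEFAULT_N_UNITS = 1500
DEFAULT_N_BLOCKS = 10
DEFAULT_BLOCK_SIZE = 15
DEFAULT_N_BACKGROUND = 450
DEFAULT_LOADING = 0.9


@dataclass(frozen=True)
class BlockSpec:
    """A planted block: ``n_vars`` variables loading on one latent factor."""

    id: str
    n_vars: int
    loading: float = DEFAULT_LOADING

    def __post_init__(self) -> None:
        if self.n_vars < 1:
            raise ValueError("n_vars must be positive")
        if not 0.0 < self.loading <= 1.0:
            raise ValueError(f"loading must lie in (0, 1], got {self.loading}")


@dataclass
class GroundTruth:
    """What was planted: block membership, factor structure, outcome recipe."""

    membership: dict[str, str]  # variable -> block id or "background"
    block_ids: list[str]
    factor_corr: np.ndarray
    factor_scores: np.ndarray  # n_units x n_blocks latent draws
    seed: int
    outcome: dict | None = None
    cohorts: dict | None = None

    def block_members(self, block_id: str) -> frozenset[str]:
        return frozenset(v for v, b in self.membership.items() if b == block_id)


def default_county_blocks(
    n_blocks: int = DEFAULT_N_BLOCKS,
    block_size: int = DEFAULT_BLOCK_SIZE,
    loading: float = DEFAULT_LOADING,
) -> list[BlockSpec]:
    return [BlockSpec(f"B{k + 1:02d}", block_size, loading) for k in range(n_blocks)]


def _check_factor_corr(p: np.ndarray, n_blocks: int) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (n_blocks, n_blocks):
        raise ValueError(f"factor_corr must be {n_blocks}x{n_blocks}, got {p.shape}")
    if not np.allclose(p, p.T) or not np.allclose(np.diag(p), 1.0):
        raise ValueError("factor_corr must be symmetric with unit diagonal")
    try:
        np.linalg.cholesky(p)
    except np.linalg.LinAlgError:
        raise ValueError("factor_corr is not positive definite") from None
    return p


def _synthesize(
    rng: np.random.Generator,
    n_units: int,
    block_defs: Sequence[tuple[str, int, float]],  # (id, n_vars, effective loading)
    n_background: int,
    factor_corr: np.ndarray,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Draw factors and variables; loading 0 yields a pure-noise (scrambled)
    block.  Returns (values, variable ids, factor scores)."""
    n_blocks = len(block_defs)
    chol = np.linalg.cholesky(factor_corr)
    factors = rng.standard_normal((n_units, n_blocks)) @ chol.T
    cols: list[np.ndarray] = []
    var_ids: list[str] = []
    for b, (bid, n_vars, a) in enumerate(block_defs):
        noise = rng.standard_normal((n_units, n_vars))
        block = a * factors[:, [b]] + np.sqrt(1.0 - a * a) * noise
        cols.append(block)
        var_ids.extend(f"{bid}_{k + 1:02d}" for k in range(n_vars))
    if n_background:
        cols.append(rng.standard_normal((n_units, n_background)))
        var_ids.extend(f"bg{k + 1:03d}" for k in range(n_background))
    values = np.hstack(cols) if cols else np.empty((n_units, 0))
    return values, var_ids, factors


def generate_block_data(
    n_units: int = DEFAULT_N_UNITS,
    blocks: Sequence[BlockSpec] | None = None,
    n_background: int = DEFAULT_N_BACKGROUND,
    factor_corr: np.ndarray | None = None,
    seed: int = 0,
    missing_rate: float = 0.0,
    outlier_rate: float = 0.0,
    outlier_scale: float = 6.0,
) -> tuple[DataMatrix, GroundTruth]:
    """Generate a units x variables matrix with planted correlated blocks.

    ``factor_corr`` defaults to the identity (independent factors).  With
    ``missing_rate`` > 0 entries are blanked MCAR; with ``outlier_rate`` > 0
    entries receive heavy additive shocks of scale ``outlier_scale``.
    """
    if n_units < 10:
        raise ValueError("n_units must be at least 10")
    if blocks is None:
        blocks = default_county_blocks()
    ids = [b.id for b in blocks]
    if len(set(ids)) != len(ids):
        raise ValueError("block ids must be unique")
    factor_corr = (
        np.eye(len(blocks)) if factor_corr is None
        else _check_factor_corr(factor_corr, len(blocks))
    )
    rng = np.random.default_rng(seed)
    values, var_ids, factors = _synthesize(
        rng, n_units, [(b.id, b.n_vars, b.loading) for b in blocks],
        n_background, factor_corr,
    )
    if len(set(var_ids)) != len(var_ids):
        raise ValueError("block variable ids collide; use distinct block ids")
    if outlier_rate > 0:
        shock = rng.random(values.shape) < outlier_rate
        values = values + shock * rng.normal(0.0, outlier_scale, size=values.shape)
    if missing_rate > 0:
        values = values.copy()
        values[rng.random(values.shape) < missing_rate] = np.nan
    unit_ids = [f"C{k + 1:05d}" for k in range(n_units)]
    membership = {}
    for b in blocks:
        for k in range(b.n_vars):
            membership[f"{b.id}_{k + 1:02d}"] = b.id
    for k in range(n_background):
        membership[f"bg{k + 1:03d}"] = "background"
    dm = DataMatrix(unit_ids, var_ids, values)
    truth = GroundTruth(
        membership=membership,
        block_ids=list(ids),
        factor_corr=factor_corr,
        factor_scores=factors,
        seed=seed,
    )
    return dm, truth


def generate_outcome(
    dm: DataMatrix,
    truth: GroundTruth,
    block_weights: dict[str, float],
    noise_sd: float,
    seed: int = 0,
    name: str = "outcome",
) -> tuple[DataMatrix, GroundTruth]:
    """Append an outcome column driven by weighted latent factors plus noise.

    ``outcome_i = sum_b w_b * f_{i,b} + N(0, noise_sd^2)``; the recipe is
    recorded in ``truth.outcome``.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    unknown = set(block_weights) - set(truth.block_ids)
    if unknown:
        raise ValueError(f"unknown block id(s) in weights: {sorted(unknown)}")
    if name in dm.variable_ids:
        raise ValueError(f"variable {name!r} already exists")
    w = np.array([block_weights.get(b, 0.0) for b in truth.block_ids])
    rng = np.random.default_rng(seed)
    y = truth.factor_scores @ w + rng.normal(0.0, noise_sd, size=dm.n_units)
    out_dm = dm.with_column(name, y, outcome=True)
    truth.outcome = {
        "name": name,
        "weights": dict(block_weights),
        "noise_sd": float(noise_sd),
        "seed": int(seed),
    }
    return out_dm, truth


def theoretical_outcome_correlation(
    truth: GroundTruth, block_id: str, loading: float
) -> float:
    """Closed-form |r(outcome, x)| for a variable of ``block_id`` under the
    recorded outcome recipe."""
    if truth.outcome is None:
        raise ValueError("truth has no outcome recipe")
    w = np.array([truth.outcome["weights"].get(b, 0.0) for b in truth.block_ids])
    sd = truth.outcome["noise_sd"]
    var_y = float(w @ truth.factor_corr @ w) + sd * sd
    b = truth.block_ids.index(block_id)
    cov = loading * float(truth.factor_corr[b] @ w)
    return abs(cov) / np.sqrt(var_y)


def generate_two_cohorts(
    shared: Sequence[BlockSpec],
    a_only: Sequence[BlockSpec],
    b_only: Sequence[BlockSpec],
    n_units: int = DEFAULT_N_UNITS,
    seed: int = 0,
    n_background: int = 0,
) -> tuple[DataMatrix, DataMatrix, GroundTruth]:
    """Two cohort matrices over one variable universe.

    Blocks in ``a_only`` are correlated structure in cohort A but scrambled
    (loading 0, pure noise) in cohort B, and vice versa; ``shared`` blocks
    have identical distribution in both (draws are cohort-independent).
    Factors are independent across blocks.
    """
    all_blocks = list(shared) + list(a_only) + list(b_only)
    ids = [b.id for b in all_blocks]
    if len(set(ids)) != len(ids):
        raise ValueError("block ids overlap across cohort specifications")
    p = np.eye(len(all_blocks))
    ss = np.random.SeedSequence(seed).spawn(2)
    b_only_ids = {b.id for b in b_only}
    a_only_ids = {b.id for b in a_only}

    def defs(scrambled: set[str]) -> list[tuple[str, int, float]]:
        return [
            (b.id, b.n_vars, 0.0 if b.id in scrambled else b.loading)
            for b in all_blocks
        ]

    rng_a = np.random.default_rng(ss[0])
    rng_b = np.random.default_rng(ss[1])
    vals_a, var_ids, factors_a = _synthesize(rng_a, n_units, defs(b_only_ids), n_background, p)
    vals_b, _, factors_b = _synthesize(rng_b, n_units, defs(a_only_ids), n_background, p)
    if len(set(var_ids)) != len(var_ids):
        raise ValueError("block variable ids collide; use distinct block ids")
    unit_a = [f"A{k + 1:05d}" for k in range(n_units)]
    unit_b = [f"B{k + 1:05d}" for k in range(n_units)]
    membership = {}
    for b in all_blocks:
        for k in range(b.n_vars):
            membership[f"{b.id}_{k + 1:02d}"] = b.id
    for k in range(n_background):
        membership[f"bg{k + 1:03d}"] = "background"
    truth = GroundTruth(
        membership=membership,
        block_ids=ids,
        factor_corr=p,
        factor_scores=factors_a,
        seed=seed,
        cohorts={
            "shared": sorted(b.id for b in shared),
            "a_only": sorted(a_only_ids),
            "b_only": sorted(b_only_ids),
        },
    )
    return (
        DataMatrix(unit_a, var_ids, vals_a),
        DataMatrix(unit_b, list(var_ids), vals_b.copy()),
        truth,
    )
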