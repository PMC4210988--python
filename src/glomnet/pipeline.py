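"""The end-to-end toolchain: load -> filter -> normalize -> correlate ->
threshold -> paraclique -> rank -> coarsen (-> compare cohorts).

A :class:`PipelineConfig` fully determines a run; the resolved configuration
is serialized verbatim into the run's provenance record, and re-running the
same configuration produces byte-identical artifacts (no timestamps are
written).  Feedback and re-tuning are realized as re-runs with an edited
configuration, not interactive state.

A second input (``input_b``) switches the pipeline into two-cohort mode:
both cohorts run through identical stages, the coarsened graphs are
optionally thresholded to matched relative densities, and a differential
summary is emitted.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import correlate as correlate_mod
from .coarsen import (
    DEFAULT_OUTCOME_CUTOFF,
    CoarsenedGraph,
    RankedParaclique,
    coarsen as build_coarsened,
    match_relative_densities,
    rank_paracliques_by_outcome,
)
from .correlate import CorrelationGraph, apply_threshold, select_threshold, threshold_profile
from .datamatrix import (
    DEFAULT_VARIANCE_EPSILON,
    DataMatrix,
    filter_low_variance,
    load_data_matrix,
    write_data_matrix,
    zscore_normalize,
)
from .differential import DifferentialSummary, differential_summary
from .graphs import SimpleGraph, write_edge_list
from .paraclique import DEFAULT_GLOM, DEFAULT_MIN_CORE, Paraclique, extract_all_paracliques

__all__ = ["PipelineConfig", "PipelineResult", "CohortResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one toolchain run.

    Every field is validated before any stage executes; ``threshold`` fixes
    t directly, otherwise ``criterion`` selects it from the profile grid.
    """

    input: str | None = None
    input_b: str | None = None
    outcome: str | None = None
    delimiter: str | None = None
    normalize: bool = True
    variance_epsilon: float = DEFAULT_VARIANCE_EPSILON
    method: str = "pearson"
    min_overlap: int = correlate_mod.DEFAULT_MIN_OVERLAP
    absolute: bool = True
    threshold: float | None = None
    criterion: str = "spectral_drop"
    grid_start: float = correlate_mod.DEFAULT_GRID_START
    grid_stop: float = correlate_mod.DEFAULT_GRID_STOP
    grid_step: float = correlate_mod.DEFAULT_GRID_STEP
    glom: int = DEFAULT_GLOM
    min_core: int = DEFAULT_MIN_CORE
    overlap: bool = False
    fixpoint: bool = False
    outcome_cutoff: float = DEFAULT_OUTCOME_CUTOFF
    coarsen: bool = True
    match_density: bool = False
    write_correlation_matrix: bool = False
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if self.method not in correlate_mod.SUPPORTED_METHODS:
            raise ValueError(f"unsupported correlation method {self.method!r}")
        if self.variance_epsilon < 0:
            raise ValueError("variance_epsilon must be nonnegative")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be positive")
        if self.threshold is not None and not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.criterion not in ("spectral_drop", "clique_drop"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if not (0.0 <= self.grid_start < self.grid_stop <= 1.0 and self.grid_step > 0):
            raise ValueError("grid must satisfy 0 <= start < stop <= 1 with step > 0")
        if self.glom < 0:
            raise ValueError("glom must be nonnegative")
        if self.min_core < 2:
            raise ValueError("min_core must be at least 2")
        if not 0.0 <= self.outcome_cutoff <= 1.0:
            raise ValueError("outcome_cutoff must lie in [0, 1]")

    def grid(self) -> list[float]:
        return correlate_mod.default_grid(self.grid_start, self.grid_stop, self.grid_step)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class CohortResult:
    """Everything one cohort's stages produced."""

    data: DataMatrix
    correlation: CorrelationGraph
    profile: pd.DataFrame | None
    threshold: float
    threshold_source: str  # "fixed" or the criterion name
    graph: SimpleGraph
    paracliques: list[Paraclique]
    ranking: list[RankedParaclique] = field(default_factory=list)
    coarsened: CoarsenedGraph | None = None
    dropped_variables: list[str] = field(default_factory=list)


@dataclass
class PipelineResult:
    config: PipelineConfig
    a: CohortResult
    b: CohortResult | None = None
    differential: DifferentialSummary | None = None
    output_dir: Path | None = None
    provenance: dict[str, Any] = field(default_factory=dict)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and a remediation hint."""

    def __init__(self, stage: str, cause: Exception, hint: str = ""):
        msg = f"pipeline stage {stage!r} failed: {cause}"
        if hint:
            msg += f" (hint: {hint})"
        super().__init__(msg)
        self.stage = stage


def _run_cohort(dm: DataMatrix, config: PipelineConfig) -> CohortResult:
    before = list(dm.variable_ids)
    try:
        dm = filter_low_variance(dm, config.variance_epsilon)
    except Exception as e:  # pragma: no cover - defensive
        raise PipelineError("filter_low_variance", e) from e
    dropped = [v for v in before if v not in set(dm.variable_ids)]
    if config.normalize:
        try:
            dm = zscore_normalize(dm)
        except ValueError as e:
            raise PipelineError(
                "zscore_normalize", e,
                hint="raise variance_epsilon so constant variables are filtered",
            ) from e
    cg = correlate_mod.correlation_matrix(dm, config.method, config.min_overlap)
    # the outcome is ranked against paracliques, never allowed to join them
    cg_vars = cg.drop([config.outcome]) if config.outcome else cg
    profile = None
    if config.threshold is not None:
        t, source = float(config.threshold), "fixed"
    else:
        profile = threshold_profile(
            cg_vars, config.grid(), absolute=config.absolute,
            with_cliques=(config.criterion == "clique_drop") or None,
        )
        t = select_threshold(profile, config.criterion)
        source = config.criterion
    graph = apply_threshold(cg_vars, t, absolute=config.absolute)
    paracliques = extract_all_paracliques(
        graph, glom=config.glom, min_core=config.min_core,
        overlap=config.overlap, fixpoint=config.fixpoint,
    )
    ranking: list[RankedParaclique] = []
    if config.outcome:
        ranking = rank_paracliques_by_outcome(
            cg, paracliques, config.outcome, config.outcome_cutoff,
        )
    coarsened = None
    if config.coarsen and len(paracliques) >= 2:
        # label nodes by their smallest core member: a naming scheme that is
        # stable across cohorts, so coarsened graphs can be compared
        labels = [min(pc.core) for pc in paracliques]
        coarsened = build_coarsened(cg_vars, paracliques, labels=labels)
    return CohortResult(
        data=dm, correlation=cg, profile=profile, threshold=t,
        threshold_source=source, graph=graph, paracliques=paracliques,
        ranking=ranking, coarsened=coarsened, dropped_variables=dropped,
    )


def _write_cohort(res: CohortResult, outdir: Path, config: PipelineConfig) -> list[str]:
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def emit(name: str) -> Path:
        written.append(name)
        return outdir / name

    write_data_matrix(res.data, emit("preprocessed.csv"))
    if config.write_correlation_matrix:
        res.correlation.write_matrix_csv(emit("correlation_matrix.csv"))
    if res.profile is not None:
        res.profile.to_csv(emit("threshold_profile.csv"), index=False)
    write_edge_list(res.graph, emit("graph_edges.tsv"), emit("graph_vertices.txt"))
    with open(emit("paracliques.json"), "w", encoding="utf-8") as fh:
        json.dump([pc.to_dict() for pc in res.paracliques], fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(emit("membership.tsv"), "w", encoding="utf-8") as fh:
        fh.write("variable\tparaclique_index\trole\n")
        for pc in res.paracliques:
            for v in sorted(pc.core):
                fh.write(f"{v}\t{pc.extraction_index}\tcore\n")
            for v in sorted(pc.glommed):
                fh.write(f"{v}\t{pc.extraction_index}\tglommed\n")
    if res.ranking:
        with open(emit("ranking.tsv"), "w", encoding="utf-8") as fh:
            fh.write("paraclique_index\tmedian_abs_r\tselected\n")
            for rp in res.ranking:
                fh.write(f"{rp.index}\t{rp.median_abs_r_to_outcome!r}\t"
                         f"{str(rp.selected).lower()}\n")
    if res.coarsened is not None:
        res.coarsened.write_edge_list(emit("coarsened_edges.tsv"))
        res.coarsened.write_node_map(emit("coarsened_nodes.json"))
    return written


def _cohort_provenance(res: CohortResult) -> dict[str, Any]:
    return {
        "n_units": res.data.n_units,
        "n_variables": res.data.n_variables,
        "dropped_low_variance": res.dropped_variables,
        "threshold": res.threshold,
        "threshold_source": res.threshold_source,
        "n_edges": res.graph.n_edges,
        "n_paracliques": len(res.paracliques),
        "paraclique_sizes": [pc.size for pc in res.paracliques],
        "n_selected": sum(1 for rp in res.ranking if rp.selected),
        "coarsened_edges": res.coarsened.n_edges if res.coarsened else None,
    }


def run_pipeline(
    config: PipelineConfig,
    dm: DataMatrix | None = None,
    dm_b: DataMatrix | None = None,
) -> PipelineResult:
    """Execute the toolchain under ``config``.

    Inputs come from ``config.input`` / ``config.input_b`` unless in-memory
    matrices are supplied.  When ``config.output_dir`` is set, every
    intermediate artifact plus a provenance record and a manifest are
    written there (two-cohort runs write into ``a/`` and ``b/``
    subdirectories).
    """
    config.validate()
    if config.outcome is None and dm is not None and dm.outcome_id is not None:
        config = dataclasses.replace(config, outcome=dm.outcome_id)
    if dm is None:
        if config.input is None:
            raise ValueError("no input: set config.input or pass a DataMatrix")
        try:
            dm = load_data_matrix(config.input, outcome=config.outcome,
                                  delimiter=config.delimiter)
        except Exception as e:
            raise PipelineError("load", e, hint="check the input path and dialect") from e
    elif config.outcome and dm.outcome_id != config.outcome:
        if config.outcome not in dm.variable_ids:
            raise PipelineError(
                "load", ValueError(f"outcome {config.outcome!r} not present"),
                hint="outcome must name a column of the input",
            )
    if dm_b is None and config.input_b:
        try:
            dm_b = load_data_matrix(config.input_b, outcome=config.outcome,
                                    delimiter=config.delimiter)
        except Exception as e:
            raise PipelineError("load_b", e, hint="check the input path and dialect") from e

    res_a = _run_cohort(dm, config)
    res_b = _run_cohort(dm_b, config) if dm_b is not None else None

    diff = None
    if res_b is not None:
        if config.match_density and res_a.coarsened and res_b.coarsened:
            ga, gb = match_relative_densities(res_a.coarsened, res_b.coarsened)
            res_a.coarsened, res_b.coarsened = ga, gb
        if res_a.coarsened and res_b.coarsened:
            diff = differential_summary(res_a.coarsened, res_b.coarsened)
        else:
            diff = differential_summary(res_a.graph, res_b.graph)

    provenance: dict[str, Any] = {
        "config": config.to_dict(),
        "cohort_a": _cohort_provenance(res_a),
    }
    if res_b is not None:
        provenance["cohort_b"] = _cohort_provenance(res_b)

    outdir = None
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, Any] = {}
        if res_b is None:
            manifest["a"] = _write_cohort(res_a, outdir, config)
        else:
            manifest["a"] = _write_cohort(res_a, outdir / "a", config)
            manifest["b"] = _write_cohort(res_b, outdir / "b", config)
        if diff is not None:
            diff.write_json(outdir / "differential.json")
            manifest["differential"] = ["differential.json"]
        with open(outdir / "provenance.json", "w", encoding="utf-8") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return PipelineResult(
        config=config, a=res_a, b=res_b, differential=diff,
        output_dir=outdir, provenance=provenance,
    )
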