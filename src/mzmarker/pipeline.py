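"""End-to-end orchestration: normalize -> partition -> reduce -> rank ->
select -> markers -> final test.

`run_pipeline` wires the individual modules together in the order the
screening workflow prescribes and records every decision in a run log
(a list of JSON-serializable dicts). Feature grouping by default sees
only fit-partition rows so the held-out patients cannot influence
feature selection; ``reduction_rows="all"`` reproduces the variant in
which every vector (test included) feeds the elimination, and
``marker_rows="all"`` does the same for the marker criterion.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from . import learning, markers, reduction
from .exceptions import ConfigError
from .io import IntensityMatrix, normalize_rows
from .learning import (
    ConfusionCounts,
    DiagnosisClassifier,
    Metrics,
    PartitionPlan,
    RankingTrace,
    TreesFunction,
)
from .markers import MarkerDecision


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the full screen; defaults follow the workflow's
    standard settings (20% test, 10 experiments at 20% validation,
    0.9 trim factor, beta = 0.4, relative pivot tolerance 1e-8)."""

    seed: int = 0
    test_fraction: float = 0.2
    n_experiments: int = 10
    val_fraction: float = 0.2
    pivot_tolerance: float = 1e-8
    reduction_rows: str = "fit"  # "all" = accession-reproduction variant
    reduction_factor: float = 0.9
    lengths_grid: tuple[int, ...] = (16, 64, 256)
    trees_grid: tuple[int, ...] = (10, 20, 58)
    beta: float = 0.4
    marker_rows: str = "fit"
    aggregation: str = "patient"

    def validate(self) -> None:
        if self.reduction_rows not in ("fit", "all"):
            raise ConfigError(f"reduction_rows must be 'fit' or 'all', got {self.reduction_rows!r}")
        if self.marker_rows not in ("fit", "all"):
            raise ConfigError(f"marker_rows must be 'fit' or 'all', got {self.marker_rows!r}")


@dataclass
class PipelineResult:
    plan: PartitionPlan
    dependency: reduction.DependencyReduction
    reduced: IntensityMatrix
    trees_fn: TreesFunction
    trace: RankingTrace
    optimal_channels: tuple[int, ...]
    classifier: DiagnosisClassifier
    test_metrics: Metrics
    test_counts: ConfusionCounts
    marker_decisions: list[MarkerDecision]
    run_log: list[dict] = field(default_factory=list)


def run_pipeline(matrix: IntensityMatrix, config: PipelineConfig) -> PipelineResult:
    """Run the whole biomarker screen on a labeled feature matrix."""
    config.validate()
    log: list[dict] = [{"step": "config", **asdict(config)}]

    normalized = matrix if matrix.normalized else normalize_rows(matrix)

    plan = learning.split_fit_test(
        normalized.patient_class, config.test_fraction, seed=config.seed
    )
    plan = learning.make_experiments(
        plan, config.n_experiments, config.val_fraction, seed=config.seed
    )
    log.append(
        {
            "step": "partition",
            "test": {c: len(p) for c, p in plan.test_patients.items()},
            "fit": {c: len(p) for c, p in plan.fit_patients.items()},
            "n_experiments": len(plan.experiments),
        }
    )

    reduction_input = (
        normalized if config.reduction_rows == "all"
        else normalized.subset_patients(plan.all_fit())
    )
    dependency = reduction.find_dependent_groups(reduction_input, config.pivot_tolerance)
    reduced = reduction.reduce(normalized, dependency)
    log.append(
        {
            "step": "reduction",
            "rows": config.reduction_rows,
            "n_rows_used": dependency.n_rows_used,
            "n_channels_in": len(dependency.mz_labels),
            "n_representatives": len(dependency.representatives),
        }
    )

    fit_matrix = reduced.subset_patients(plan.all_fit())
    trees_fn = learning.grid_search_trees(
        fit_matrix, plan, config.lengths_grid, config.trees_grid,
        seed=config.seed, aggregation=config.aggregation,
    )
    log.append({"step": "grid_search", "mapping": dict(trees_fn.mapping)})

    trace = learning.iterate_ranking(
        fit_matrix, plan, trees_fn, config.reduction_factor,
        seed=config.seed, aggregation=config.aggregation,
    )
    optimal = learning.select_optimal(trace)
    log.append({"step": "ranking", "iterations": len(trace.iterations),
                "optimal_length": len(optimal)})

    marker_patients = None if config.marker_rows == "all" else plan.all_fit()
    decisions = markers.detect_markers(
        reduced, list(optimal), beta=config.beta, patients=marker_patients
    )
    log.append(
        {
            "step": "markers",
            "beta": config.beta,
            "rows": config.marker_rows,
            "n_markers": sum(d.is_marker for d in decisions),
        }
    )

    classifier = learning.train_diagnosis_classifier(
        reduced, plan, optimal, trees_fn, seed=config.seed
    )
    test_metrics, test_counts = learning.evaluate_on_test(
        classifier, reduced, plan, aggregation=config.aggregation
    )
    log.append(
        {
            "step": "final_test",
            "aggregation": config.aggregation,
            "counts": asdict(test_counts),
            "metrics_percent": test_metrics.as_percent(),
        }
    )

    return PipelineResult(
        plan=plan,
        dependency=dependency,
        reduced=reduced,
        trees_fn=trees_fn,
        trace=trace,
        optimal_channels=tuple(optimal),
        classifier=classifier,
        test_metrics=test_metrics,
        test_counts=test_counts,
        marker_decisions=decisions,
        run_log=log,
    )
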