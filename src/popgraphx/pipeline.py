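"""End-to-end pipeline: cohort -> cleaning -> split -> standardization ->
population graph -> trained classifier.

Convenience layer used by the CLI, the evaluation suite and the tests;
every stage is also callable on its own.  A single seed fans out to
per-stage derived seeds so stages stay independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import SIMILARITY_FEATURES
from .gcn import GCNConfig, GCNModel, TrainResult, evaluate_metrics, predict, train
from .popgraph import DEFAULT_EDGE_THRESHOLD, PopulationGraph, build_graph_from_table
from .preprocess import (
    ScalerStats,
    SplitAssignment,
    clean_features,
    feature_matrix,
    label_codes,
    split_dataset,
    standardize,
)
from .synthetic_cohort import CohortSpec, default_spec, generate_cohort

_STAGE_OFFSETS = {"cohort": 1, "split": 2, "model": 3, "shapley": 4}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the run seed (stable, < 2**31)."""
    return (seed * 1000 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class PipelineResult:
    table: pd.DataFrame            # original-unit cohort (after cleaning)
    standardized: pd.DataFrame
    split: SplitAssignment
    scaler: ScalerStats
    graph: PopulationGraph
    X: np.ndarray
    y: np.ndarray
    train_result: TrainResult
    test_metrics: dict = field(default_factory=dict)

    @property
    def model(self) -> GCNModel:
        return self.train_result.model


def run_pipeline(seed: int, spec: CohortSpec | None = None,
                 table: pd.DataFrame | None = None,
                 n_override: dict[str, int] | None = None,
                 edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
                 config: GCNConfig | None = None,
                 measures: tuple[str, ...] = SIMILARITY_FEATURES
                 ) -> PipelineResult:
    """Run the full study pipeline for one seed.

    Either ``table`` (a raw cohort CSV already loaded) or ``spec``
    (synthetic generation parameters; defaults to the published cohort
    statistics) provides the input data.
    """
    if table is None:
        spec = spec or default_spec()
        table = generate_cohort(spec, seed=stage_seed(seed, "cohort"),
                                n_override=n_override)
    cleaned = clean_features(table)
    split = split_dataset(cleaned, seed=stage_seed(seed, "split"))
    std, scaler = standardize(cleaned, split)
    graph = build_graph_from_table(std, measures=measures,
                                   edge_threshold=edge_threshold)
    X = feature_matrix(std)
    y = label_codes(std)
    cfg = config or GCNConfig(in_dim=X.shape[1])
    result = train(X, graph, y, split, cfg, seed=stage_seed(seed, "model"))
    test_mask = split.mask("test")
    pred = predict(result.model, X, graph)
    metrics = evaluate_metrics(y[test_mask], pred[test_mask])
    return PipelineResult(table=cleaned, standardized=std, split=split,
                          scaler=scaler, graph=graph, X=X, y=y,
                          train_result=result, test_metrics=metrics)
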