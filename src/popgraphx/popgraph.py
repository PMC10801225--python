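"""Population-graph construction.

Nodes are subjects; edge weights encode cognitive similarity.  For each
cognitive measure (memory, executive function, language) pairwise
Euclidean distances are scaled into [0,1] by the maximum pairwise
distance and subtracted from one.  The per-measure similarities are
combined (arithmetic mean), min-max rescaled over the off-diagonal, and
thresholded: weights below ``edge_threshold`` are dropped (no
significant similarity = no edge).  The diagonal is always zero.

The spectral GCN consumes the renormalized adjacency
``A_tilde = D_hat^{-1/2} (A + I) D_hat^{-1/2}`` where ``D_hat`` is the
degree matrix of the self-looped adjacency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

#: Weights below this are "no significant similarity" and become
#: non-edges.  Chosen so that surviving neighborhoods sit at the tens
#: scale (single-digit same-class neighbors at weights > 0.96) and a
#: node's own features keep non-negligible weight after the self-looped
#: renormalization — both prerequisites for meaningful occlusion
#: explanations.
DEFAULT_EDGE_THRESHOLD = 0.95


@dataclass
class PopulationGraph:
    """Weighted symmetric adjacency plus cached renormalization.

    ``A`` has zero diagonal and entries in [0,1]; ``labels`` (optional)
    are the per-node class labels used for class-wise edge silencing and
    neighborhood profiles.
    """

    A: np.ndarray
    similarities: dict[str, np.ndarray] = field(default_factory=dict)
    labels: np.ndarray | None = None
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD
    _A_tilde: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def A_tilde(self) -> np.ndarray:
        if self._A_tilde is None:
            self._A_tilde = normalize_adjacency(self.A)
        return self._A_tilde


def measure_similarity(values: np.ndarray) -> np.ndarray:
    """Similarity matrix of one measurement vector.

    ``S[h, w] = 1 - |v_h - v_w| / max_pairwise_distance``; diagonal 0.
    An all-equal vector yields similarity 1 off-diagonal (with a
    warning), by convention.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 nodes")
    delta = np.abs(v[:, None] - v[None, :])
    dmax = delta.max()
    if dmax == 0.0:
        warnings.warn("all measurements equal; similarity 1 off-diagonal")
        S = np.ones_like(delta)
    else:
        S = 1.0 - delta / dmax
    np.fill_diagonal(S, 0.0)
    return S


def build_adjacency(similarities: dict[str, np.ndarray],
                    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
                    labels: np.ndarray | None = None) -> PopulationGraph:
    """Combine per-measure similarities into the final weighted adjacency.

    Mean over measures, min-max rescale over off-diagonal entries, then
    zero out entries strictly below ``edge_threshold``.
    """
    mats = list(similarities.values())
    if not mats:
        raise ValueError("need at least one similarity matrix")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("similarity matrices have mismatched shapes")
    A = np.mean(mats, axis=0)
    n = A.shape[0]
    off = ~np.eye(n, dtype=bool)
    lo, hi = A[off].min(), A[off].max()
    if hi > lo:
        A = (A - lo) / (hi - lo)
    A[A < edge_threshold] = 0.0
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 0.0)
    np.clip(A, 0.0, 1.0, out=A)
    return PopulationGraph(A=A, similarities=dict(similarities),
                           labels=None if labels is None else np.asarray(labels),
                           edge_threshold=edge_threshold)


def build_graph_from_table(table: pd.DataFrame,
                           measures: tuple[str, ...] | None = None,
                           edge_threshold: float = DEFAULT_EDGE_THRESHOLD
                           ) -> PopulationGraph:
    """Population graph from (standardized) cohort columns.

    ``measures`` defaults to the three cognitive composites.
    """
    from .features import SIMILARITY_FEATURES
    from .preprocess import label_codes
    measures = tuple(measures) if measures is not None else SIMILARITY_FEATURES
    sims = {m: measure_similarity(table[m].to_numpy(dtype=float)) for m in measures}
    return build_adjacency(sims, edge_threshold=edge_threshold,
                           labels=label_codes(table))


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """``D_hat^{-1/2} (A + I) D_hat^{-1/2}`` (always well defined: the
    self-loop makes every degree >= 1)."""
    A = np.asarray(A, dtype=float)
    A_hat = A + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_hat * inv_sqrt[:, None] * inv_sqrt[None, :]


def neighborhood(graph: PopulationGraph, node: int, min_weight: float,
                 same_class_as: int | None = None) -> np.ndarray:
    """Nodes w with ``A[node, w] > min_weight``, optionally restricted to
    one class label."""
    if not 0 <= node < graph.n_nodes:
        raise IndexError(f"node {node} not in graph of size {graph.n_nodes}")
    sel = graph.A[node] > min_weight
    sel[node] = False
    if same_class_as is not None:
        if graph.labels is None:
            raise ValueError("graph has no labels to filter by class")
        sel &= graph.labels == same_class_as
    return np.flatnonzero(sel)


# -- persistence -------------------------------------------------------

def write_edge_list(graph: PopulationGraph, path) -> None:
    """Whitespace TSV edge list (i, j, weight), upper triangle only."""
    i, j = np.nonzero(np.triu(graph.A, k=1))
    with open(path, "w") as fh:
        for a, b in zip(i, j):
            fh.write(f"{a}\t{b}\t{graph.A[a, b]:.10g}\n")


def read_edge_list(path, n_nodes: int,
                   edge_threshold: float = DEFAULT_EDGE_THRESHOLD) -> PopulationGraph:
    A = np.zeros((n_nodes, n_nodes))
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            a, b, w = line.split()
            A[int(a), int(b)] = A[int(b), int(a)] = float(w)
    return PopulationGraph(A=A, edge_threshold=edge_threshold)


def write_mtx(graph: PopulationGraph, path) -> None:
    spio.mmwrite(path, sparse.coo_matrix(graph.A))


def read_mtx(path, edge_threshold: float = DEFAULT_EDGE_THRESHOLD) -> PopulationGraph:
    A = np.asarray(spio.mmread(path).todense(), dtype=float)
    return PopulationGraph(A=A, edge_threshold=edge_threshold)
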