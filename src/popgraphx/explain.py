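"""Decomposition-based factual/counterfactual explanations.

For a node x with predicted class y* and runner-up class y', the
influence of an input element is the drop in class probability when
that element is occluded:

* feature level:  Var_i(y|x)  = p(y|x) - p(y|x \\ T_i)
* group level:    GrpVar(y|x) = p(y|x) - p(y|x \\ T_{1..a})   (all a
  features of one modality occluded concurrently)
* edge level:     EdgVar(y|x) = p(y|x) - p(y|x \\ E_c)        (edges to
  all class-c neighbors silenced, adjacency renormalized)

Positive influence supports the class, negative opposes it; because
probabilities sum to one, the three class-wise variations of any single
occlusion sum to zero, so probability lost by the predicted class is
gained by the others — the counterfactual reading.

Display helpers normalize influences to mean absolute magnitude 1,
discretize feature values into clinical bins, compute deviations from
age/gender-matched healthy references, and render template sentences.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (
    CLASSES,
    CONTINUOUS_FEATURES,
    FEATURES,
    GROUPS,
    LOWER_IS_WORSE,
)
from .gcn import GCNModel, MaskSpec, forward, node_class_probs_for_rows
from .popgraph import PopulationGraph

#: Qualitative severity bins by signed SD distance from the pooled mean.
_SD_BINS = (
    (-np.inf, -1.5, "very low"),
    (-1.5, -0.5, "low"),
    (-0.5, 0.5, "nominal"),
    (0.5, 1.0, "not so high"),
    (1.0, 1.5, "high"),
    (1.5, np.inf, "very high"),
)

_GDS_CUTOFFS = ((9, "normal"), (19, "mild depressive"), (np.inf, "severe depressive"))
_MMSE_CUTOFFS = ((9, "severe dementia"), (20, "moderate dementia"),
                 (24, "mild dementia"), (30, "normal cognition"))


@dataclass
class ExplanationBundle:
    """All influence scores for one node, plus display products."""

    node: int
    probabilities: np.ndarray          # (3,) base class probabilities
    predicted_class: str
    counterfactual_class: str
    feature_influences: pd.DataFrame   # 13 x 3 (classes), raw Var
    group_influences: pd.DataFrame     # 5 x 3, raw GrpVar
    edge_influences: pd.DataFrame      # 3 (silenced class) x 3, raw EdgVar
    neighbor_profile: dict[str, float] = field(default_factory=dict)
    normalized_factual: pd.Series | None = None
    normalized_counterfactual: pd.Series | None = None
    sentences: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "node": int(self.node),
            "probabilities": {c: float(p) for c, p in
                              zip(CLASSES, self.probabilities)},
            "predicted_class": self.predicted_class,
            "counterfactual_class": self.counterfactual_class,
            "feature_influences": self.feature_influences.round(12).to_dict(),
            "group_influences": self.group_influences.round(12).to_dict(),
            "edge_influences": self.edge_influences.round(12).to_dict(),
            "neighbor_profile": self.neighbor_profile,
            "normalized_factual": None if self.normalized_factual is None
            else self.normalized_factual.round(12).to_dict(),
            "normalized_counterfactual": None if self.normalized_counterfactual is None
            else self.normalized_counterfactual.round(12).to_dict(),
            "sentences": self.sentences,
        }, indent=2)


def _require_trained(model: GCNModel) -> None:
    if not model.trained:
        raise ValueError("model is not trained")


def predicted_and_runner_up(probs: np.ndarray) -> tuple[int, int]:
    """Class codes of the predicted and second-most-probable class.

    A runner-up tie is broken toward the class clinically adjacent to
    the prediction in the ordering NC < MCI < AD.
    """
    order = np.argsort(probs)[::-1]
    y_star = int(order[0])
    cand = [int(order[1]), int(order[2])]
    if np.isclose(probs[cand[0]], probs[cand[1]]):
        cand.sort(key=lambda c: (abs(c - y_star), c))
    return y_star, cand[0]


def _occlusion_probs(model: GCNModel, graph: PopulationGraph, X: np.ndarray,
                     node: int, feature_sets: list[list[int]]) -> np.ndarray:
    """Node probabilities with each listed feature set occluded (rows of
    the interest node only), via the fast single-row evaluator."""
    rows = np.repeat(X[node][None, :], len(feature_sets), axis=0)
    for k, fs in enumerate(feature_sets):
        rows[k, fs] = 0.0
    return node_class_probs_for_rows(model, X, graph, node, rows)


def feature_influences(node: int, model: GCNModel, graph: PopulationGraph,
                       X: np.ndarray) -> pd.DataFrame:
    """Raw per-feature influences for all three classes (13 x 3)."""
    _require_trained(model)
    base = node_class_probs_for_rows(model, X, graph, node, X[node][None, :])[0]
    occluded = _occlusion_probs(model, graph, X, node,
                                [[j] for j in range(len(FEATURES))])
    var = base[None, :] - occluded
    return pd.DataFrame(var, index=list(FEATURES), columns=list(CLASSES))


def group_influences(node: int, model: GCNModel, graph: PopulationGraph,
                     X: np.ndarray) -> pd.DataFrame:
    """Raw per-modality influences (5 x 3): all group members occluded
    concurrently."""
    _require_trained(model)
    names = list(GROUPS)
    sets = []
    for g in names:
        members = [FEATURES.index(f) for f in GROUPS[g]]
        if not members:
            raise ValueError(f"empty group {g!r}")
        sets.append(members)
    base = node_class_probs_for_rows(model, X, graph, node, X[node][None, :])[0]
    occluded = _occlusion_probs(model, graph, X, node, sets)
    return pd.DataFrame(base[None, :] - occluded, index=names, columns=list(CLASSES))


def edge_class_influences(node: int, model: GCNModel, graph: PopulationGraph,
                          X: np.ndarray) -> pd.DataFrame:
    """Raw per-class edge influences (3 x 3): for each class c, edges
    from the node to class-c neighbors are zeroed, the adjacency is
    renormalized, and the probability change is measured."""
    _require_trained(model)
    if graph.labels is None:
        raise ValueError("graph has no node labels")
    base = forward(model, X, graph)[node]
    rows = []
    for c in range(len(CLASSES)):
        probs = forward(model, X, graph,
                        MaskSpec(edge_classes=[(node, c)]))[node]
        rows.append(base - probs)
    return pd.DataFrame(rows, index=list(CLASSES), columns=list(CLASSES))


def neighbor_class_profile(node: int, graph: PopulationGraph,
                           weighted: bool = False) -> dict[str, float]:
    """Percentage of the node's (nonzero-weight) neighbors per class."""
    if graph.labels is None:
        raise ValueError("graph has no node labels")
    w = graph.A[node].copy()
    w[node] = 0.0
    nbr = np.flatnonzero(w)
    if nbr.size == 0:
        warnings.warn(f"node {node} is isolated; neighbor profile is all zero")
        return {c: 0.0 for c in CLASSES}
    out = {}
    total = w[nbr].sum() if weighted else float(nbr.size)
    for ci, c in enumerate(CLASSES):
        sel = nbr[graph.labels[nbr] == ci]
        mass = w[sel].sum() if weighted else float(sel.size)
        out[c] = 100.0 * mass / total
    return out


def normalize_influences(vector: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Scale influences so the mean absolute value is 1 (signs kept).

    An all-zero vector is returned unchanged with a warning.
    """
    arr = np.asarray(vector, dtype=float)
    scale = np.abs(arr).mean()
    if scale == 0.0:
        warnings.warn("all influences are zero; nothing to normalize")
        return vector
    out = arr / scale
    if isinstance(vector, pd.Series):
        return pd.Series(out, index=vector.index)
    return out


def pooled_stats(table: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """All-class pooled mean/SD per continuous feature (for binning)."""
    return {f: (float(table[f].mean()), float(table[f].std(ddof=0)))
            for f in CONTINUOUS_FEATURES}


def discretize_feature(name: str, value: float,
                       pooled: dict[str, tuple[float, float]] | None = None) -> str:
    """Bin label for a feature value.

    GDS and MMSE use published clinical cutoffs; other continuous
    features are binned by signed SD distance from the pooled mean, with
    the sign flipped for features where lower values are clinically
    worse (so a very low MMSE-like score reads as "very high" severity
    direction, matching the qualitative usage "not so high" for mildly
    reduced imaging values).
    """
    if name == "gds":
        for hi, lab in _GDS_CUTOFFS:
            if value <= hi:
                return lab
    if name == "mmse":
        for hi, lab in _MMSE_CUTOFFS:
            if value <= hi:
                return lab
        return _MMSE_CUTOFFS[-1][1]
    if name == "gender":
        return "female" if value == 2 else "male"
    if name in ("abeta", "tau"):
        return "positive" if value > 0 else "negative"
    if name not in CONTINUOUS_FEATURES:
        raise KeyError(f"unknown feature {name!r}")
    if pooled is None or name not in pooled:
        raise ValueError(f"pooled stats required to bin {name!r}")
    mu, sd = pooled[name]
    z = (value - mu) / sd if sd > 0 else 0.0
    if name in LOWER_IS_WORSE:
        z = -z
    for lo, hi, lab in _SD_BINS:
        if lo <= z < hi:
            return lab
    return _SD_BINS[-1][2]


def reference_deviation(record: pd.Series, reference_table: pd.DataFrame,
                        age_window: float = 5.0) -> pd.Series:
    """Deviation of a record from healthy (NC) subjects of the same
    gender within +-``age_window`` years of age, in original units.

    An empty stratum widens the age window stepwise (with a warning).
    """
    ref = reference_table[reference_table["label"] == "NC"]
    if ref.empty:
        raise ValueError("reference table holds no NC rows")
    window = age_window
    while True:
        stratum = ref[(ref["gender"] == record["gender"])
                      & ((ref["age"] - record["age"]).abs() <= window)]
        if len(stratum):
            break
        warnings.warn(f"empty reference stratum; widening age window to "
                      f"{window + age_window:g} years")
        window += age_window
    means = stratum[list(FEATURES)].mean()
    return record[list(FEATURES)].astype(float) - means


def render_text(bundle: ExplanationBundle,
                discretizations: dict[str, str],
                deviations: pd.Series | None = None,
                floor: float = 0.25) -> list[str]:
    """Template sentences for the influential features, ordered by
    decreasing influence magnitude.

    One sentence per feature with |normalized factual influence| above
    ``floor``.
    """
    norm = bundle.normalized_factual
    if norm is None:
        raise ValueError("bundle has no normalized factual influences")
    order = norm.abs().sort_values(ascending=False).index
    sentences = []
    for f in order:
        v = norm[f]
        if abs(v) <= floor:
            continue
        direction = "supports" if v > 0 else "opposes"
        bin_label = discretizations.get(f, "unknown")
        if deviations is not None and f in deviations.index \
                and np.isfinite(deviations[f]):
            dev = f"({deviations[f]:+.2f} vs. matched healthy reference)"
        else:
            dev = "(no reference)"
        sentences.append(
            f"{f.upper()} is {bin_label} {dev}, which {direction} "
            f"{bundle.predicted_class}")
    return sentences


def explain_node(node: int, model: GCNModel, graph: PopulationGraph,
                 X: np.ndarray, display_table: pd.DataFrame | None = None,
                 floor: float = 0.25) -> ExplanationBundle:
    """Full explanation bundle for one node.

    ``display_table`` (original-unit cohort rows, pre-standardization)
    enables discretization, reference deviations and text; without it
    only the raw and normalized influences are produced.
    """
    _require_trained(model)
    base = forward(model, X, graph)[node]
    y_star, y_prime = predicted_and_runner_up(base)
    feats = feature_influences(node, model, graph, X)
    groups = group_influences(node, model, graph, X)
    edges = edge_class_influences(node, model, graph, X)
    bundle = ExplanationBundle(
        node=node,
        probabilities=base,
        predicted_class=CLASSES[y_star],
        counterfactual_class=CLASSES[y_prime],
        feature_influences=feats,
        group_influences=groups,
        edge_influences=edges,
        neighbor_profile=neighbor_class_profile(node, graph),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle.normalized_factual = normalize_influences(feats[CLASSES[y_star]])
        bundle.normalized_counterfactual = normalize_influences(feats[CLASSES[y_prime]])
    if display_table is not None:
        record = display_table.iloc[node]
        pooled = pooled_stats(display_table)
        discretizations = {f: discretize_feature(f, float(record[f]), pooled)
                           for f in FEATURES}
        deviations = reference_deviation(record, display_table)
        bundle.sentences = render_text(bundle, discretizations, deviations,
                                       floor=floor)
    return bundle
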