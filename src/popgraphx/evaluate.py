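"""Evaluation suite: explanation stability, Shapley agreement, and
modality ablation.

* Stability: explanations of same-class neighbors at decreasing
  edge-weight thresholds should stay in the same range; reported as the
  per-feature |max - min| of normalized influences across each
  neighborhood.
* Shapley agreement: decomposition influences are compared against
  Shapley attributions of the predicted-class probability, with train
  rows as the background distribution (feature values outside a
  coalition are replaced by background-row values).  Exact enumeration
  and seeded permutation sampling are both provided; the exact
  enumerator doubles as an oracle for the sampler.
* Modality ablation: retrain with modality groups removed and compare
  macro-F1 / accuracy across subsets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .features import CLASSES, FEATURES, GROUPS, resolve_groups
from .gcn import (
    GCNConfig,
    GCNModel,
    evaluate_metrics,
    forward,
    node_class_probs_for_rows,
    predict,
    train,
)
from .explain import feature_influences, normalize_influences
from .popgraph import PopulationGraph, neighborhood

DEFAULT_THRESHOLDS = (0.96, 0.94, 0.90, 0.85, 0.80)


# ---------------------------------------------------------------------
# Stability
# ---------------------------------------------------------------------

@dataclass
class StabilityReport:
    anchor: int
    thresholds: tuple[float, ...]
    neighbor_sets: dict[float, np.ndarray]
    distances: pd.DataFrame  # thresholds x 13 features, |max - min| influence

    def to_csv(self, path) -> None:
        df = self.distances.copy()
        df.insert(0, "n_neighbors",
                  [len(self.neighbor_sets[e]) for e in self.thresholds])
        df.to_csv(path)


def stability_table(anchor: int, graph: PopulationGraph, model: GCNModel,
                    X: np.ndarray,
                    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                    normalized: bool = True,
                    rescale_per_feature: bool = False,
                    neighbor_graph: PopulationGraph | None = None
                    ) -> StabilityReport:
    """Neighborhood explanation-similarity table.

    For each threshold e, same-class neighbors with edge weight > e are
    collected (anchor included); each node's feature influences for its
    own predicted class are computed, and the per-feature |max - min|
    across the neighborhood is reported.

    ``neighbor_graph`` lets neighbor identification use a less
    aggressively thresholded graph than the model's (needed when the
    model graph's edge threshold sits above the loosest stability
    threshold, which would make all looser neighborhoods coincide);
    influences are always computed on ``graph``.
    """
    if neighbor_graph is None:
        neighbor_graph = graph
    if neighbor_graph.labels is None:
        raise ValueError("graph has no node labels")
    anchor_class = int(neighbor_graph.labels[anchor])
    loosest = min(thresholds)
    if neighborhood(neighbor_graph, anchor, loosest,
                    same_class_as=anchor_class).size == 0:
        warnings.warn("anchor has no same-class neighbor at the loosest "
                      "threshold; empty report")
        empty = pd.DataFrame(np.zeros((len(thresholds), len(FEATURES))),
                             index=list(thresholds), columns=list(FEATURES))
        return StabilityReport(anchor, tuple(thresholds),
                               {e: np.array([], dtype=int) for e in thresholds},
                               empty)

    influence_cache: dict[int, np.ndarray] = {}

    def node_influence(i: int) -> np.ndarray:
        if i not in influence_cache:
            infl = feature_influences(i, model, graph, X)
            y_own = int(np.argmax(
                node_class_probs_for_rows(model, X, graph, i, X[i][None, :])[0]))
            vec = infl[CLASSES[y_own]]
            if normalized:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    vec = normalize_influences(vec)
            influence_cache[i] = np.asarray(vec, dtype=float)
        return influence_cache[i]

    rows = []
    nbr_sets = {}
    for e in thresholds:
        nbrs = neighborhood(neighbor_graph, anchor, e, same_class_as=anchor_class)
        nbr_sets[e] = nbrs
        members = np.concatenate([[anchor], nbrs])
        vecs = np.vstack([node_influence(int(i)) for i in members])
        rows.append(np.abs(vecs.max(axis=0) - vecs.min(axis=0)))
    dist = pd.DataFrame(rows, index=list(thresholds), columns=list(FEATURES))
    if rescale_per_feature:
        peak = dist.max(axis=0).replace(0.0, 1.0)
        dist = dist / peak
    return StabilityReport(anchor, tuple(thresholds), nbr_sets, dist)


# ---------------------------------------------------------------------
# Shapley values
# ---------------------------------------------------------------------

def _shapley_exact_game(value_fn, k: int) -> np.ndarray:
    """Exact Shapley values of a set function over k players.

    ``value_fn(masks)`` maps a (B, k) boolean coalition matrix to (B,)
    values; evaluated once per distinct coalition.
    """
    n_sub = 1 << k
    masks = ((np.arange(n_sub)[:, None] >> np.arange(k)) & 1).astype(bool)
    values = np.asarray(value_fn(masks), dtype=float)
    phi = np.zeros(k)
    fact = [math.factorial(i) for i in range(k + 1)]
    sizes = masks.sum(axis=1)
    for i in range(k):
        without_i = ~masks[:, i]
        idx = np.flatnonzero(without_i)
        s = sizes[idx]
        weight = np.array([fact[si] * fact[k - si - 1] / fact[k] for si in s])
        with_i = idx | (1 << i)
        phi[i] = np.sum(weight * (values[with_i] - values[idx]))
    return phi


def shapley_values(node: int, model: GCNModel, graph: PopulationGraph,
                   X: np.ndarray, background: np.ndarray,
                   mode: str = "sampled", n_perm: int = 2000,
                   seed: int = 0, target_class: int | None = None) -> np.ndarray:
    """Shapley attribution of p(y*|x) over the node's features.

    Features outside a coalition take values from training-background
    rows.  ``exact`` enumerates all coalitions (refused above 20
    features), averaging the value function over every background row;
    ``sampled`` pairs each of ``n_perm`` random feature permutations
    with one random background row and accumulates marginal
    contributions.  Both are deterministic for a fixed seed.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise ValueError("background must be non-empty")
    k = X.shape[1]
    x = X[node]
    if target_class is None:
        base = node_class_probs_for_rows(model, X, graph, node, x[None, :])[0]
        target_class = int(np.argmax(base))

    def probs_for(rows: np.ndarray) -> np.ndarray:
        out = np.empty(len(rows))
        chunk = 4096
        for s in range(0, len(rows), chunk):
            out[s:s + chunk] = node_class_probs_for_rows(
                model, X, graph, node, rows[s:s + chunk])[:, target_class]
        return out

    if mode == "exact":
        if k > 20:
            raise ValueError("exact mode refused for more than 20 features")

        def value_fn(masks: np.ndarray) -> np.ndarray:
            # average over all background rows
            n_bg = len(background)
            vals = np.zeros(len(masks))
            for b in background:
                rows = np.where(masks, x[None, :], b[None, :])
                vals += probs_for(rows)
            return vals / n_bg

        return _shapley_exact_game(value_fn, k)

    if mode != "sampled":
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(k) for _ in range(n_perm)])
    bg_idx = rng.integers(0, len(background), size=n_perm)
    # Build every intermediate coalition row: n_perm * (k + 1) rows.
    rows = np.empty((n_perm * (k + 1), k))
    for p in range(n_perm):
        cur = background[bg_idx[p]].copy()
        base_at = p * (k + 1)
        rows[base_at] = cur
        for step, feat in enumerate(perms[p]):
            cur = cur.copy()
            cur[feat] = x[feat]
            rows[base_at + step + 1] = cur
    vals = probs_for(rows).reshape(n_perm, k + 1)
    marginals = np.diff(vals, axis=1)  # (n_perm, k) in permutation order
    phi = np.zeros(k)
    for p in range(n_perm):
        phi[perms[p]] += marginals[p]
    return phi / n_perm


# ---------------------------------------------------------------------
# Agreement between decomposition and Shapley
# ---------------------------------------------------------------------

@dataclass
class AgreementReport:
    per_class_r: dict[str, float]
    sign_agreement: dict[str, float]
    n_nodes: dict[str, int]
    pooled: pd.DataFrame  # columns: node, class, feature, decomposition, shapley


def method_agreement(nodes: np.ndarray, model: GCNModel,
                     graph: PopulationGraph, X: np.ndarray,
                     background: np.ndarray, mode: str = "sampled",
                     n_perm: int = 2000, seed: int = 0,
                     per_node_normalize: bool = True) -> AgreementReport:
    """Pearson correlation per predicted class between decomposition
    influences and Shapley attributions, pooled over (feature, node)
    pairs, plus the sign-agreement rate.

    By default both methods' vectors are scaled per node to mean
    absolute magnitude 1 before pooling — the scale the explanations are
    presented on.  Without it, pooled r mostly reflects *magnitude*
    heterogeneity across nodes (confidently classified nodes have
    near-zero influences under both methods) rather than whether the
    methods agree on which features matter; per-node agreement is the
    quantity of interest.  Pooled r remains invariant to any positive
    rescaling of either method's vectors.
    """
    records = []
    for node in np.asarray(nodes, dtype=int):
        base = node_class_probs_for_rows(model, X, graph, node, X[node][None, :])[0]
        y_star = int(np.argmax(base))
        dec = np.asarray(
            feature_influences(node, model, graph, X)[CLASSES[y_star]], dtype=float)
        shap = shapley_values(node, model, graph, X, background, mode=mode,
                              n_perm=n_perm, seed=seed + node,
                              target_class=y_star)
        if per_node_normalize:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dec = np.asarray(normalize_influences(dec), dtype=float)
                shap = np.asarray(normalize_influences(shap), dtype=float)
        for j, f in enumerate(FEATURES):
            records.append({"node": node, "class": CLASSES[y_star],
                            "feature": f, "decomposition": float(dec[j]),
                            "shapley": float(shap[j])})
    pooled = pd.DataFrame(records)
    per_class_r, signs, counts = {}, {}, {}
    for c in CLASSES:
        sub = pooled[pooled["class"] == c]
        counts[c] = sub["node"].nunique()
        if counts[c] < 2:
            per_class_r[c] = float("nan")
            signs[c] = float("nan")
            continue
        d, s = sub["decomposition"].to_numpy(), sub["shapley"].to_numpy()
        if np.ptp(d) == 0 or np.ptp(s) == 0:
            warnings.warn(f"constant attribution vector for class {c}; "
                          "correlation undefined")
            per_class_r[c] = float("nan")
        else:
            per_class_r[c] = float(sstats.pearsonr(d, s).statistic)
        nz = (d != 0) | (s != 0)
        signs[c] = float(np.mean(np.sign(d[nz]) == np.sign(s[nz]))) if nz.any() \
            else float("nan")
    return AgreementReport(per_class_r, signs, counts, pooled)


def select_test_nodes(model: GCNModel, X: np.ndarray, graph: PopulationGraph,
                      split, per_class: int = 50,
                      seed: int = 0) -> np.ndarray:
    """Up to ``per_class`` test-partition nodes per *predicted* class,
    sampled reproducibly."""
    test_idx = np.flatnonzero(split.mask("test") if hasattr(split, "mask")
                              else np.asarray(split["test"]))
    pred = predict(model, X, graph)
    rng = np.random.default_rng(seed)
    chosen = []
    for c in range(len(CLASSES)):
        pool = test_idx[pred[test_idx] == c]
        if len(pool) > per_class:
            pool = rng.choice(pool, size=per_class, replace=False)
        chosen.append(np.sort(pool))
    return np.concatenate(chosen)


# ---------------------------------------------------------------------
# Modality ablation
# ---------------------------------------------------------------------

@dataclass
class AblationReport:
    table: pd.DataFrame      # mean metrics per subset (Table-style layout)
    per_seed: pd.DataFrame   # every (subset, seed) run

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def modality_ablation(subsets: list[str], table: pd.DataFrame,
                      seeds: list[int],
                      config: GCNConfig | None = None,
                      edge_threshold: float | None = None) -> AblationReport:
    """Retrain the classifier on modality subsets (e.g. ``"D+CT+NT"``).

    Features of removed groups are dropped from X.  The graph still
    uses the cognitive measures; when the cognitive group itself is
    removed the graph falls back to all retained features (logged
    loudly via a warning).
    """
    from .popgraph import DEFAULT_EDGE_THRESHOLD, build_graph_from_table
    from .preprocess import label_codes, split_dataset, standardize

    if edge_threshold is None:
        edge_threshold = DEFAULT_EDGE_THRESHOLD
    rows = []
    for subset in subsets:
        groups = resolve_groups(subset)
        feats = [f for g in groups for f in GROUPS[g]]
        if not feats:
            raise ValueError(f"subset {subset!r} removes all features")
        for seed in seeds:
            split = split_dataset(table, seed=seed)
            std, _ = standardize(table, split)
            if "cognitive" in groups:
                graph = build_graph_from_table(std, edge_threshold=edge_threshold)
            else:
                warnings.warn(
                    f"subset {subset!r} drops the graph-defining cognitive "
                    "measures; graph rebuilt from all retained features")
                graph = build_graph_from_table(std, measures=tuple(feats),
                                               edge_threshold=edge_threshold)
            X = std[feats].to_numpy(dtype=float)
            y = label_codes(std)
            cfg = GCNConfig(in_dim=X.shape[1]) if config is None else \
                GCNConfig(**{**config.__dict__,
                             "hidden_dims": tuple(config.hidden_dims),
                             "in_dim": X.shape[1]})
            result = train(X, graph, y, split, cfg, seed=seed)
            test_mask = split.mask("test")
            pred = predict(result.model, X, graph)
            metrics = evaluate_metrics(y[test_mask], pred[test_mask])
            row = {"subset": subset, "seed": seed,
                   "mcf": metrics["mcf"], "mca": metrics["mca"]}
            for c in CLASSES:
                row[f"precision_{c}"] = metrics["precision"][c]
                row[f"recall_{c}"] = metrics["recall"][c]
                row[f"f1_{c}"] = metrics["f1"][c]
            rows.append(row)
    per_seed = pd.DataFrame(rows)
    mean_table = (per_seed.drop(columns="seed")
                  .groupby("subset", sort=False).mean().reset_index())
    return AblationReport(table=mean_table, per_seed=per_seed)
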