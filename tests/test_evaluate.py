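"""Evaluation-suite tests: Shapley oracles (closed forms, efficiency,
sampled-vs-exact convergence), stability tables, agreement reports and
modality ablation."""

import warnings

import numpy as np
import pytest

from popgraphx.evaluate import (
    DEFAULT_THRESHOLDS,
    _shapley_exact_game,
    method_agreement,
    modality_ablation,
    select_test_nodes,
    shapley_values,
    stability_table,
)
from popgraphx.features import CLASSES, FEATURES
from popgraphx.gcn import GCNConfig, init_model, node_class_probs_for_rows, predict
from popgraphx.popgraph import PopulationGraph, build_graph_from_table


# ------------------------------------------------------------- Shapley

def test_exact_shapley_additive_game_closed_form(rng):
    """For v(S) = sum_{i in S} a_i the Shapley value is exactly a_i."""
    a = rng.normal(size=6)

    def value_fn(masks):
        return masks @ a

    assert np.allclose(_shapley_exact_game(value_fn, 6), a, atol=1e-12)


def test_exact_shapley_interaction_game_hand_case():
    """Two-player game v({}) = 0, v({0}) = 1, v({1}) = 2, v({0,1}) = 6:
    phi_0 = (1 + 4)/2 = 2.5, phi_1 = (2 + 5)/2 = 3.5."""
    table = {(False, False): 0.0, (True, False): 1.0,
             (False, True): 2.0, (True, True): 6.0}

    def value_fn(masks):
        return np.array([table[(bool(m[0]), bool(m[1]))] for m in masks])

    phi = _shapley_exact_game(value_fn, 2)
    assert np.allclose(phi, [2.5, 3.5])
    # efficiency: allocations sum to v(full) - v(empty)
    assert phi.sum() == pytest.approx(6.0)


def _toy_model_and_graph(rng, n=5, d=4):
    A = rng.random((n, n))
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 0.0)
    g = PopulationGraph(A=A, labels=rng.integers(0, 3, size=n))
    model = init_model(GCNConfig(in_dim=d, hidden_dims=(8,)), seed=9)
    model.trained = True
    X = rng.normal(size=(n, d))
    return model, g, X


def test_shapley_efficiency_identity_exact_mode(rng):
    model, g, X = _toy_model_and_graph(rng)
    node = 2
    background = X[:3]
    base = node_class_probs_for_rows(model, X, g, node, X[node][None, :])[0]
    y_star = int(np.argmax(base))
    phi = shapley_values(node, model, g, X, background, mode="exact",
                         target_class=y_star)
    bg_vals = node_class_probs_for_rows(model, X, g, node,
                                        background)[:, y_star]
    assert phi.sum() == pytest.approx(base[y_star] - bg_vals.mean(), abs=1e-10)


def test_sampled_shapley_converges_to_exact(rng):
    """On a 4-feature toy with a single background row the sampled
    estimator reproduces exact enumeration."""
    model, g, X = _toy_model_and_graph(rng, n=5, d=4)
    node = 1
    background = X[3][None, :]
    exact = shapley_values(node, model, g, X, background, mode="exact",
                           target_class=0)
    sampled = shapley_values(node, model, g, X, background, mode="sampled",
                             n_perm=3000, seed=4, target_class=0)
    assert np.allclose(sampled, exact, atol=0.02)
    assert np.corrcoef(sampled, exact)[0, 1] > 0.99


def test_sampled_shapley_deterministic_per_seed(rng):
    model, g, X = _toy_model_and_graph(rng)
    a = shapley_values(0, model, g, X, X[1:3], n_perm=50, seed=5)
    b = shapley_values(0, model, g, X, X[1:3], n_perm=50, seed=5)
    c = shapley_values(0, model, g, X, X[1:3], n_perm=50, seed=6)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_shapley_input_validation(rng):
    model, g, X = _toy_model_and_graph(rng, n=4, d=21)
    with pytest.raises(ValueError, match="refused"):
        shapley_values(0, model, g, X, X[:2], mode="exact")
    model2, g2, X2 = _toy_model_and_graph(rng)
    with pytest.raises(ValueError, match="non-empty"):
        shapley_values(0, model2, g2, X2, np.empty((0, 4)))
    with pytest.raises(ValueError, match="unknown mode"):
        shapley_values(0, model2, g2, X2, X2[:2], mode="banana")


# ------------------------------------------------------------- stability

def test_stability_table_shape_and_nesting(small_pipeline):
    res = small_pipeline
    nbr_graph = build_graph_from_table(res.standardized,
                                       edge_threshold=min(DEFAULT_THRESHOLDS))
    anchor = int(np.argmax((nbr_graph.A > 0).sum(axis=1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = stability_table(anchor, res.graph, res.model, res.X,
                              neighbor_graph=nbr_graph)
    assert rep.distances.shape == (len(DEFAULT_THRESHOLDS), 13)
    assert list(rep.distances.columns) == list(FEATURES)
    assert (rep.distances.to_numpy() >= 0).all()
    # looser thresholds include every tighter neighborhood
    sets = [set(rep.neighbor_sets[e]) for e in DEFAULT_THRESHOLDS]
    for tight, loose in zip(sets, sets[1:]):
        assert tight <= loose


def test_stability_table_isolated_anchor_warns(small_pipeline):
    res = small_pipeline
    iso = PopulationGraph(A=np.zeros_like(res.graph.A),
                          labels=res.graph.labels)
    with pytest.warns(UserWarning, match="no same-class neighbor"):
        rep = stability_table(3, res.graph, res.model, res.X,
                              neighbor_graph=iso)
    assert np.allclose(rep.distances.to_numpy(), 0.0)


def test_stability_report_csv(tmp_path, small_pipeline):
    res = small_pipeline
    anchor = int(np.argmax((res.graph.A > 0).sum(axis=1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = stability_table(anchor, res.graph, res.model, res.X,
                              thresholds=(0.97, 0.95))
    rep.to_csv(tmp_path / "stab.csv")
    assert (tmp_path / "stab.csv").read_text().count("\n") == 3


# ------------------------------------------------------------- agreement

def test_method_agreement_structure_and_range(small_pipeline):
    res = small_pipeline
    nodes = select_test_nodes(res.model, res.X, res.graph, res.split,
                              per_class=3, seed=0)
    background = res.X[res.split.mask("train")][:20]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = method_agreement(nodes, res.model, res.graph, res.X,
                               background, n_perm=200, seed=0)
    assert set(rep.per_class_r) == set(CLASSES)
    for c in CLASSES:
        if rep.n_nodes[c] >= 2:
            assert -1.0 <= rep.per_class_r[c] <= 1.0
            assert 0.0 <= rep.sign_agreement[c] <= 1.0
    assert len(rep.pooled) == 13 * len(nodes)
    assert set(rep.pooled.columns) == {"node", "class", "feature",
                                       "decomposition", "shapley"}


def test_method_agreement_rescaling_invariance(small_pipeline):
    """Pooled r is invariant to positive rescaling of either method's
    per-node vectors — guaranteed by construction via the per-node
    normalization, asserted here on the pooled pairs."""
    res = small_pipeline
    nodes = select_test_nodes(res.model, res.X, res.graph, res.split,
                              per_class=2, seed=1)
    background = res.X[res.split.mask("train")][:10]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = method_agreement(nodes, res.model, res.graph, res.X,
                               background, n_perm=100, seed=0)
    for _, grp in rep.pooled.groupby("node"):
        assert np.abs(grp["decomposition"]).mean() == pytest.approx(1.0, abs=1e-9)
        assert np.abs(grp["shapley"]).mean() == pytest.approx(1.0, abs=1e-9)


def test_select_test_nodes(small_pipeline):
    res = small_pipeline
    nodes = select_test_nodes(res.model, res.X, res.graph, res.split,
                              per_class=2, seed=0)
    test_idx = set(np.flatnonzero(res.split.mask("test")))
    assert set(nodes) <= test_idx
    pred = predict(res.model, res.X, res.graph)
    for c in range(3):
        assert np.sum(pred[nodes] == c) <= 2
    again = select_test_nodes(res.model, res.X, res.graph, res.split,
                              per_class=2, seed=0)
    assert np.array_equal(nodes, again)


# ------------------------------------------------------------- ablation

def test_modality_ablation_runs_and_reports(small_cohort):
    from popgraphx.preprocess import clean_features
    cleaned = clean_features(small_cohort)
    rep = modality_ablation(["D+MRI+CT+NT+BM", "D+CT+NT"], cleaned, seeds=[1])
    assert list(rep.table["subset"]) == ["D+MRI+CT+NT+BM", "D+CT+NT"]
    assert {"mcf", "mca"} <= set(rep.table.columns)
    assert len(rep.per_seed) == 2
    assert (rep.per_seed["mca"] > 0).all()


def test_modality_ablation_warns_without_cognitive(small_cohort):
    from popgraphx.preprocess import clean_features
    cleaned = clean_features(small_cohort)
    with pytest.warns(UserWarning, match="cognitive"):
        rep = modality_ablation(["D+NT"], cleaned, seeds=[1])
    assert len(rep.per_seed) == 1


def test_modality_ablation_rejects_unknown_group(small_cohort):
    with pytest.raises(KeyError, match="unknown modality"):
        modality_ablation(["D+XX"], small_cohort, seeds=[1])
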