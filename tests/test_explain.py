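"""Explanation tests: conservation, occlusion identities, normalization,
discretization, reference deviations and text rendering."""

import json
import warnings

import numpy as np
import pandas as pd
import pytest

from popgraphx.explain import (
    discretize_feature,
    edge_class_influences,
    explain_node,
    feature_influences,
    group_influences,
    neighbor_class_profile,
    normalize_influences,
    pooled_stats,
    predicted_and_runner_up,
    reference_deviation,
    render_text,
)
from popgraphx.features import CLASSES, FEATURES, GROUPS
from popgraphx.gcn import MaskSpec, forward, init_model


def test_feature_influence_conservation(small_pipeline, rng):
    """Class-wise variations of any occlusion sum to zero: probability
    lost by one class is gained by the others."""
    res = small_pipeline
    nodes = rng.choice(res.graph.n_nodes, size=12, replace=False)
    for node in nodes:
        infl = feature_influences(int(node), res.model, res.graph, res.X)
        assert np.allclose(infl.sum(axis=1), 0.0, atol=1e-9)


def test_group_and_edge_influence_conservation(small_pipeline):
    res = small_pipeline
    for node in (0, 61, 150):
        g = group_influences(node, res.model, res.graph, res.X)
        e = edge_class_influences(node, res.model, res.graph, res.X)
        assert np.allclose(g.sum(axis=1), 0.0, atol=1e-9)
        assert np.allclose(e.sum(axis=1), 0.0, atol=1e-9)
        assert list(g.index) == list(GROUPS)


def test_group_influence_consistent_with_feature_cells(small_pipeline):
    """Occluding a whole group equals masking each member cell in one
    full forward pass (fast path vs. generic mask machinery)."""
    res = small_pipeline
    node = 5
    base = forward(res.model, res.X, res.graph)[node]
    grp = group_influences(node, res.model, res.graph, res.X)
    for gname, members in GROUPS.items():
        cells = [(node, FEATURES.index(f)) for f in members]
        occ = forward(res.model, res.X, res.graph,
                      MaskSpec(feature_cells=cells))[node]
        assert np.allclose(grp.loc[gname].to_numpy(), base - occ, atol=1e-10)


def test_single_feature_group_identity(small_pipeline):
    """A 'group' holding one feature reproduces the per-feature variation
    exactly (the group operator reduces to the feature operator)."""
    res = small_pipeline
    node = 23
    base = forward(res.model, res.X, res.graph)[node]
    feats = feature_influences(node, res.model, res.graph, res.X)
    for j, f in enumerate(FEATURES):
        occ = forward(res.model, res.X, res.graph,
                      MaskSpec(feature_cells=[(node, j)]))[node]
        assert np.allclose(feats.loc[f].to_numpy(), base - occ, atol=1e-10)


def test_predicted_and_runner_up():
    assert predicted_and_runner_up(np.array([0.7, 0.2, 0.1])) == (0, 1)
    assert predicted_and_runner_up(np.array([0.1, 0.2, 0.7])) == (2, 1)
    # tie between NC and AD behind MCI resolves to the adjacent class
    y, r = predicted_and_runner_up(np.array([0.25, 0.5, 0.25]))
    assert y == 1 and r in (0, 2)


def test_normalize_influences_hand_case():
    v = pd.Series([0.02, -0.04, 0.06], index=["a", "b", "c"])
    out = normalize_influences(v)
    assert np.allclose(out.to_numpy(), [0.5, -1.0, 1.5])
    assert np.abs(out).mean() == pytest.approx(1.0)
    with pytest.warns(UserWarning, match="zero"):
        same = normalize_influences(np.zeros(3))
    assert np.allclose(same, 0.0)


def test_discretize_clinical_cutoffs():
    assert discretize_feature("gds", 7.1) == "normal"
    assert discretize_feature("gds", 15.0) == "mild depressive"
    assert discretize_feature("gds", 25.0) == "severe depressive"
    assert discretize_feature("mmse", 22.4) == "mild dementia"
    assert discretize_feature("mmse", 29.0) == "normal cognition"
    assert discretize_feature("mmse", 15.0) == "moderate dementia"
    assert discretize_feature("mmse", 5.0) == "severe dementia"
    assert discretize_feature("gender", 2.0) == "female"
    assert discretize_feature("gender", 1.0) == "male"
    assert discretize_feature("abeta", 1.0) == "positive"
    assert discretize_feature("tau", -1.0) == "negative"


def test_discretize_sd_bins_and_orientation():
    pooled = {"phs": (0.0, 1.0), "mct": (2.7, 0.1)}
    assert discretize_feature("phs", 0.0, pooled) == "nominal"
    assert discretize_feature("phs", 1.2, pooled) == "high"
    assert discretize_feature("phs", 2.0, pooled) == "very high"
    assert discretize_feature("phs", -2.0, pooled) == "very low"
    # lower-is-worse features flip: a thin cortex reads as high severity
    assert discretize_feature("mct", 2.5, pooled) == "very high"
    assert discretize_feature("mct", 2.9, pooled) == "very low"
    with pytest.raises(KeyError):
        discretize_feature("nope", 1.0, pooled)
    with pytest.raises(ValueError, match="pooled"):
        discretize_feature("phs", 1.0)


def test_reference_deviation(small_pipeline):
    table = small_pipeline.table
    record = table[table["label"] == "AD"].iloc[0]
    dev = reference_deviation(record, table)
    ref = table[(table["label"] == "NC")
                & (table["gender"] == record["gender"])
                & ((table["age"] - record["age"]).abs() <= 5.0)]
    assert dev["mmse"] == pytest.approx(record["mmse"] - ref["mmse"].mean())
    # an empty stratum widens the age window with a warning
    young = record.copy()
    young["age"] = table.loc[table["label"] == "NC", "age"].min() - 12.0
    with pytest.warns(UserWarning, match="widening"):
        dev2 = reference_deviation(young, table)
    assert np.isfinite(dev2["mmse"])


def test_neighbor_class_profile(small_pipeline):
    res = small_pipeline
    node = int(np.argmax((res.graph.A > 0).sum(axis=1)))
    prof = neighbor_class_profile(node, res.graph)
    assert set(prof) == set(CLASSES)
    assert sum(prof.values()) == pytest.approx(100.0)
    weighted = neighbor_class_profile(node, res.graph, weighted=True)
    assert sum(weighted.values()) == pytest.approx(100.0)


def test_explain_node_bundle_and_text(small_pipeline):
    res = small_pipeline
    node = 61  # an MCI-labeled subject in the small cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = explain_node(node, res.model, res.graph, res.X,
                              display_table=res.table)
    assert bundle.probabilities.sum() == pytest.approx(1.0)
    assert bundle.predicted_class in CLASSES
    assert bundle.counterfactual_class in CLASSES
    assert bundle.predicted_class != bundle.counterfactual_class
    assert bundle.feature_influences.shape == (13, 3)
    assert bundle.group_influences.shape == (5, 3)
    assert bundle.edge_influences.shape == (3, 3)
    # every rendered sentence names its direction and the predicted class
    for s in bundle.sentences:
        assert ("supports" in s) or ("opposes" in s)
        assert bundle.predicted_class in s
    # sentences cover exactly the features above the influence floor
    n_above = int((bundle.normalized_factual.abs() > 0.25).sum())
    assert len(bundle.sentences) == n_above
    payload = json.loads(bundle.to_json())
    assert payload["node"] == node
    assert set(payload["probabilities"]) == set(CLASSES)


def test_render_text_ordering_and_floor():
    bundle_probs = np.array([0.6, 0.3, 0.1])
    from popgraphx.explain import ExplanationBundle
    fi = pd.DataFrame(np.zeros((13, 3)), index=list(FEATURES),
                      columns=list(CLASSES))
    bundle = ExplanationBundle(
        node=0, probabilities=bundle_probs, predicted_class="NC",
        counterfactual_class="MCI", feature_influences=fi,
        group_influences=fi.iloc[:5], edge_influences=fi.iloc[:3])
    norm = pd.Series(np.zeros(13), index=list(FEATURES))
    norm["mmse"], norm["tau"], norm["age"] = 2.0, -1.0, 0.1
    bundle.normalized_factual = norm
    sentences = render_text(bundle, {"mmse": "normal cognition",
                                     "tau": "negative"})
    assert len(sentences) == 2  # age is under the 0.25 floor
    assert sentences[0].startswith("MMSE") and "supports NC" in sentences[0]
    assert sentences[1].startswith("TAU") and "opposes NC" in sentences[1]


def test_untrained_model_refused(small_pipeline):
    res = small_pipeline
    fresh = init_model(res.model.config, seed=0)
    with pytest.raises(ValueError, match="not trained"):
        feature_influences(0, fresh, res.graph, res.X)
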