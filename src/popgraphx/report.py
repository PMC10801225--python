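"""Figure generation for explanation reports.

Figures mirror the package's JSON artifacts and never encode anything
absent from them: a paired horizontal bar chart (factual vs
counterfactual influences), a modality pie chart, and a
neighbor-class-percentage chart.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .explain import ExplanationBundle
from .features import CLASSES, FEATURES


def paired_influence_chart(bundle: ExplanationBundle, path) -> None:
    """Factual (left) and counterfactual (right) normalized influences."""
    fact = bundle.normalized_factual
    counter = bundle.normalized_counterfactual
    y = np.arange(len(FEATURES))
    fig, axes = plt.subplots(1, 2, figsize=(9, 5), sharey=True)
    for ax, vec, title in (
        (axes[0], fact, f"factual: {bundle.predicted_class}"),
        (axes[1], counter, f"counterfactual: {bundle.counterfactual_class}"),
    ):
        vals = np.asarray(vec, dtype=float)
        colors = np.where(vals >= 0, "tab:green", "tab:red")
        ax.barh(y, vals, color=colors)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_title(title)
    axes[0].set_yticks(y, [f.upper() for f in FEATURES])
    axes[0].invert_yaxis()
    fig.suptitle(f"node {bundle.node}: influence per feature (normalized)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def group_pie_chart(bundle: ExplanationBundle, path) -> None:
    """Share of supporting modality influences for the predicted class."""
    vals = bundle.group_influences[bundle.predicted_class]
    pos = vals[vals > 0]
    fig, ax = plt.subplots(figsize=(5, 5))
    if len(pos):
        ax.pie(pos, labels=list(pos.index), autopct="%.0f%%")
    else:
        ax.text(0.5, 0.5, "no supporting group", ha="center")
    ax.set_title(f"supporting modalities for {bundle.predicted_class}")
    fig.savefig(path)
    plt.close(fig)


def neighbor_profile_chart(bundle: ExplanationBundle, path) -> None:
    """Percentage of graph neighbors per diagnostic class."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(list(CLASSES), [bundle.neighbor_profile[c] for c in CLASSES],
           color=["tab:blue", "tab:orange", "tab:red"])
    ax.set_ylabel("% of connected neighbors")
    ax.set_title(f"node {bundle.node}: neighborhood composition")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_report(bundle: ExplanationBundle, out_dir) -> list[str]:
    """Write the three figures plus the JSON bundle; returns paths."""
    import os

    paths = []
    base = os.path.join(str(out_dir), f"node_{bundle.node}")
    json_path = base + "_bundle.json"
    with open(json_path, "w") as fh:
        fh.write(bundle.to_json())
    paths.append(json_path)
    for fn, suffix in ((paired_influence_chart, "_influences.svg"),
                       (group_pie_chart, "_groups.svg"),
                       (neighbor_profile_chart, "_neighbors.svg")):
        p = base + suffix
        fn(bundle, p)
        paths.append(p)
    return paths
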