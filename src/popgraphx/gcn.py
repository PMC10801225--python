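"""Semi-supervised spectral graph convolutional classifier.

The model stacks graph-convolution layers

    H_{l+1} = relu(A_tilde H_l W_l) [+ H_l when widths match]

over the renormalized adjacency, with a softmax head; training is
transductive: the forward pass runs over the whole graph while the
cross-entropy loss is computed on train-partition rows only.  Training
follows the published protocol — 100 epochs, Adam with learning rate
0.01, validation every 5 epochs, best-validation checkpoint.

Masked forward contract (used by the explanation module): occluded
feature cells are *omitted* from every weighted sum they enter (the
NaN-aware-summation semantics), which for a linear aggregation equals
zeroing their contribution — not zero-imputing the standardized value,
and with no renormalization of the remaining terms.  Occluded edge
groups zero the node's edges to one class in A, after which A_tilde is
recomputed (degrees change).

Everything is plain numpy: the forward, backward and Adam steps are
written out explicitly, which keeps runs bit-reproducible from a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .features import CLASSES
from .popgraph import PopulationGraph, normalize_adjacency


@dataclass
class GCNConfig:
    """Architecture and training hyperparameters (defaults = published
    protocol where one is printed)."""

    in_dim: int = 13
    hidden_dims: tuple[int, ...] = (32,)
    n_classes: int = 3
    learning_rate: float = 0.01
    epochs: int = 100
    val_every: int = 5
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    @property
    def layer_dims(self) -> tuple[int, ...]:
        return (self.in_dim, *self.hidden_dims, self.n_classes)


@dataclass
class GCNModel:
    """Layer weights plus the config and seed that produced them."""

    weights: list[np.ndarray]
    config: GCNConfig
    seed: int = 0
    trained: bool = False

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def copy(self) -> "GCNModel":
        return GCNModel([w.copy() for w in self.weights], self.config,
                        self.seed, self.trained)

    def save(self, path) -> None:
        payload = {
            "config": self.config.__dict__ | {"hidden_dims": list(self.config.hidden_dims)},
            "seed": self.seed,
            "trained": self.trained,
            "weights": [w.tolist() for w in self.weights],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "GCNModel":
        with open(path) as fh:
            d = json.load(fh)
        cfg_d = d["config"]
        cfg_d["hidden_dims"] = tuple(cfg_d["hidden_dims"])
        cfg = GCNConfig(**cfg_d)
        return cls([np.asarray(w, dtype=float) for w in d["weights"]],
                   cfg, d["seed"], d["trained"])


@dataclass
class MaskSpec:
    """Cells and edge groups to silence in a forward pass.

    ``feature_cells``: (node, feature-index) pairs whose values are
    omitted.  ``edge_classes``: (node, class-code) pairs; all edges from
    that node to nodes of that class are zeroed before renormalization.
    An empty MaskSpec is the identity.
    """

    feature_cells: list[tuple[int, int]] = field(default_factory=list)
    edge_classes: list[tuple[int, int]] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not self.feature_cells and not self.edge_classes

    def validate(self, n_nodes: int, n_features: int) -> None:
        for i, j in self.feature_cells:
            if not (0 <= i < n_nodes and 0 <= j < n_features):
                raise IndexError(f"mask cell ({i}, {j}) out of range")
        for i, _c in self.edge_classes:
            if not 0 <= i < n_nodes:
                raise IndexError(f"mask edge group node {i} out of range")


def init_model(config: GCNConfig | None = None, seed: int = 0) -> GCNModel:
    """Glorot-uniform weight initialization from a fixed seed."""
    config = config or GCNConfig()
    rng = np.random.default_rng(seed)
    dims = config.layer_dims
    weights = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (d_in + d_out))
        weights.append(rng.uniform(-limit, limit, size=(d_in, d_out)))
    return GCNModel(weights=weights, config=config, seed=seed)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _masked_inputs(X: np.ndarray, graph: PopulationGraph,
                   mask: MaskSpec | None) -> tuple[np.ndarray, np.ndarray]:
    """Apply a MaskSpec, returning the effective (X, A_tilde)."""
    A_tilde = graph.A_tilde
    if mask is None or mask.is_empty():
        return X, A_tilde
    mask.validate(graph.n_nodes, X.shape[1])
    Xm = X
    if mask.feature_cells:
        Xm = X.copy()
        rows, cols = zip(*mask.feature_cells)
        Xm[list(rows), list(cols)] = 0.0  # omitted-from-sum semantics
    if mask.edge_classes:
        if graph.labels is None:
            raise ValueError("edge-class masking needs node labels on the graph")
        A = graph.A.copy()
        for node, c in mask.edge_classes:
            sel = graph.labels == c
            sel[node] = False
            A[node, sel] = 0.0
            A[sel, node] = 0.0
        A_tilde = normalize_adjacency(A)
    return Xm, A_tilde


def forward(model: GCNModel, X: np.ndarray, graph: PopulationGraph,
            mask: MaskSpec | None = None) -> np.ndarray:
    """Per-node class probabilities (rows sum to 1)."""
    if X.shape[1] != model.weights[0].shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} features; model expects {model.weights[0].shape[0]}")
    if X.shape[0] != graph.n_nodes:
        raise ValueError("X and graph disagree on node count")
    Xm, A_tilde = _masked_inputs(X, graph, mask)
    H = Xm
    last = model.n_layers - 1
    for l, W in enumerate(model.weights):
        Z = A_tilde @ H @ W
        if l < last:
            Z_act = np.maximum(Z, 0.0)
        else:
            Z_act = Z
        if Z_act.shape == H.shape:
            Z_act = Z_act + H  # residual only at matching widths
        H = Z_act
    return _softmax(H)


def node_class_probs_for_rows(model: GCNModel, X: np.ndarray,
                              graph: PopulationGraph, node: int,
                              rows: np.ndarray) -> np.ndarray:
    """Probabilities of one node under many variants of its own feature row.

    ``rows`` is (B, d); returns (B, C).  Exactly equivalent to running
    :func:`forward` B times with ``X[node] = rows[b]``, but for the
    default two-layer architecture it exploits that only the interest
    node's row varies: the hidden response of each neighbor is piecewise
    linear in each variant's projected activation, so per hidden unit
    the weighted relu sum is evaluated with sorted breakpoints and
    prefix sums instead of a full graph forward.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    dims_change = all(
        w.shape[0] != w.shape[1] for w in model.weights)  # no residual fires
    if model.n_layers != 2 or not dims_change:
        out = np.empty((rows.shape[0], model.config.n_classes))
        Xv = X.copy()
        for b, r in enumerate(rows):
            Xv[node] = r
            out[b] = forward(model, Xv, graph)[node]
        return out

    W0, W1 = model.weights
    A_tilde = graph.A_tilde
    col = A_tilde[:, node]
    nbr = np.flatnonzero(col)  # includes the node itself (self-loop)
    c = col[nbr]
    w_out = A_tilde[node, nbr]
    X0 = X.copy()
    X0[node, :] = 0.0
    Zb = (A_tilde[nbr] @ X0) @ W0  # (m, h): neighbor pre-activations
    # minus the interest node's contribution

    # Per hidden unit: g(alpha) = sum_j w_j relu(Zb_j + c_j alpha) is
    # piecewise linear with breakpoints alpha_j = -Zb_j / c_j (c_j > 0).
    alpha = -Zb / c[:, None]                      # (m, h)
    order = np.argsort(alpha, axis=0)
    alpha_sorted = np.take_along_axis(alpha, order, axis=0)
    wz = np.take_along_axis(w_out[:, None] * Zb, order, axis=0)
    wc = np.take_along_axis((w_out * c)[:, None] * np.ones_like(Zb), order, axis=0)
    m, h = Zb.shape
    P1 = np.vstack([np.zeros((1, h)), np.cumsum(wz, axis=0)])
    P2 = np.vstack([np.zeros((1, h)), np.cumsum(wc, axis=0)])

    P_rows = rows @ W0  # (B, h): each variant's projected activation
    B = P_rows.shape[0]
    S = np.empty((B, h))
    for u in range(h):
        pos = np.searchsorted(alpha_sorted[:, u], P_rows[:, u], side="left")
        S[:, u] = P1[pos, u] + P_rows[:, u] * P2[pos, u]
    return _softmax(S @ W1)


@dataclass
class TrainResult:
    model: GCNModel
    history: pd.DataFrame  # columns: epoch, loss, val_acc (NaN off-cadence)
    best_epoch: int
    best_val_acc: float


def train(X: np.ndarray, graph: PopulationGraph, labels: np.ndarray,
          split, config: GCNConfig | None = None, seed: int = 0) -> TrainResult:
    """Full-batch transductive training with hand-rolled Adam.

    ``split`` is a :class:`~popgraphx.preprocess.SplitAssignment` or a
    dict of boolean masks with keys ``train`` and ``validation``.
    Returns the checkpoint with the best validation accuracy among the
    every-``val_every``-epoch evaluations.
    """
    config = config or GCNConfig(in_dim=X.shape[1])
    if hasattr(split, "mask"):
        train_mask = split.mask("train")
        val_mask = split.mask("validation")
    else:
        train_mask = np.asarray(split["train"])
        val_mask = np.asarray(split["validation"])
    if not train_mask.any():
        raise ValueError("empty train partition")
    labels = np.asarray(labels, dtype=int)
    n, C = X.shape[0], config.n_classes
    Y = np.zeros((n, C))
    Y[np.arange(n), labels] = 1.0
    n_tr = int(train_mask.sum())

    model = init_model(config, seed=seed)
    W0, W1 = None, None
    if model.n_layers != 2:
        raise NotImplementedError("training implemented for 2-layer models")
    W0, W1 = model.weights
    A_tilde = graph.A_tilde
    AX = A_tilde @ X  # A_tilde and X are fixed during training

    m = [np.zeros_like(W0), np.zeros_like(W1)]
    v = [np.zeros_like(W0), np.zeros_like(W1)]
    b1, b2, eps, lr = (config.adam_beta1, config.adam_beta2,
                       config.adam_eps, config.learning_rate)

    best = model.copy()
    best_acc, best_epoch = -1.0, 0
    rows = []
    t = 0
    for epoch in range(1, config.epochs + 1):
        Z0 = AX @ W0
        H1 = np.maximum(Z0, 0.0)
        AH1 = A_tilde @ H1
        P = _softmax(AH1 @ W1)
        eps_p = 1e-12
        loss = -np.log(P[train_mask, labels[train_mask]] + eps_p).mean()

        dZ1 = (P - Y) * train_mask[:, None] / n_tr
        AdZ1 = A_tilde @ dZ1
        gW1 = AH1.T @ dZ1
        dH1 = AdZ1 @ W1.T
        dZ0 = dH1 * (Z0 > 0)
        gW0 = AX.T @ dZ0

        t += 1
        for k, (W, g) in enumerate(((W0, gW0), (W1, gW1))):
            m[k] = b1 * m[k] + (1 - b1) * g
            v[k] = b2 * v[k] + (1 - b2) * g * g
            m_hat = m[k] / (1 - b1 ** t)
            v_hat = v[k] / (1 - b2 ** t)
            W -= lr * m_hat / (np.sqrt(v_hat) + eps)

        val_acc = np.nan
        if epoch % config.val_every == 0 and val_mask.any():
            probs = forward(model, X, graph)
            pred = probs.argmax(axis=1)
            val_acc = float((pred[val_mask] == labels[val_mask]).mean())
            if val_acc > best_acc:
                best_acc, best_epoch = val_acc, epoch
                best = model.copy()
        rows.append({"epoch": epoch, "loss": float(loss), "val_acc": val_acc})

    if best_acc < 0:  # no validation rows: keep the final weights
        best, best_acc, best_epoch = model.copy(), np.nan, config.epochs
    best.trained = True
    return TrainResult(model=best, history=pd.DataFrame(rows),
                       best_epoch=best_epoch, best_val_acc=best_acc)


def predict(model: GCNModel, X: np.ndarray, graph: PopulationGraph) -> np.ndarray:
    """Predicted class codes for every node."""
    return forward(model, X, graph).argmax(axis=1)


def evaluate_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Per-class precision/recall/F1 (percent), macro-F1 (MCF), accuracy
    (MCA), and the confusion matrix (rows = true, columns = predicted,
    so precision reads down a column and recall across a row)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("labels and predictions differ in length")
    labels_idx = np.arange(len(CLASSES))
    import warnings as _warnings
    for c in labels_idx:
        if not np.any(y_true == c):
            _warnings.warn(f"class {CLASSES[c]} absent from labels; its F1 is 0")
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels_idx, zero_division=0)
    conf = _sk_confusion(y_true, y_pred, labels=labels_idx)
    return {
        "precision": {CLASSES[i]: 100 * prec[i] for i in labels_idx},
        "recall": {CLASSES[i]: 100 * rec[i] for i in labels_idx},
        "f1": {CLASSES[i]: 100 * f1[i] for i in labels_idx},
        "mcf": 100 * float(f1.mean()),
        "mca": 100 * float((y_true == y_pred).mean()),
        "confusion": conf,
    }
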