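"""Graph-convolutional analog of the antennal-lobe circuit.

The network has 17 nodes: 16 sensor nodes (one per gas sensor, carrying
that sensor's 8-dimensional feature vector) and one reward node.  All
sensor-sensor adjacency entries are 1; the reward node's edges are set
per training sample (+1 for rewarded odors, -1 for habituated ones) and 0
at test time.  Two graph-convolution layers

    H(l+1) = h(A . H(l) . W(l))

(h = ReLU by default, W1: 8 -> d1 features, W2: d1 -> 4) are followed by
a flatten and two fully connected layers producing the 2-class
rewarded-vs-habituated logits.  Training minimizes cross-entropy with
Adam (lr 0.01, 20 epochs); the forward/backward pass and the optimizer
are implemented directly in numpy.

The contrast-enhancement analysis treats layer 1 as the untrained circuit
and layer 2 as the trained one: per sensor node, the uniqueness index is
computed from layer-1 mean activations (rewarded vs habituated odors) and
the change in activity is the layer-2 minus layer-1 mean activation for
rewarded odors, regressed with the same OLS used for the biophysical
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import ContrastResult, contrast_regression, uniqueness_index

__all__ = ["GraphSpec", "GCNModel", "gcn_layer", "set_reward_edges",
           "train_gcn", "gcn_contrast_analysis", "relu"]

N_SENSORS = 16


def relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(x):
    return (x > 0.0).astype(float)


@dataclass
class GraphSpec:
    """Adjacency of the 16-sensor + 1-reward-node graph."""

    n_sensor_nodes: int = N_SENSORS
    adjacency: np.ndarray = None
    normalize: bool = False  # optional symmetric degree normalization

    def __post_init__(self):
        if self.adjacency is None:
            n = self.n_sensor_nodes + 1
            A = np.zeros((n, n))
            A[: self.n_sensor_nodes, : self.n_sensor_nodes] = 1.0
            # edges connect distinct sensors; no self-loops, so each node's
            # aggregation (sum - own value) keeps per-sensor identity
            np.fill_diagonal(A, 0.0)
            self.adjacency = A

    def effective_adjacency(self) -> np.ndarray:
        if not self.normalize:
            return self.adjacency
        deg = np.abs(self.adjacency).sum(axis=1)
        d = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
        return d[:, None] * self.adjacency * d[None, :]


def set_reward_edges(graph: GraphSpec, label: str) -> GraphSpec:
    """Return a copy with reward-node edges set for the sample's label.

    ``rewarded`` -> +1, ``habituated`` -> -1; ``test`` -> 0 (the reward
    node acts only through its edges and carries no supervision signal at
    test time).
    """
    values = {"rewarded": 1.0, "habituated": -1.0, "test": 0.0}
    if label not in values:
        raise ValueError(f"unknown label {label!r}")
    A = graph.adjacency.copy()
    r = graph.n_sensor_nodes
    A[r, :r] = values[label]
    A[:r, r] = values[label]
    A[r, r] = 0.0
    return GraphSpec(n_sensor_nodes=graph.n_sensor_nodes, adjacency=A,
                     normalize=graph.normalize)


def gcn_layer(H: np.ndarray, A: np.ndarray, W: np.ndarray, h=relu) -> np.ndarray:
    """One graph-convolution layer: h(A . H . W)."""
    H = np.asarray(H, dtype=float)
    A = np.asarray(A, dtype=float)
    W = np.asarray(W, dtype=float)
    if A.shape[1] != H.shape[0] or H.shape[1] != W.shape[0]:
        raise ValueError("shape mismatch in gcn_layer")
    return h(A @ H @ W)


@dataclass
class GCNModel:
    """Two graph-convolution layers plus a two-layer classification head."""

    n_features: int = 8
    d1: int = 8  # layer-1 output width (not printed; feature-preserving)
    d2: int = 4  # layer-2 output width
    fc_hidden: int = 64
    n_classes: int = 2
    n_nodes: int = N_SENSORS + 1
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.params:
            rng = np.random.default_rng(self.seed)

            def glorot(fan_in, fan_out):
                s = np.sqrt(6.0 / (fan_in + fan_out))
                return rng.uniform(-s, s, size=(fan_in, fan_out))

            flat = self.n_nodes * self.d2
            self.params = {
                "W1": glorot(self.n_features, self.d1),
                "W2": glorot(self.d1, self.d2),
                "W3": glorot(flat, self.fc_hidden),
                "b3": np.zeros(self.fc_hidden),
                "W4": glorot(self.fc_hidden, self.n_classes),
                "b4": np.zeros(self.n_classes),
            }

    # -- forward ----------------------------------------------------------
    def forward(self, X: np.ndarray, A: np.ndarray, cache: bool = False):
        """Logits for one sample (X: nodes x features incl. reward row)."""
        p = self.params
        Z1 = A @ X @ p["W1"]
        H1 = relu(Z1)
        Z2 = A @ H1 @ p["W2"]
        H2 = relu(Z2)
        f = H2.reshape(-1)
        Z3 = f @ p["W3"] + p["b3"]
        H3 = relu(Z3)
        logits = H3 @ p["W4"] + p["b4"]
        if cache:
            return logits, (X, A, Z1, H1, Z2, H2, f, Z3, H3)
        return logits

    def hidden_activations(self, X: np.ndarray, A: np.ndarray):
        """(H1, H2) node-level activations of the two conv layers."""
        p = self.params
        H1 = relu(A @ X @ p["W1"])
        H2 = relu(A @ H1 @ p["W2"])
        return H1, H2

    # -- backward ---------------------------------------------------------
    def _backward(self, cache, dlogits):
        p = self.params
        X, A, Z1, H1, Z2, H2, f, Z3, H3 = cache
        g = {}
        g["W4"] = np.outer(H3, dlogits)
        g["b4"] = dlogits
        dH3 = p["W4"] @ dlogits
        dZ3 = dH3 * _relu_grad(Z3)
        g["W3"] = np.outer(f, dZ3)
        g["b3"] = dZ3
        df = p["W3"] @ dZ3
        dH2 = df.reshape(H2.shape)
        dZ2 = dH2 * _relu_grad(Z2)
        g["W2"] = (A @ H1).T @ dZ2
        dH1 = A.T @ dZ2 @ p["W2"].T
        dZ1 = dH1 * _relu_grad(Z1)
        g["W1"] = (A @ X).T @ dZ1
        return g


def _features_to_node_matrix(row: np.ndarray, n_sensors: int, n_features: int):
    """One flat sample -> (n_sensors+1) x n_features with zero reward row."""
    X = np.zeros((n_sensors + 1, n_features))
    X[:n_sensors] = row.reshape(n_sensors, n_features)
    return X


def train_gcn(features: pd.DataFrame, labels: pd.DataFrame, seed: int = 0,
              lr: float = 0.01, epochs: int = 20, d1: int = 8,
              test_fraction: float = 0.2, normalize_adjacency: bool = False,
              reward_edge_dropout: float = 0.5):
    """Train the GCN on z-scored sensor features.

    ``features`` has one row per sample (n_sensors*n_features columns, as
    produced by the synthetic sensor generator after z-scoring); labels
    must contain a ``reward`` column with "rewarded"/"habituated".  The
    split is stratified 80/20.  Returns ``(model, info)`` with held-out
    accuracy, final loss, and the index arrays of the split.

    During training the reward node's edges carry the sample's label (+1
    rewarded, -1 habituated); at test time they are neutral (0).  Because
    a train-only label signal would otherwise be exploited as a shortcut
    that vanishes at test time, the reward edges are dropped (set to 0)
    for a random ``reward_edge_dropout`` fraction of training samples, so
    the sensor pathway must learn the task as well.
    """
    X_all = features.to_numpy(dtype=float)
    y_all = (labels["reward"].to_numpy() == "rewarded").astype(int)
    n = len(y_all)
    n_features = X_all.shape[1] // N_SENSORS
    rng = np.random.default_rng(seed)

    test_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(y_all == cls)
        k = max(1, int(round(test_fraction * len(idx))))
        test_idx.append(rng.permutation(idx)[:k])
    test_idx = np.sort(np.concatenate(test_idx))
    train_idx = np.setdiff1d(np.arange(n), test_idx)

    model = GCNModel(n_features=n_features, d1=d1, seed=seed)
    graph = GraphSpec(normalize=normalize_adjacency)
    A_by_label = {
        1: set_reward_edges(graph, "rewarded").effective_adjacency(),
        0: set_reward_edges(graph, "habituated").effective_adjacency(),
    }
    A_test = set_reward_edges(graph, "test").effective_adjacency()

    # Adam state
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(vv) for k, vv in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    loss = np.nan

    for _ in range(epochs):
        order = rng.permutation(train_idx)
        for i in order:
            Xi = _features_to_node_matrix(X_all[i], N_SENSORS, n_features)
            if rng.random() < reward_edge_dropout:
                Ai = A_test
            else:
                Ai = A_by_label[y_all[i]]
            logits, cache = model.forward(Xi, Ai, cache=True)
            if not np.all(np.isfinite(logits)):
                raise RuntimeError("non-finite training loss")
            z = logits - logits.max()
            p = np.exp(z) / np.exp(z).sum()
            loss = -np.log(max(p[y_all[i]], 1e-12))
            dlogits = p.copy()
            dlogits[y_all[i]] -= 1.0
            grads = model._backward(cache, dlogits)
            step += 1
            for k, gk in grads.items():
                m[k] = b1 * m[k] + (1 - b1) * gk
                v[k] = b2 * v[k] + (1 - b2) * gk * gk
                mhat = m[k] / (1 - b1 ** step)
                vhat = v[k] / (1 - b2 ** step)
                model.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def predict(idx):
        out = np.empty(len(idx), dtype=int)
        for j, i in enumerate(idx):
            Xi = _features_to_node_matrix(X_all[i], N_SENSORS, n_features)
            out[j] = int(np.argmax(model.forward(Xi, A_test)))
        return out

    acc = float(np.mean(predict(test_idx) == y_all[test_idx]))
    info = {"accuracy": acc, "final_loss": float(loss),
            "train_idx": train_idx, "test_idx": test_idx,
            "train_accuracy": float(np.mean(predict(train_idx) == y_all[train_idx]))}
    return model, info


def gcn_contrast_analysis(model: GCNModel, features: pd.DataFrame,
                          labels: pd.DataFrame,
                          normalize_adjacency: bool = False) -> ContrastResult:
    """Layer-wise contrast enhancement of the trained GCN.

    Per sensor node: UI from layer-1 mean activations (averaged over
    features and over samples of each reward group), change in activity =
    layer-2 minus layer-1 mean activation for rewarded samples; OLS of
    change on UI.  Nodes with zero layer-1 habituated activation are
    excluded (reported through the regression's unit count).
    """
    X_all = features.to_numpy(dtype=float)
    y = labels["reward"].to_numpy()
    n_features = X_all.shape[1] // N_SENSORS
    A = set_reward_edges(GraphSpec(normalize=normalize_adjacency),
                         "test").effective_adjacency()

    sums = {"rewarded": [np.zeros(N_SENSORS), np.zeros(N_SENSORS), 0],
            "habituated": [np.zeros(N_SENSORS), np.zeros(N_SENSORS), 0]}
    for i in range(len(y)):
        Xi = _features_to_node_matrix(X_all[i], N_SENSORS, n_features)
        H1, H2 = model.hidden_activations(Xi, A)
        acc = sums[y[i]]
        acc[0] += H1[:N_SENSORS].mean(axis=1)
        acc[1] += H2[:N_SENSORS].mean(axis=1)
        acc[2] += 1

    l1_rew = sums["rewarded"][0] / sums["rewarded"][2]
    l2_rew = sums["rewarded"][1] / sums["rewarded"][2]
    l1_hab = sums["habituated"][0] / sums["habituated"][2]

    ui = uniqueness_index(l1_rew, l1_hab)
    change = l2_rew - l1_rew  # printed as a plain difference for the GCN
    return contrast_regression(ui, change)
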