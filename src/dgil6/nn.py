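"""The dual-channel graph network and its loss.

One channel stacks three multi-head graph-attention (GAT) layers: per head
``k``, edge logits ``g(a_k^T [W_k h_i || W_k h_j])`` are softmax-normalised
over each node's neighbourhood (self-loops included), the attention-weighted
sums of projected neighbour features are activated and the heads
concatenated, followed by layer normalisation. The other channel is a
single graph-convolution (GCN) layer, ``sigma(D^-1/2 A D^-1/2 H W)`` with
self-loops already part of ``A``. Each channel is global-max-pooled to a
64-vector; their concatenation (GAT first) feeds a four-layer fully
connected head whose scalar output passes through a sigmoid. Training
minimises a weighted binary cross-entropy with a 10:1 positive:negative
weight to counter class imbalance.

All forward passes run through :mod:`dgil6.autodiff`; graphs in a batch are
padded to a common length with isolated, masked-out dummy nodes, which
leaves the per-graph outputs bit-identical to the unpadded computation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .autodiff import Adam, Tensor, concat, weighted_bce_with_logits
from .graphs import PeptideGraph

DEFAULT_DECISION_THRESHOLD = 0.35
DEFAULT_POS_WEIGHT = 10.0
_BIG = 1e9

__all__ = [
    "GatLayerParams",
    "GcnLayerParams",
    "ClassifierParams",
    "ModelParams",
    "init_params",
    "gat_attention",
    "gat_layer_forward",
    "gcn_layer_forward",
    "global_max_pool",
    "forward",
    "forward_batch",
    "pack_graphs",
    "predict_label",
    "weighted_bce_loss",
]


@dataclasses.dataclass
class GatLayerParams:
    """One multi-head attention layer plus its layer-norm affine."""

    weight: Tensor  # (D_in, hidden) — per-head projections side by side
    attn_left: Tensor  # (K, hidden/K) — attention vector half acting on h_i
    attn_right: Tensor  # (K, hidden/K) — half acting on h_j
    gain: Tensor  # (hidden,) layer-norm gain
    offset: Tensor  # (hidden,) layer-norm offset

    def tensors(self) -> list[Tensor]:
        return [self.weight, self.attn_left, self.attn_right, self.gain, self.offset]


@dataclasses.dataclass
class GcnLayerParams:
    weight: Tensor  # (D_in, hidden)

    def tensors(self) -> list[Tensor]:
        return [self.weight]


@dataclasses.dataclass
class ClassifierParams:
    """Four affine maps fused -> h1 -> h2 -> h3 -> 1."""

    weights: list[Tensor]
    biases: list[Tensor]

    def tensors(self) -> list[Tensor]:
        return [*self.weights, *self.biases]


@dataclasses.dataclass
class ModelParams:
    """All learnable weights plus the fixed architectural hyperparameters."""

    gat_layers: list[GatLayerParams]
    gcn_layers: list[GcnLayerParams]
    classifier: ClassifierParams
    heads: int = 8
    hidden: int = 64
    in_dim: int = 70
    use_gat: bool = True
    use_gcn: bool = True
    dropout_rate: float = 0.5
    decision_threshold: float = DEFAULT_DECISION_THRESHOLD
    activation: str = "relu"

    @property
    def fused_dim(self) -> int:
        return self.hidden * (int(self.use_gat) + int(self.use_gcn))

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for layer in self.gat_layers:
            out.extend(layer.tensors())
        for layer in self.gcn_layers:
            out.extend(layer.tensors())
        out.extend(self.classifier.tensors())
        return out

    # -- serialisation ----------------------------------------------------

    def config(self) -> dict:
        return {
            "in_dim": self.in_dim,
            "hidden": self.hidden,
            "heads": self.heads,
            "gat_layers": len(self.gat_layers),
            "gcn_layers": len(self.gcn_layers),
            "use_gat": self.use_gat,
            "use_gcn": self.use_gcn,
            "classifier_hidden": [w.shape[1] for w in self.classifier.weights[:-1]],
            "dropout": self.dropout_rate,
            "threshold": self.decision_threshold,
            "activation": self.activation,
        }

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.gat_layers):
            state[f"gat{i}.weight"] = layer.weight.data
            state[f"gat{i}.attn_left"] = layer.attn_left.data
            state[f"gat{i}.attn_right"] = layer.attn_right.data
            state[f"gat{i}.gain"] = layer.gain.data
            state[f"gat{i}.offset"] = layer.offset.data
        for i, layer in enumerate(self.gcn_layers):
            state[f"gcn{i}.weight"] = layer.weight.data
        for i, (w, b) in enumerate(zip(self.classifier.weights, self.classifier.biases)):
            state[f"clf{i}.weight"] = w.data
            state[f"clf{i}.bias"] = b.data
        return state

    @classmethod
    def from_state_dict(cls, state: dict[str, np.ndarray], config: dict) -> "ModelParams":
        def param(key: str) -> Tensor:
            if key not in state:
                raise ValueError(f"checkpoint state is missing array {key!r}")
            return Tensor(np.array(state[key]), requires_grad=True)

        gat = [
            GatLayerParams(
                weight=param(f"gat{i}.weight"),
                attn_left=param(f"gat{i}.attn_left"),
                attn_right=param(f"gat{i}.attn_right"),
                gain=param(f"gat{i}.gain"),
                offset=param(f"gat{i}.offset"),
            )
            for i in range(int(config["gat_layers"])) if config.get("use_gat", True)
        ]
        gcn = [
            GcnLayerParams(weight=param(f"gcn{i}.weight"))
            for i in range(int(config["gcn_layers"])) if config.get("use_gcn", True)
        ]
        n_clf = len(config["classifier_hidden"]) + 1
        clf = ClassifierParams(
            weights=[param(f"clf{i}.weight") for i in range(n_clf)],
            biases=[param(f"clf{i}.bias") for i in range(n_clf)],
        )
        params = cls(
            gat_layers=gat,
            gcn_layers=gcn,
            classifier=clf,
            heads=int(config["heads"]),
            hidden=int(config["hidden"]),
            in_dim=int(config["in_dim"]),
            use_gat=bool(config.get("use_gat", True)),
            use_gcn=bool(config.get("use_gcn", True)),
            dropout_rate=float(config["dropout"]),
            decision_threshold=float(config["threshold"]),
            activation=str(config["activation"]),
        )
        _validate_params(params)
        return params


def _validate_params(params: ModelParams) -> None:
    if not (params.use_gat or params.use_gcn):
        raise ValueError("at least one of the GAT and GCN channels must be enabled")
    if params.hidden % params.heads:
        raise ValueError("hidden width must be divisible by the number of heads")
    if params.activation not in ("relu", "leaky_relu"):
        raise ValueError(f"unknown activation {params.activation!r}")
    expect = params.fused_dim
    for i, w in enumerate(params.classifier.weights):
        if w.shape[0] != expect:
            raise ValueError(
                f"classifier layer {i} expects input {w.shape[0]}, chain gives {expect}"
            )
        expect = w.shape[1]
    if expect != 1:
        raise ValueError("classifier must end in a scalar output")


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def init_params(
    seed: int | np.random.Generator,
    in_dim: int = 70,
    hidden: int = 64,
    heads: int = 8,
    n_gat_layers: int = 3,
    n_gcn_layers: int = 1,
    use_gat: bool = True,
    use_gcn: bool = True,
    classifier_hidden: Sequence[int] = (64, 32, 16),
    dropout: float = 0.5,
    decision_threshold: float = DEFAULT_DECISION_THRESHOLD,
    activation: str = "relu",
) -> ModelParams:
    """Glorot-initialised parameters for the configured architecture."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dh = hidden // heads
    gat = [
        GatLayerParams(
            weight=_glorot(rng, (in_dim if i == 0 else hidden, hidden)),
            attn_left=_glorot(rng, (heads, dh)),
            attn_right=_glorot(rng, (heads, dh)),
            gain=Tensor(np.ones(hidden), requires_grad=True),
            offset=Tensor(np.zeros(hidden), requires_grad=True),
        )
        for i in range(n_gat_layers)
    ] if use_gat else []
    gcn = [
        GcnLayerParams(weight=_glorot(rng, (in_dim if i == 0 else hidden, hidden)))
        for i in range(n_gcn_layers)
    ] if use_gcn else []
    fused = hidden * (int(use_gat) + int(use_gcn))
    dims = [fused, *classifier_hidden, 1]
    clf = ClassifierParams(
        weights=[_glorot(rng, (a, b)) for a, b in zip(dims[:-1], dims[1:])],
        biases=[Tensor(np.zeros(b), requires_grad=True) for b in dims[1:]],
    )
    params = ModelParams(
        gat_layers=gat,
        gcn_layers=gcn,
        classifier=clf,
        heads=heads,
        hidden=hidden,
        in_dim=in_dim,
        use_gat=use_gat,
        use_gcn=use_gcn,
        dropout_rate=dropout,
        decision_threshold=decision_threshold,
        activation=activation,
    )
    _validate_params(params)
    return params


# ---------------------------------------------------------------------------
# forward pieces


def _act(t: Tensor, name: str) -> Tensor:
    return t.relu() if name == "relu" else t.leaky_relu(0.2)


def _act_np(x: np.ndarray, name: str) -> np.ndarray:
    return np.maximum(x, 0.0) if name == "relu" else np.where(x > 0, x, 0.2 * x)


def _dropout(t: Tensor, rate: float, training: bool, rng) -> Tensor:
    if not training or rate <= 0.0:
        return t
    if rng is None:
        raise ValueError("training-mode dropout needs a random generator")
    keep = (rng.random(t.shape) >= rate) / (1.0 - rate)
    return t * keep


def _layer_norm(x: Tensor, gain: Tensor, offset: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=-1, keepdims=True)
    return centred / ((var + eps) ** 0.5) * gain + offset


def _gat_layer_t(H: Tensor, adj: np.ndarray, layer: GatLayerParams, heads: int,
                 activation: str) -> Tensor:
    B, L, _ = H.shape
    dh = layer.weight.shape[1] // heads
    proj = (H @ layer.weight).reshape(B, L, heads, dh)
    src = (proj * layer.attn_left.reshape(1, 1, heads, dh)).sum(axis=-1)  # (B,L,K)
    dst = (proj * layer.attn_right.reshape(1, 1, heads, dh)).sum(axis=-1)
    slope = 0.0 if activation == "relu" else 0.2
    alpha = src.pairwise_softmax(dst, adj > 0, negative_slope=slope)
    heads_out = _act(alpha.attend(proj), activation).reshape(B, L, heads * dh)
    return _layer_norm(heads_out, layer.gain, layer.offset)


def _sym_norm(adj: np.ndarray) -> np.ndarray:
    """``D^-1/2 A D^-1/2`` for self-looped adjacency (batched or single)."""
    deg = adj.sum(axis=-1)
    dinv = 1.0 / np.sqrt(deg)
    return adj * dinv[..., :, None] * dinv[..., None, :]


def _gcn_layer_t(H: Tensor, ahat: np.ndarray, layer: GcnLayerParams,
                 activation: str) -> Tensor:
    return _act(Tensor(ahat) @ (H @ layer.weight), activation)


def forward_batch(
    feat: np.ndarray,
    adj: np.ndarray,
    mask: np.ndarray,
    params: ModelParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
):
    """Run the whole network on a padded batch.

    ``feat`` (B, Lmax, D), ``adj`` (B, Lmax, Lmax) with self-loops everywhere
    (padded nodes isolated), ``mask`` (B, Lmax) with 1 on real nodes.
    Returns ``(logits, fused)`` autodiff tensors of shapes (B,) and
    (B, fused_dim); ``fused`` is the pooled dual-channel vector before the
    classifier (GAT columns first).
    """
    B, L, D = feat.shape
    if D != params.in_dim:
        raise ValueError(f"feature width {D} does not match the model's {params.in_dim}")
    X = Tensor(feat)
    pool_mask = (mask - 1.0)[:, :, None] * _BIG  # 0 on real nodes, -BIG on padding
    pooled: list[Tensor] = []
    if params.use_gat:
        H = X
        for layer in params.gat_layers:
            H = _gat_layer_t(H, adj, layer, params.heads, params.activation)
        g = (H + pool_mask).max(axis=1)
        pooled.append(_dropout(g, params.dropout_rate, training, rng))
    if params.use_gcn:
        ahat = _sym_norm(adj)
        Hc = X
        for layer in params.gcn_layers:
            Hc = _gcn_layer_t(Hc, ahat, layer, params.activation)
        c = (Hc + pool_mask).max(axis=1)
        pooled.append(_dropout(c, params.dropout_rate, training, rng))
    fused = pooled[0] if len(pooled) == 1 else concat(pooled, axis=-1)
    x = fused
    n_layers = len(params.classifier.weights)
    for i, (w, b) in enumerate(zip(params.classifier.weights, params.classifier.biases)):
        x = x @ w + b
        if i < n_layers - 1:
            x = _dropout(_act(x, params.activation), params.dropout_rate, training, rng)
    return x.reshape(B), fused


def pack_graphs(graphs: Sequence[PeptideGraph], pad_to: int | None = None):
    """Pad graphs to a common length: ``(feat, adj, mask)`` numpy arrays.

    Padded nodes carry zero features and only a self-loop, and are excluded
    from pooling by the mask, so padding does not change any graph's output.
    """
    if not graphs:
        raise ValueError("cannot pack an empty list of graphs")
    widths = {g.features.width for g in graphs}
    if len(widths) != 1:
        raise ValueError(f"graphs disagree on feature width: {sorted(widths)}")
    L = pad_to or max(g.n_nodes for g in graphs)
    B, D = len(graphs), widths.pop()
    feat = np.zeros((B, L, D))
    adj = np.zeros((B, L, L))
    mask = np.zeros((B, L))
    for b, g in enumerate(graphs):
        n = g.n_nodes
        feat[b, :n] = g.features.values
        adj[b, :n, :n] = g.adjacency.adj
        adj[b, range(n, L), range(n, L)] = 1.0  # keep padded softmax rows defined
        mask[b, :n] = 1.0
    return feat, adj, mask


# ---------------------------------------------------------------------------
# single-graph operations (inspection / oracle surface)


def gat_attention(
    H: np.ndarray,
    adj: np.ndarray,
    layer: GatLayerParams,
    head: int,
    activation: str = "relu",
) -> np.ndarray:
    """Attention matrix of one head: rows softmax-normalised over neighbours.

    Entries off the adjacency support are exactly zero. A row whose edge
    logits are all zeroed by the activation degrades to uniform weights over
    the neighbourhood, which is well-defined.
    """
    W = layer.weight.data
    dh = W.shape[1] // layer.attn_left.shape[0]
    proj = H @ W[:, head * dh : (head + 1) * dh]
    e = _act_np(
        (proj @ layer.attn_left.data[head])[:, None]
        + (proj @ layer.attn_right.data[head])[None, :],
        activation,
    )
    e = np.where(adj > 0, e, -np.inf)
    e -= e.max(axis=1, keepdims=True)
    ez = np.exp(e)
    alpha = ez / ez.sum(axis=1, keepdims=True)
    return np.where(adj > 0, alpha, 0.0)


def gat_layer_forward(
    H: np.ndarray, adj: np.ndarray, layer: GatLayerParams, heads: int = 8,
    activation: str = "relu",
) -> np.ndarray:
    """One full GAT layer (all heads, activation, concat, layer norm)."""
    out = _gat_layer_t(Tensor(H[None]), np.asarray(adj, float)[None], layer, heads, activation)
    return out.data[0]


def gcn_layer_forward(
    H: np.ndarray, adj: np.ndarray, layer: GcnLayerParams, activation: str = "relu"
) -> np.ndarray:
    """One GCN layer with symmetric degree normalisation."""
    ahat = _sym_norm(np.asarray(adj, dtype=np.float64))
    return _act_np(ahat @ np.asarray(H, float) @ layer.weight.data, activation)


def global_max_pool(H: np.ndarray) -> np.ndarray:
    """Column-wise maximum over nodes; invariant to node order."""
    H = np.asarray(H)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("global max pooling needs at least one node")
    return H.max(axis=0)


def forward(
    graph: PeptideGraph,
    params: ModelParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Whole-network pass on one graph: ``(logit, sigmoid probability)``."""
    feat, adj, mask = pack_graphs([graph])
    logits, _ = forward_batch(feat, adj, mask, params, training=training, rng=rng)
    logit = float(logits.data[0])
    return logit, float(1.0 / (1.0 + np.exp(-logit)))


def predict_label(probability: float, threshold: float = DEFAULT_DECISION_THRESHOLD) -> int:
    """1 iff the probability strictly exceeds the decision threshold."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    return int(probability > threshold)


def weighted_bce_loss(
    logits: np.ndarray, labels: np.ndarray, pos_weight: float = DEFAULT_POS_WEIGHT
) -> float:
    """Mean weighted binary cross-entropy on pre-sigmoid logits."""
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    if logits.shape != labels.shape:
        raise ValueError("logits and labels must have equal length")
    return float(weighted_bce_with_logits(Tensor(logits), labels, pos_weight).data)
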