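"""A scikit-learn style estimator wrapping the dual-channel graph network.

``DualChannelGraphClassifier`` takes a list of :class:`~dgil6.graphs.PeptideGraph`
objects as ``X`` and binary labels as ``y``; it follows the usual estimator
contract (``get_params``/``set_params``, ``fit`` returning ``self``,
trailing-underscore fitted attributes) so it composes with
``sklearn.base.clone`` and model-selection utilities that accept list-like
``X``.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .autodiff import Adam, weighted_bce_with_logits
from .graphs import PeptideGraph
from .nn import (
    DEFAULT_DECISION_THRESHOLD,
    DEFAULT_POS_WEIGHT,
    ModelParams,
    forward_batch,
    init_params,
    pack_graphs,
)

__all__ = ["DualChannelGraphClassifier"]


class DualChannelGraphClassifier(ClassifierMixin, BaseEstimator):
    """IL-6-inducing peptide classifier over residue-contact graphs.

    Parameters
    ----------
    hidden : int
        Width of each channel's node representation (and of the pooled
        per-channel vector).
    heads : int
        Number of attention heads per GAT layer; must divide ``hidden``.
    n_gat_layers, n_gcn_layers : int
        Depth of the two channels.
    use_gat, use_gcn : bool
        Channel toggles for ablation; at least one must stay enabled.
    classifier_hidden : tuple of int
        Hidden widths of the fully connected head (four affine maps by
        default: fused -> 64 -> 32 -> 16 -> 1).
    dropout : float
        Dropout rate applied after pooling and after each hidden classifier
        layer, active only during training.
    activation : {"relu", "leaky_relu"}
        Activation used for attention logits, layer outputs and the head.
    decision_threshold : float
        Probability cut-off for :meth:`predict`; a peptide is called
        positive when its sigmoid output strictly exceeds it.
    pos_weight : float
        Multiplier on positive-sample loss terms (10:1 by default).
    lr, lr_decay, decay_every : float, float, int
        Adam initial learning rate, multiplicative decay factor, and the
        epoch period of the decay (lr at epoch e is
        ``lr * lr_decay**(e // decay_every)``).
    epochs, batch_size : int
        Training schedule.
    random_state : int or None
        Seed for weight initialisation, shuffling and dropout; fixing it
        makes training bit-reproducible.

    Attributes
    ----------
    params_ : ModelParams
        The trained weights.
    classes_ : ndarray
        Always ``[0, 1]`` after fitting.
    loss_history_ : list of float
        Mean weighted BCE per epoch.
    n_features_in_ : int
        Node feature width seen during :meth:`fit`.
    """

    def __init__(
        self,
        hidden: int = 64,
        heads: int = 8,
        n_gat_layers: int = 3,
        n_gcn_layers: int = 1,
        use_gat: bool = True,
        use_gcn: bool = True,
        classifier_hidden: tuple[int, ...] = (64, 32, 16),
        dropout: float = 0.5,
        activation: str = "relu",
        decision_threshold: float = DEFAULT_DECISION_THRESHOLD,
        pos_weight: float = DEFAULT_POS_WEIGHT,
        lr: float = 1e-3,
        lr_decay: float = 0.95,
        decay_every: int = 5,
        epochs: int = 40,
        batch_size: int = 256,
        random_state: int | None = None,
    ):
        self.hidden = hidden
        self.heads = heads
        self.n_gat_layers = n_gat_layers
        self.n_gcn_layers = n_gcn_layers
        self.use_gat = use_gat
        self.use_gcn = use_gcn
        self.classifier_hidden = classifier_hidden
        self.dropout = dropout
        self.activation = activation
        self.decision_threshold = decision_threshold
        self.pos_weight = pos_weight
        self.lr = lr
        self.lr_decay = lr_decay
        self.decay_every = decay_every
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _validate_graphs(self, X: Sequence[PeptideGraph]) -> list[PeptideGraph]:
        graphs = list(X)
        if not graphs:
            raise ValueError("the dataset is empty")
        for g in graphs:
            if not isinstance(g, PeptideGraph):
                raise TypeError(f"expected PeptideGraph inputs, got {type(g).__name__}")
        return graphs

    def learning_rate_at(self, epoch: int) -> float:
        """Learning rate in force during ``epoch`` (0-based)."""
        return self.lr * self.lr_decay ** (epoch // self.decay_every)

    def fit(self, X: Sequence[PeptideGraph], y=None):
        """Train the network on labelled peptide graphs.

        ``y`` may be omitted when every graph's record carries a label.
        """
        graphs = self._validate_graphs(X)
        if y is None:
            y = [g.label for g in graphs]
        labels = np.asarray(y)
        if labels.shape != (len(graphs),):
            raise ValueError("y must provide one label per graph")
        if any(l is None for l in y) or not np.all(np.isin(labels, (0, 1))):
            raise ValueError("labels must be binary (0/1) for every graph")
        labels = labels.astype(np.float64)
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1 or self.lr <= 0 or not 0 < self.lr_decay <= 1:
            raise ValueError("invalid training configuration")
        if len(np.unique(labels)) < 2:
            warnings.warn("training data contains a single class", UserWarning)

        rng = np.random.default_rng(self.random_state)
        feat, adj, mask = pack_graphs(graphs)
        self.n_features_in_ = feat.shape[2]
        params = init_params(
            rng,
            in_dim=self.n_features_in_,
            hidden=self.hidden,
            heads=self.heads,
            n_gat_layers=self.n_gat_layers,
            n_gcn_layers=self.n_gcn_layers,
            use_gat=self.use_gat,
            use_gcn=self.use_gcn,
            classifier_hidden=tuple(self.classifier_hidden),
            dropout=self.dropout,
            decision_threshold=self.decision_threshold,
            activation=self.activation,
        )
        optimiser = Adam(params.parameters(), lr=self.lr)
        n = len(graphs)
        self.loss_history_ = []
        for epoch in range(self.epochs):
            optimiser.lr = self.learning_rate_at(epoch)
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits, _ = forward_batch(
                    feat[idx], adj[idx], mask[idx], params, training=True, rng=rng
                )
                loss = weighted_bce_with_logits(logits, labels[idx], self.pos_weight)
                optimiser.zero_grad()
                loss.backward()
                optimiser.step()
                epoch_loss += float(loss.data) * len(idx)
            self.loss_history_.append(epoch_loss / n)
        self.params_ = params
        self.classes_ = np.array([0, 1])
        return self

    # ------------------------------------------------------------------

    def _forward(self, X: Sequence[PeptideGraph]):
        if not hasattr(self, "params_"):
            raise RuntimeError("this classifier has not been fitted yet")
        graphs = self._validate_graphs(X)
        all_logits, all_fused = [], []
        for start in range(0, len(graphs), self.batch_size):  # bound peak memory
            logits, fused = forward_batch(
                *pack_graphs(graphs[start : start + self.batch_size]),
                self.params_,
                training=False,
            )
            all_logits.append(logits.data)
            all_fused.append(fused.data)
            logits.release()
        return np.concatenate(all_logits), np.vstack(all_fused)

    def decision_function(self, X) -> np.ndarray:
        """Pre-sigmoid logits, one per peptide."""
        return self._forward(X)[0]

    def predict_proba(self, X) -> np.ndarray:
        """Column-stacked ``P(y=0)``, ``P(y=1)`` with a sigmoid head."""
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        """Binary labels at the strict ``> decision_threshold`` cut-off."""
        return (self.predict_proba(X)[:, 1] > self.decision_threshold).astype(int)

    def transform(self, X) -> np.ndarray:
        """Fused 128-d pooled features (GAT columns 0-63, GCN 64-127)."""
        return self._forward(X)[1]

    def save(self, path) -> None:
        """Checkpoint the fitted weights and architecture."""
        from .io_formats import save_checkpoint

        save_checkpoint(self.params_, self.params_.config(), path)

    @classmethod
    def from_checkpoint(cls, path) -> "DualChannelGraphClassifier":
        """Rebuild a fitted classifier from a checkpoint file."""
        from .io_formats import load_checkpoint

        params, config = load_checkpoint(path)
        est = cls(
            hidden=params.hidden,
            heads=params.heads,
            n_gat_layers=max(len(params.gat_layers), 1),
            n_gcn_layers=max(len(params.gcn_layers), 1),
            use_gat=params.use_gat,
            use_gcn=params.use_gcn,
            classifier_hidden=tuple(config["classifier_hidden"]),
            dropout=params.dropout_rate,
            activation=params.activation,
            decision_threshold=params.decision_threshold,
        )
        est.params_ = params
        est.classes_ = np.array([0, 1])
        est.n_features_in_ = params.in_dim
        return est
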