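"""Spectral graph-convolutional decoder of cognitive state (ToM vs Pain).

``ChebNetDecoder`` is a model object built from graph samples (one per
subject x event window); ``fit`` trains the network and returns a
``DecoderResults`` carrying the learned weights, the loss history and
held-out diagnostics. Architecture per block: Chebyshev graph convolution
-> batch normalization -> ReLU -> pairwise node max-pooling -> dropout;
after the configured number of blocks the node features are flattened into a
dense softmax layer. Between blocks the graph is coarsened by merging node
pairs (in ROI-table order) and summing their edge weights, so deeper blocks
operate on smaller graphs (N -> N/2 -> N/4).

Training uses Adam with cross-entropy loss plus an optional
(rho / 2 N_P) ||W||^2 weight-decay term, early stopping on a stratified
validation split, and is bitwise-deterministic under the configured seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from ._utils import spawn_rng
from .graphs import BrainGraph

FILTER_SCHEDULES = {1: (16,), 2: (16, 32), 3: (16, 32, 64)}


class NotFittedError(RuntimeError):
    pass


@dataclass
class DecoderConfig:
    conv_depth: int = 3
    cheb_order: int = 3
    pool_size: int = 2
    dropout: float = 0.65
    learning_rate: float = 0.001
    weight_decay: float = 0.0  # rho in the loss
    patience: int = 3
    min_epochs: int = 40  # early stopping activates only after this many epochs
    batch_size: int = 32
    epochs: int = 100
    n_classes: int = 2
    val_fraction: float = 0.1
    filters: tuple[int, ...] | None = None  # overrides the depth schedule
    seed: int = 0

    def __post_init__(self):
        if self.conv_depth not in FILTER_SCHEDULES:
            raise ValueError("conv_depth must be 1, 2 or 3")
        if self.cheb_order < 1:
            raise ValueError("cheb_order must be >= 1")
        if self.pool_size != 2:
            raise ValueError("only pool size 2 is implemented")

    @property
    def filter_schedule(self) -> tuple[int, ...]:
        return self.filters if self.filters is not None else FILTER_SCHEDULES[self.conv_depth]


def coarsen_adjacency(a: np.ndarray) -> np.ndarray:
    """Merge node pairs (2i, 2i+1) and sum edge weights; odd node kept alone."""
    n = a.shape[0]
    m = (n + 1) // 2
    p = np.zeros((m, n))
    for i in range(m):
        p[i, 2 * i] = 1.0
        if 2 * i + 1 < n:
            p[i, 2 * i + 1] = 1.0
    c = p @ a @ p.T
    np.fill_diagonal(c, 0.0)
    return c


def _level_laplacians(graph: BrainGraph, depth: int) -> list[np.ndarray]:
    """Scaled Laplacians of the graph and its coarsened versions."""
    out = [graph.scaled_laplacian]
    a = graph.adjacency
    for _ in range(depth - 1):
        a = coarsen_adjacency(a)
        out.append(BrainGraph(a).scaled_laplacian)
    return out


class ChebNetDecoder:
    """Graph-convolutional classifier of the event-window state.

    Parameters
    ----------
    graphs : list of BrainGraph
        One graph per sample, each carrying ``node_features`` (N, F).
    labels : sequence
        State label per sample (two classes by default).
    groups : sequence, optional
        Subject identifier per sample; used by callers for subject-level
        splitting, stored for reference.
    config : DecoderConfig
    """

    def __init__(self, graphs: list[BrainGraph], labels, groups=None,
                 config: DecoderConfig | None = None):
        self.config = config or DecoderConfig()
        if not graphs:
            raise ValueError("no graph samples supplied")
        self.classes_ = np.unique(np.asarray(labels))
        if self.classes_.size < 2:
            raise ValueError("training data contains a single class")
        if self.classes_.size != self.config.n_classes:
            self.config.n_classes = int(self.classes_.size)
        self.y = np.searchsorted(self.classes_, np.asarray(labels))
        self.groups = None if groups is None else np.asarray(groups)
        self.n_nodes = graphs[0].n_nodes
        self.f_in = graphs[0].node_features.shape[1]
        self._cheb, self.x = self._prepare(graphs)
        self._layers: list[nn.Layer] | None = None

    # ------------------------------------------------------------------
    def _prepare(self, graphs: list[BrainGraph]):
        """Per-sample Chebyshev stacks at every coarsening level."""
        cfg = self.config
        for g in graphs:
            if g.n_nodes != self.n_nodes:
                raise ValueError("all graphs must share the node count")
            if g.node_features is None or g.node_features.shape[1] != self.f_in:
                raise ValueError("all graphs need node_features of equal width")
        cheb = []
        per_graph = [_level_laplacians(g, cfg.conv_depth) for g in graphs]
        for level in range(cfg.conv_depth):
            lts = np.stack([pg[level] for pg in per_graph])
            cheb.append(nn.cheb_tensor(lts, cfg.cheb_order))
        x = np.stack([g.node_features for g in graphs])
        return cheb, x

    def _node_counts(self) -> list[int]:
        counts = [self.n_nodes]
        for _ in range(self.config.conv_depth - 1):
            counts.append((counts[-1] + 1) // 2)
        return counts

    def _build(self, rng: np.random.Generator, drop_rng: np.random.Generator):
        cfg = self.config
        counts = self._node_counts()
        layers: list[nn.Layer] = []
        f_prev = self.f_in
        n_cur = self.n_nodes
        for level, f_out in enumerate(cfg.filter_schedule):
            layers.append(nn.ChebConv(cfg.cheb_order, f_prev, f_out, counts[level], rng))
            layers.append(nn.BatchNorm(f_out))
            layers.append(nn.ReLU())
            layers.append(nn.NodeMaxPool())
            layers.append(nn.Dropout(cfg.dropout, drop_rng))
            f_prev = f_out
            n_cur = (counts[level] + 1) // 2
        layers.append(nn.Flatten())
        layers.append(nn.Dense(n_cur * f_prev, cfg.n_classes, rng))
        return layers

    def _forward(self, layers, cheb_batch, x, training):
        h = x
        level = 0
        for layer in layers:
            if isinstance(layer, nn.ChebConv):
                h = layer.forward((cheb_batch[level], h), training)
                level += 1
            else:
                h = layer.forward(h, training)
        return nn.softmax(h)

    @staticmethod
    def _backward(layers, dlogits):
        d = dlogits
        for layer in reversed(layers):
            d = layer.backward(d)

    # ------------------------------------------------------------------
    def fit(self, train_idx=None) -> "DecoderResults":
        cfg = self.config
        rng = spawn_rng(cfg.seed, "decoder", "init")
        drop_rng = spawn_rng(cfg.seed, "decoder", "dropout")
        shuffle_rng = spawn_rng(cfg.seed, "decoder", "shuffle")
        layers = self._build(rng, drop_rng)
        opt = nn.Adam(layers, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

        idx = np.arange(self.x.shape[0]) if train_idx is None else np.asarray(train_idx)
        # stratified validation split for early stopping
        val_idx, tr_idx = [], []
        for cls in range(cfg.n_classes):
            cls_idx = idx[self.y[idx] == cls]
            cls_idx = cls_idx[shuffle_rng.permutation(cls_idx.size)]
            n_val = max(1, int(round(cfg.val_fraction * cls_idx.size)))
            val_idx.extend(cls_idx[:n_val])
            tr_idx.extend(cls_idx[n_val:])
        tr_idx, val_idx = np.array(tr_idx), np.array(val_idx)

        onehot = np.eye(cfg.n_classes)[self.y]
        history = []
        best_val, best_state, patience_left = np.inf, None, cfg.patience
        for epoch in range(cfg.epochs):
            order = tr_idx[shuffle_rng.permutation(tr_idx.size)]
            losses = []
            for start in range(0, order.size, cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                cheb_b = [c[batch] for c in self._cheb]
                probs = self._forward(layers, cheb_b, self.x[batch], training=True)
                loss = nn.cross_entropy(probs, onehot[batch],
                                        opt.weights_sq_sum(), cfg.weight_decay,
                                        opt.n_params)
                losses.append(loss)
                dlogits = (probs - onehot[batch]) / batch.size
                self._backward(layers, dlogits)
                opt.step()
            val_probs = self._forward(layers, [c[val_idx] for c in self._cheb],
                                      self.x[val_idx], training=False)
            val_loss = nn.cross_entropy(val_probs, onehot[val_idx])
            history.append((epoch, float(np.mean(losses)), val_loss))
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = copy.deepcopy([l.params for l in layers if l.params])
                bn_state = copy.deepcopy([(l.running_mean, l.running_var)
                                          for l in layers if isinstance(l, nn.BatchNorm)])
                patience_left = cfg.patience
            else:
                patience_left -= 1
                if patience_left <= 0 and epoch + 1 >= cfg.min_epochs:
                    break
        if best_state is not None:
            it = iter(best_state)
            for layer in layers:
                if layer.params:
                    for p, saved in zip(layer.params, next(it)):
                        p[...] = saved
            bn_it = iter(bn_state)
            for layer in layers:
                if isinstance(layer, nn.BatchNorm):
                    layer.running_mean, layer.running_var = next(bn_it)
        self._layers = layers
        hist = pd.DataFrame(history, columns=["epoch", "train_loss", "val_loss"])
        return DecoderResults(self, layers, hist)

    # ------------------------------------------------------------------
    def predict_proba(self, layers=None, idx=None) -> np.ndarray:
        layers = layers if layers is not None else self._layers
        if layers is None:
            raise NotFittedError("decoder has not been fitted")
        idx = np.arange(self.x.shape[0]) if idx is None else np.asarray(idx)
        out = []
        for start in range(0, idx.size, 256):
            b = idx[start:start + 256]
            out.append(self._forward(layers, [c[b] for c in self._cheb],
                                     self.x[b], training=False))
        return np.vstack(out)


class DecoderResults:
    """Fitted decoder: weights, training history, prediction and summary."""

    def __init__(self, model: ChebNetDecoder, layers, history: pd.DataFrame):
        self.model = model
        self._layers = layers
        self.history = history

    @property
    def n_epochs(self) -> int:
        return len(self.history)

    def predict_proba(self, idx=None) -> np.ndarray:
        return self.model.predict_proba(self._layers, idx)

    def predict(self, idx=None) -> np.ndarray:
        """Class labels; exact probability ties resolve to the lower class index."""
        probs = self.predict_proba(idx)
        return self.model.classes_[np.argmax(probs, axis=1)]

    def accuracy(self, idx) -> float:
        idx = np.asarray(idx)
        return float(np.mean(self.predict(idx) == self.model.classes_[self.model.y[idx]]))

    def save(self, path) -> None:
        """Checkpoint: npz of weights + JSON sidecar (config, history, classes).

        Format version 1; ``load_weights`` restores the weights into a
        freshly built model with the same configuration.
        """
        path = Path(path)
        arrays = {}
        for li, layer in enumerate(self._layers):
            for pi, p in enumerate(layer.params):
                arrays[f"layer{li}_param{pi}"] = p
            if isinstance(layer, nn.BatchNorm):
                arrays[f"layer{li}_running_mean"] = layer.running_mean
                arrays[f"layer{li}_running_var"] = layer.running_var
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "format": "fcdecode-decoder/1",
            "config": asdict(self.model.config),
            "classes": [str(c) for c in self.model.classes_],
            "history": self.history.to_dict(orient="list"),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    def load_weights(self, path) -> None:
        """Restore weights saved by :meth:`save` into this fitted result."""
        path = Path(path)
        data = np.load(path.with_suffix(".npz"))
        for li, layer in enumerate(self._layers):
            for pi, p in enumerate(layer.params):
                p[...] = data[f"layer{li}_param{pi}"]
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = data[f"layer{li}_running_mean"]
                layer.running_var = data[f"layer{li}_running_var"]

    def plot_history(self, ax=None):
        """Training and validation loss per epoch."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history.epoch, self.history.train_loss, label="train")
        ax.plot(self.history.epoch, self.history.val_loss, label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("cross-entropy loss")
        ax.legend()
        return ax

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "ChebNet state decoder",
            "=" * 44,
            f"samples: {self.model.x.shape[0]}   nodes: {self.model.n_nodes}   "
            f"node features: {self.model.f_in}",
            f"blocks: {cfg.conv_depth} (filters {cfg.filter_schedule}), "
            f"Chebyshev order K={cfg.cheb_order}",
            f"optimizer: Adam lr={cfg.learning_rate}, dropout={cfg.dropout}, "
            f"weight decay rho={cfg.weight_decay}, patience={cfg.patience}",
            f"epochs run: {self.n_epochs}   "
            f"final train loss: {self.history.train_loss.iloc[-1]:.4f}   "
            f"best val loss: {self.history.val_loss.min():.4f}",
        ]
        return "\n".join(lines)
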