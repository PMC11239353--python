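"""Convolutional variational autoencoder over connectivity matrices, with a
latent-space classifier of false-belief performance group.

The encoder compresses an N x N connectivity matrix (N in {12, 8, 6}) through
two stride-2 SAME convolutions (32 then 64 filters), a dense ReLU layer, and
two linear heads for the posterior mean mu(x) and log-variance log sigma^2(x)
of a 32-dimensional Gaussian latent. The decoder mirrors it with a dense
layer, two transposed convolutions and a sigmoid output; correlation inputs
are mapped from [-1, 1] to [0, 1] to match the sigmoid range.

Training maximizes the ELBO: per-sample squared reconstruction error summed
over matrix entries plus the closed-form Gaussian KL to the standard-normal
prior, optimized with Adam. The ``vae_loss`` helper reports the per-entry
(mean) reconstruction error alongside the KL term.

Group prediction follows the printed protocol: a dense head with three
sigmoid outputs trained with one-hot binary cross-entropy on the latent
means; the predicted group is the argmax, ties resolving to the lowest group
index in (pass, inconsistent, fail) order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from ._utils import spawn_rng
from .cohort import GROUPS


@dataclass
class VaeConfig:
    kernel: int = 3
    filters: int = 32  # first conv; doubles in the second
    strides: int = 2
    epochs: int = 50
    latent_dim: int = 32
    channels: int = 1
    batch_train: int = 128
    batch_predict: int = 32
    learning_rate: float = 0.001
    padding: str = "SAME"
    #: epochs over which the KL weight ramps 0 -> 1 (posterior-collapse guard)
    kl_warmup_epochs: int = 10
    #: per-dimension KL floor (nats) below which the KL gradient is switched
    #: off, preventing full posterior collapse (free bits)
    free_bits: float = 0.05
    seed: int = 0


def kl_term(mu: np.ndarray, log_var: np.ndarray) -> float:
    """Closed-form KL( N(mu, diag sigma^2) || N(0, I) ) summed over dims
    (and averaged over the batch axis if 2-D)."""
    mu = np.asarray(mu, dtype=float)
    log_var = np.asarray(log_var, dtype=float)
    per = 0.5 * (mu ** 2 + np.exp(log_var) - 1.0 - log_var)
    if per.ndim == 1:
        return float(per.sum())
    return float(per.sum(axis=1).mean())


def reparameterize(mu: np.ndarray, log_var: np.ndarray,
                   rng: np.random.Generator | int | None = None) -> np.ndarray:
    """z = mu + sigma * eps with eps ~ N(0, 1) from a seeded stream."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    eps = rng.standard_normal(np.shape(mu))
    return np.asarray(mu) + np.exp(np.asarray(log_var) / 2.0) * eps


@dataclass
class VaeLoss:
    reconstruction: float  # mean squared error over entries
    kl: float
    @property
    def total(self) -> float:
        return self.reconstruction + self.kl


def vae_loss(x: np.ndarray, x_recon: np.ndarray, mu: np.ndarray,
             log_var: np.ndarray) -> VaeLoss:
    """Reported diagnostic: per-entry MSE plus the Gaussian KL term."""
    mse = float(np.mean((np.asarray(x) - np.asarray(x_recon)) ** 2))
    return VaeLoss(reconstruction=mse, kl=kl_term(mu, log_var))


def _conv_out(n: int, stride: int = 2) -> int:
    return -(-n // stride)


class ConnectivityVAE:
    """VAE model over a stack of connectivity matrices.

    Parameters
    ----------
    matrices : (n, N, N) array or list of ConnectivityMatrix
        Correlation matrices in [-1, 1]; rescaled internally to [0, 1].
    config : VaeConfig
    """

    def __init__(self, matrices, config: VaeConfig | None = None):
        self.config = config or VaeConfig()
        arr = (np.stack([m.values for m in matrices])
               if not isinstance(matrices, np.ndarray) else np.asarray(matrices, float))
        if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
            raise ValueError("matrices must be (n, N, N)")
        if arr.shape[0] == 0:
            raise ValueError("empty dataset")
        self.n_rois = arr.shape[1]
        self.x = ((np.clip(arr, -1.0, 1.0) + 1.0) / 2.0)[..., None]  # (n, N, N, 1)
        self._build()

    # ------------------------------------------------------------------
    def _build(self):
        cfg = self.config
        n = self.n_rois
        rng = spawn_rng(cfg.seed, "vae", "init")
        n1, n2 = _conv_out(n), _conv_out(_conv_out(n))
        f1, f2 = cfg.filters, cfg.filters * 2
        flat = n2 * n2 * f2
        self.enc_conv1 = nn.Conv2D((n, n), cfg.channels, f1, rng, cfg.kernel, cfg.strides)
        self.enc_relu1 = nn.ReLU()
        self.enc_conv2 = nn.Conv2D((n1, n1), f1, f2, rng, cfg.kernel, cfg.strides)
        self.enc_relu2 = nn.ReLU()
        self.enc_flatten = nn.Flatten()
        self.enc_dense = nn.Dense(flat, cfg.latent_dim, rng)
        self.enc_relu3 = nn.ReLU()
        self.z_mean = nn.Dense(cfg.latent_dim, cfg.latent_dim, rng)
        self.z_log_var = nn.Dense(cfg.latent_dim, cfg.latent_dim, rng)

        self.dec_dense = nn.Dense(cfg.latent_dim, flat, rng)
        self.dec_relu0 = nn.ReLU()
        self.dec_convt1 = nn.ConvTranspose2D((n2, n2), (n1, n1), f2, f2, rng,
                                             cfg.kernel, cfg.strides)
        self.dec_relu1 = nn.ReLU()
        self.dec_convt2 = nn.ConvTranspose2D((n1, n1), (n, n), f2, f1, rng,
                                             cfg.kernel, cfg.strides)
        self.dec_relu2 = nn.ReLU()
        self.dec_out = nn.ConvTranspose2D((n, n), (n, n), f1, cfg.channels, rng,
                                          cfg.kernel, stride=1)
        self.dec_sigmoid = nn.Sigmoid()
        self._n2, self._f2 = n2, f2
        self.encoder_layers = [self.enc_conv1, self.enc_relu1, self.enc_conv2,
                               self.enc_relu2, self.enc_flatten, self.enc_dense,
                               self.enc_relu3, self.z_mean, self.z_log_var]
        self.decoder_layers = [self.dec_dense, self.dec_relu0, self.dec_convt1,
                               self.dec_relu1, self.dec_convt2, self.dec_relu2,
                               self.dec_out, self.dec_sigmoid]

    def count_params(self, part: str = "encoder") -> dict[str, int]:
        """Per-layer and total trainable parameter counts from shape algebra."""
        if part == "encoder":
            rows = {
                "encoder_input": 0,
                "conv2d_1": self.enc_conv1.n_params,
                "conv2d_2": self.enc_conv2.n_params,
                "flatten": 0,
                "dense": self.enc_dense.weight.size + self.enc_dense.bias.size,
                "z_mean": self.z_mean.weight.size + self.z_mean.bias.size,
                "z_log_var": self.z_log_var.weight.size + self.z_log_var.bias.size,
            }
        elif part == "decoder":
            rows = {
                "z_sampling": 0,
                "dense": self.dec_dense.weight.size + self.dec_dense.bias.size,
                "reshape": 0,
                "conv2d_transpose_1": self.dec_convt1.n_params,
                "conv2d_transpose_2": self.dec_convt2.n_params,
                "decoder_output": self.dec_out.n_params,
            }
        else:
            raise ValueError("part must be 'encoder' or 'decoder'")
        rows["total"] = sum(rows.values())
        return rows

    # ------------------------------------------------------------------
    def _encode_batch(self, xb, training):
        h = xb
        for layer in (self.enc_conv1, self.enc_relu1, self.enc_conv2,
                      self.enc_relu2, self.enc_flatten, self.enc_dense,
                      self.enc_relu3):
            h = layer.forward(h, training)
        return self.z_mean.forward(h, training), self.z_log_var.forward(h, training)

    def _decode_batch(self, z, training):
        h = self.dec_dense.forward(z, training)
        h = self.dec_relu0.forward(h, training)
        h = h.reshape(-1, self._n2, self._n2, self._f2)
        for layer in (self.dec_convt1, self.dec_relu1, self.dec_convt2,
                      self.dec_relu2, self.dec_out, self.dec_sigmoid):
            h = layer.forward(h, training)
        return h

    def encode(self, matrices) -> tuple[np.ndarray, np.ndarray]:
        """Posterior (mu, log_var) for a batch of raw correlation matrices."""
        arr = (np.stack([m.values for m in matrices])
               if not isinstance(matrices, np.ndarray) else np.asarray(matrices, float))
        single = arr.ndim == 2
        if single:
            arr = arr[None]
        if arr.shape[1] != self.n_rois:
            raise ValueError(f"expected {self.n_rois}x{self.n_rois} matrices")
        xb = ((np.clip(arr, -1, 1) + 1) / 2)[..., None]
        mu, lv = self._encode_batch(xb, training=False)
        return (mu[0], lv[0]) if single else (mu, lv)

    # ------------------------------------------------------------------
    def fit(self) -> "VAEResults":
        cfg = self.config
        all_layers = self.encoder_layers + [self.dec_dense, self.dec_convt1,
                                            self.dec_convt2, self.dec_out]
        opt = nn.Adam(all_layers, lr=cfg.learning_rate)
        rng = spawn_rng(cfg.seed, "vae", "train")
        n = self.x.shape[0]
        n_entries = self.n_rois * self.n_rois
        history = []
        for epoch in range(cfg.epochs):
            beta = (min(1.0, (epoch + 1) / cfg.kl_warmup_epochs)
                    if cfg.kl_warmup_epochs > 0 else 1.0)
            order = rng.permutation(n)
            ep_rec, ep_kl = [], []
            for start in range(0, n, cfg.batch_train):
                batch = order[start:start + cfg.batch_train]
                xb = self.x[batch]
                b = xb.shape[0]
                mu, lv = self._encode_batch(xb, training=True)
                eps = rng.standard_normal(mu.shape)
                sigma = np.exp(lv / 2.0)
                z = mu + sigma * eps
                xr = self._decode_batch(z, training=True)
                rec = float(np.sum((xr - xb) ** 2) / b)
                kl = float(np.sum(0.5 * (mu ** 2 + np.exp(lv) - 1.0 - lv)) / b)
                ep_rec.append(rec / n_entries)
                ep_kl.append(kl)
                # backward: d/dxr of sum-squared reconstruction
                dxr = 2.0 * (xr - xb) / b
                d = self.dec_sigmoid.backward(dxr)
                d = self.dec_out.backward(d)
                d = self.dec_relu2.backward(d)
                d = self.dec_convt2.backward(d)
                d = self.dec_relu1.backward(d)
                d = self.dec_convt1.backward(d)
                d = d.reshape(b, -1)
                d = self.dec_relu0.backward(d)
                dz = self.dec_dense.backward(d)
                kl_dim = 0.5 * (mu ** 2 + np.exp(lv) - 1.0 - lv).mean(axis=0)
                active = (kl_dim > cfg.free_bits).astype(float)  # free bits
                dmu = dz + beta * active * mu / b
                dlv = (dz * eps * sigma * 0.5
                       + beta * active * 0.5 * (np.exp(lv) - 1.0) / b)
                dh = self.z_mean.backward(dmu) + self.z_log_var.backward(dlv)
                dh = self.enc_relu3.backward(dh)
                dh = self.enc_dense.backward(dh)
                dh = self.enc_flatten.backward(dh)
                dh = self.enc_relu2.backward(dh)
                dh = self.enc_conv2.backward(dh)
                dh = self.enc_relu1.backward(dh)
                self.enc_conv1.backward(dh)
                opt.step()
            history.append((epoch, float(np.mean(ep_rec)), float(np.mean(ep_kl))))
        hist = pd.DataFrame(history, columns=["epoch", "recon_mse", "kl"])
        return VAEResults(self, hist)


class VAEResults:
    """Fitted VAE: latent codes, reconstructions, loss history, summary."""

    def __init__(self, model: ConnectivityVAE, history: pd.DataFrame):
        self.model = model
        self.history = history

    def latent_means(self, matrices=None) -> np.ndarray:
        if matrices is None:
            mu, _ = self.model._encode_batch(self.model.x, training=False)
            return mu
        mu, _ = self.model.encode(matrices)
        return mu

    def reconstruct(self, matrices=None) -> np.ndarray:
        """Reconstructed matrices mapped back to the correlation scale."""
        if matrices is None:
            mu, _ = self.model._encode_batch(self.model.x, training=False)
        else:
            mu, _ = self.model.encode(matrices)
        xr = self.model._decode_batch(mu, training=False)
        return xr[..., 0] * 2.0 - 1.0

    def plot_history(self, ax=None):
        """Reconstruction and KL loss terms per epoch."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history.epoch, self.history.recon_mse, label="recon MSE/entry")
        ax.plot(self.history.epoch, self.history.kl, label="KL")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss term")
        ax.set_yscale("log")
        ax.legend()
        return ax

    def summary(self) -> str:
        cfg = self.model.config
        enc = self.model.count_params("encoder")["total"]
        dec = self.model.count_params("decoder")["total"]
        return "\n".join([
            "Convolutional VAE over connectivity matrices",
            "=" * 44,
            f"input: {self.model.n_rois}x{self.model.n_rois}   latent dim: {cfg.latent_dim}",
            f"trainable parameters: encoder {enc}, decoder {dec}",
            f"epochs: {len(self.history)}   final recon MSE/entry: "
            f"{self.history.recon_mse.iloc[-1]:.5f}   final KL: "
            f"{self.history.kl.iloc[-1]:.3f}",
        ])


# ---------------------------------------------------------------------------
# latent-space performance-group classifier
# ---------------------------------------------------------------------------

class LatentGroupClassifier:
    """Dense head with 3 sigmoid outputs over the VAE latent space."""

    def __init__(self, classes: np.ndarray, dense: nn.Dense,
                 history: list[float], mean: np.ndarray, std: np.ndarray):
        self.classes_ = classes
        self._dense = dense
        self._sigmoid = nn.Sigmoid()
        self.history = history
        self._mean, self._std = mean, std

    def predict_scores(self, z: np.ndarray) -> np.ndarray:
        zs = (np.asarray(z) - self._mean) / self._std
        return self._sigmoid.forward(self._dense.forward(zs, training=False),
                                     training=False)

    def predict(self, z: np.ndarray) -> np.ndarray:
        """Group labels; score ties resolve to the lowest class index."""
        return self.classes_[np.argmax(self.predict_scores(z), axis=1)]


def train_group_classifier(z: np.ndarray, labels, epochs: int = 50,
                           batch_size: int = 32, lr: float = 0.01,
                           seed: int = 0) -> LatentGroupClassifier:
    """One-vs-all sigmoid head on latent codes, binary cross-entropy loss.

    Classes are ordered (pass, inconsistent, fail); argmax decoding with
    ties toward the lower index.
    """
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels)
    present = [g for g in GROUPS if g in labels]
    if len(present) < 2:
        raise ValueError("latent classifier needs at least 2 groups present")
    classes = np.array(present)
    y_idx = np.array([present.index(l) for l in labels])
    onehot = np.eye(len(present))[y_idx]
    mean, std = z.mean(axis=0), z.std(axis=0)
    std = np.where(std < 1e-6, 1.0, std)  # leave dead latent dims unscaled
    zs = (z - mean) / std
    rng = spawn_rng(seed, "latent-classifier")
    dense = nn.Dense(z.shape[1], len(present), rng)
    sig = nn.Sigmoid()
    opt = nn.Adam([dense], lr=lr)
    history = []
    for _ in range(epochs):
        order = rng.permutation(z.shape[0])
        losses = []
        for start in range(0, z.shape[0], batch_size):
            b = order[start:start + batch_size]
            p = sig.forward(dense.forward(zs[b], training=True), training=True)
            losses.append(nn.binary_cross_entropy(p, onehot[b]))
            dlogits = (p - onehot[b]) / (b.size * p.shape[1])
            dense.backward(dlogits)
            opt.step()
        history.append(float(np.mean(losses)))
    return LatentGroupClassifier(classes, dense, history, mean, std)
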