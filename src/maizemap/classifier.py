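"""The sequence classifier: 3-layer LSTM + fully connected head, trained
with cross-entropy plus weighted center loss.

Each pixel enters as a 4-timestep sequence of 6 band reflectances (the
two-month composites in season order).  A stacked LSTM (3 layers, 128
hidden units) summarises the spectral-temporal trajectory; a 3-layer head
(128 -> 128 -> 64, tanh on the first two layers) maps the summary to a
64-dim discriminative feature f on which the center loss acts; a final
linear + softmax layer yields 4-class probabilities.  Training is 4-class
(maize, soybean, rice, others); mapping is binary — argmax == maize.

Defaults follow the published recipe: Adam, learning rate 0.001, batch
size 20, 250 epochs, center update rate alpha = 0.5.  The center-loss
weight defaults to +0.001: with L = L_ce + w * L_c the weight must be
positive for the term to *penalize* intraclass spread; a negative weight
rewards it and empirically drives the features into saturation and the
accuracy to chance (see docs/methods.md for the experiment).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import losses
from .compositing import CompositeFeatures
from .nn import Adam, Dense, LSTMStack, sigmoid, softmax

NODATA_BYTE = 255


@dataclass
class ClassifierConfig:
    n_timesteps: int = 4
    n_bands: int = 6
    recurrent_layers: int = 3
    hidden_dim: int = 128
    head_dims: tuple[int, int, int] = (128, 128, 64)
    output_activation: str = "softmax"   # or "sigmoid" (per-class, normalised)
    n_classes: int = 4
    learning_rate: float = 0.001
    batch_size: int = 20
    epochs: int = 250
    center_loss_weight: float = 0.001
    center_alpha: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if min(self.hidden_dim, *self.head_dims, self.n_classes) <= 0:
            raise ValueError("all dimensions must be positive")
        if abs(self.center_loss_weight) > 1.0:
            raise ValueError("|center_loss_weight| must be <= 1")
        if not (0.0 < self.center_alpha <= 1.0):
            raise ValueError("center_alpha must be in (0, 1]")
        if self.output_activation not in ("softmax", "sigmoid"):
            raise ValueError("output_activation must be 'softmax' or 'sigmoid'")


class MaizeClassifier:
    """Model state: recurrent extractor, head, output layer, class centers."""

    def __init__(self, config: ClassifierConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.lstm = LSTMStack(config.n_bands, config.hidden_dim,
                              config.recurrent_layers, rng)
        d1, d2, d3 = config.head_dims
        self.fc1 = Dense(config.hidden_dim, d1, "tanh", rng, "fc1")
        self.fc2 = Dense(d1, d2, "tanh", rng, "fc2")
        self.fc3 = Dense(d2, d3, "linear", rng, "fc3")   # -> feature f
        self.out = Dense(d3, config.n_classes, "linear", rng, "out")
        self.centers = np.zeros((config.n_classes, d3))
        self.layers = (self.fc1, self.fc2, self.fc3, self.out)
        self.params: dict[str, np.ndarray] = dict(self.lstm.params)
        for layer in self.layers:
            self.params.update(layer.params)
        self.lstm.params = self.params
        for layer in self.layers:
            layer.params = self.params

    # -- forward -----------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        c = self.config
        if x.ndim != 3 or x.shape[1] != c.n_timesteps or x.shape[2] != c.n_bands:
            raise ValueError(
                f"expected (N, {c.n_timesteps}, {c.n_bands}) input, got {x.shape}")
        return x

    def forward(self, x: np.ndarray, cache: dict | None = None):
        """Return (probabilities (N, C), features (N, 64))."""
        x = self._check_input(x)
        h = self.lstm.forward(x, cache)
        a = self.fc1.forward(h, cache)
        a = self.fc2.forward(a, cache)
        feat = self.fc3.forward(a, cache)
        logits = self.out.forward(feat, cache)
        if self.config.output_activation == "sigmoid":
            s = sigmoid(logits)
            probs = s / s.sum(axis=1, keepdims=True)
        else:
            probs = softmax(logits)
        return probs, feat

    def predict_proba(self, x: np.ndarray, batch: int = 1024) -> np.ndarray:
        x = self._check_input(x)
        return np.vstack([self.forward(x[i:i + batch])[0]
                          for i in range(0, len(x), batch)])

    # -- one training step -------------------------------------------------
    def loss_and_grads(self, x: np.ndarray, labels: np.ndarray):
        """Forward + backward on one batch; returns (l_ce, l_c, grads, feats)."""
        cfg = self.config
        cache: dict = {}
        probs, feat = self.forward(x, cache)
        q = losses.one_hot(labels, cfg.n_classes)
        l_ce = losses.cross_entropy(probs, q)
        l_c = losses.center_loss(feat, labels, self.centers)
        n = x.shape[0]
        if cfg.output_activation == "sigmoid":
            # d l_ce / d logits through normalised per-class sigmoid
            _, a = cache["out"]
            s = sigmoid(a)
            p = s / s.sum(axis=1, keepdims=True)
            dp = -(q / np.clip(p, losses.EPS, None)) / n
            ssum = s.sum(axis=1, keepdims=True)
            dlogits = (dp / ssum - (dp * s).sum(axis=1, keepdims=True) / ssum ** 2) \
                * s * (1.0 - s)
        else:
            dlogits = (probs - q) / n
        grads_out, dfeat = self.out.backward(cache, dlogits)
        dfeat = dfeat + losses.center_loss_grad(feat, labels, self.centers,
                                                cfg.center_loss_weight)
        grads3, da = self.fc3.backward(cache, dfeat)
        grads2, da = self.fc2.backward(cache, da)
        grads1, dh = self.fc1.backward(cache, da)
        grads_lstm = self.lstm.backward(np.asarray(x, float), cache, dh)
        grads = {**grads_lstm, **grads1, **grads2, **grads3, **grads_out}
        return l_ce, l_c, grads, feat

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        header = json.dumps(asdict(self.config))
        np.savez(path, __config__=np.frombuffer(header.encode(), np.uint8),
                 __centers__=self.centers, **self.params)

    @classmethod
    def load(cls, path) -> "MaizeClassifier":
        with np.load(path) as z:
            header = json.loads(bytes(z["__config__"]).decode())
            header["head_dims"] = tuple(header["head_dims"])
            model = cls(ClassifierConfig(**header))
            model.centers = z["__centers__"]
            for k in model.params:
                model.params[k][...] = z[k]
        return model


def build_model(config: ClassifierConfig) -> MaizeClassifier:
    """Deterministically initialised model for the given configuration."""
    return MaizeClassifier(config)


def train(model: MaizeClassifier, x: np.ndarray, labels: np.ndarray,
          log_path=None) -> pd.DataFrame:
    """Mini-batch training with Adam; centers updated after each step.

    Returns the loss history, one row per epoch with columns
    ``epoch, l_ce, l_c, loss, train_acc``; optionally also written as CSV.
    """
    cfg = model.config
    x = model._check_input(x)
    labels = np.asarray(labels, int)
    if not np.isfinite(x).all():
        raise ValueError("training features must be finite (drop invalid pixels)")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x7EA1)))
    opt = Adam(model.params, lr=cfg.learning_rate)
    n = len(x)
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ce_sum = c_sum = correct = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            l_ce, l_c, grads, feat = model.loss_and_grads(x[idx], labels[idx])
            loss = losses.total_loss(l_ce, l_c, cfg.center_loss_weight)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: l_ce={l_ce}, l_c={l_c}")
            opt.step(model.params, grads)
            model.centers = losses.update_centers(model.centers, feat,
                                                  labels[idx], cfg.center_alpha)
            ce_sum += l_ce * len(idx)
            c_sum += l_c
        probs = model.predict_proba(x)
        correct = float((probs.argmax(axis=1) == labels).mean())
        l_ce_ep = ce_sum / n
        l_c_ep = c_sum / n
        history.append((epoch, l_ce_ep, l_c_ep,
                        losses.total_loss(l_ce_ep, l_c_ep, cfg.center_loss_weight),
                        correct))
    hist = pd.DataFrame(history, columns=["epoch", "l_ce", "l_c", "loss", "train_acc"])
    if log_path is not None:
        hist.to_csv(log_path, index=False)
    return hist


def predict_binary(model: MaizeClassifier, composite: CompositeFeatures,
                   maize_class: int = 0) -> np.ndarray:
    """Binary maize map from a composite: 1 = maize, 0 = non-maize,
    255 = nodata (pixels with an invalid compositing period)."""
    h, w = composite.grid_shape
    ok = composite.all_periods_valid
    out = np.full((h, w), NODATA_BYTE, np.uint8)
    if ok.any():
        rows, cols = np.nonzero(ok)
        seq = composite.values[:, :, rows, cols].transpose(2, 0, 1)
        probs = model.predict_proba(seq)
        out[rows, cols] = (probs.argmax(axis=1) == maize_class).astype(np.uint8)
    return out
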