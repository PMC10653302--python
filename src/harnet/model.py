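"""The full activity-recognition model and its training/evaluation surface.

Architecture: SE channel gating → 1-D conv embedding → sinusoidal
positional encoding → sparse-masked Transformer encoder → mean pooling
over time → linear softmax head. Training uses class-weighted
cross-entropy with Adam and per-epoch exponential learning-rate decay.

The public surface follows the model/results idiom: build a
:class:`HARTransformer` from a :class:`~harnet.segmentation.WindowSet`,
call :meth:`~HARTransformer.fit` to obtain a :class:`HARResults` that
carries the trained network, the loss history and evaluation methods.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .attention import AttentionMask, Encoder, EncoderConfig, attention_flops, \
    full_mask, har_mask
from .autodiff import Tensor, cross_entropy, softmax
from .embedding import SEChannelEmbedding, SEConfig
from .layers import Adam, Linear, Module
from .positional import build_pe
from .segmentation import WindowSet, class_weights, stratified_kfold

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "CVReport",
    "HARNetwork",
    "HARTransformer",
    "HARResults",
    "build_model",
    "evaluate_predictions",
    "cross_validate",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the reference protocol:
    learning rate 1e-4, batch 128, 40 epochs, exponential decay)."""

    learning_rate: float = 1e-4
    lr_decay: float = 0.95
    batch_size: int = 128
    epochs: int = 40
    seed: int = 0
    use_class_weights: bool = True

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")


@dataclass
class MetricsReport:
    """Classification metrics computed from a confusion matrix."""

    accuracy: float
    f1: float                   # macro-averaged
    sensitivity: float          # macro-averaged recall
    confusion: np.ndarray       # [K, K], rows = true class

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "f1": self.f1,
                "sensitivity": self.sensitivity,
                "confusion": self.confusion.tolist()}

    def save_json(self, path):
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)

    def save_confusion_csv(self, path):
        np.savetxt(path, self.confusion, fmt="%d", delimiter=",")


@dataclass
class CVReport:
    """Per-fold metrics plus mean ± standard deviation aggregates."""

    per_fold: list[MetricsReport]

    def _values(self, metric: str) -> np.ndarray:
        return np.array([getattr(m, metric) for m in self.per_fold])

    def mean(self, metric: str) -> float:
        return float(self._values(metric).mean())

    def std(self, metric: str) -> float:
        return float(self._values(metric).std())

    def summary(self) -> str:
        lines = [f"{len(self.per_fold)}-fold cross-validation"]
        for metric in ("accuracy", "f1", "sensitivity"):
            lines.append(f"  {metric:<12s} {self.mean(metric):.4f} "
                         f"± {self.std(metric):.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"per_fold": [m.to_dict() for m in self.per_fold],
                "mean": {m: self.mean(m) for m in ("accuracy", "f1", "sensitivity")},
                "std": {m: self.std(m) for m in ("accuracy", "f1", "sensitivity")}}


def evaluate_predictions(y_true, y_pred, num_classes: int) -> MetricsReport:
    """Accuracy, macro F1 and macro sensitivity from labels and predictions.

    Per-class F1 is 2PR/(P+R), taken as 0 when a class has no predicted
    and no true positives; sensitivity is the mean per-class recall.
    """
    labels = np.arange(num_classes)
    conf = _sk_confusion(y_true, y_pred, labels=labels)
    total = conf.sum()
    accuracy = float(np.trace(conf)) / total
    tp = np.diag(conf).astype(float)
    support = conf.sum(axis=1).astype(float)
    predicted = conf.sum(axis=0).astype(float)
    recall = np.divide(tp, support, out=np.zeros_like(tp), where=support > 0)
    precision = np.divide(tp, predicted, out=np.zeros_like(tp), where=predicted > 0)
    pr = precision + recall
    f1 = np.divide(2 * precision * recall, pr, out=np.zeros_like(tp), where=pr > 0)
    return MetricsReport(accuracy, float(f1.mean()), float(recall.mean()), conf)


class HARNetwork(Module):
    """The end-to-end network mapping a [B, C, L] window batch to logits."""

    def __init__(self, n_channels: int, n_classes: int, window_length: int,
                 se_config: SEConfig, encoder_config: EncoderConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        d = encoder_config.d_model
        if se_config.d_model != d:
            raise ValueError(f"embedding output dimension ({se_config.d_model}) must "
                             f"equal the encoder d_model ({d})")
        self.se_config = se_config
        self.encoder_config = encoder_config
        self.n_classes = n_classes
        self.embed = SEChannelEmbedding(n_channels, se_config, rng)
        self.pe_table = build_pe(window_length, d).table.astype(np.float32)
        self.encoder = Encoder(encoder_config, rng)
        self.head = Linear(d, n_classes, rng)
        # mask sampled once at initialisation and fixed during training
        self.mask: AttentionMask = (
            har_mask(window_length, encoder_config, rng.integers(2**31))
            if encoder_config.use_sparse_mask else full_mask(window_length))

    def forward(self, x: Tensor, dropout_rng: np.random.Generator | None = None) -> Tensor:
        h = self.embed(x)                               # [B, t, d]
        # canonical Transformer input scaling: keep the embedding dominant
        # over the unit-amplitude positional encoding
        h = h * float(np.sqrt(self.encoder_config.d_model))
        h = h + Tensor(self.pe_table[None, :h.shape[1]])
        h = self.encoder(h, self.mask, dropout_rng)
        pooled = h.mean(axis=1)                         # [B, d]
        return self.head(pooled)

    def predict_proba(self, values: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities for windows [W, C, L] (or one [C, L] window)."""
        values = np.asarray(values, dtype=np.float32)
        single = values.ndim == 2
        if single:
            values = values[None]
        self.eval()
        out = []
        for start in range(0, len(values), batch_size):
            logits = self.forward(Tensor(values[start:start + batch_size]))
            out.append(softmax(logits).data)
        return out[0][0] if single else np.concatenate(out)

    def predict(self, values: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(values)
        return np.asarray(proba).argmax(axis=-1)

    def flops(self) -> dict:
        """Per-layer attention FLOPs under the network's own mask."""
        cfg = self.encoder_config
        return attention_flops(self.mask.t, cfg.d_model, cfg, mask=self.mask)


def build_model(se_config: SEConfig, encoder_config: EncoderConfig,
                n_classes: int, n_channels: int = 6, window_length: int = 100,
                seed: int = 0) -> HARNetwork:
    """Construct the full network; initial parameters are a deterministic
    function of the seed."""
    net = HARNetwork(n_channels, n_classes, window_length, se_config,
                     encoder_config, seed)
    logger.info("built model with %d parameters", net.num_parameters())
    return net


class HARTransformer:
    """Model object: training data plus architecture configuration.

    Parameters
    ----------
    window_set : WindowSet
        The labeled training windows.
    se_config, encoder_config : optional
        Architecture; defaults are the package's CPU-scale configuration.

    ``fit`` trains a fresh network and returns :class:`HARResults`.
    """

    def __init__(self, window_set: WindowSet, se_config: SEConfig | None = None,
                 encoder_config: EncoderConfig | None = None):
        self.window_set = window_set
        self.se_config = se_config or SEConfig()
        self.encoder_config = encoder_config or EncoderConfig(
            d_model=self.se_config.d_model)
        self.n_classes = window_set.num_classes
        self.n_channels = window_set.values.shape[1]
        self.window_length = window_set.window_length

    @classmethod
    def from_recording(cls, recording, length: int = 100, overlap: float = 0.5,
                       **kwargs) -> "HARTransformer":
        from .segmentation import sliding_window, standardize
        return cls(sliding_window(standardize(recording), length, overlap), **kwargs)

    def fit(self, config: TrainConfig | None = None, **kwargs) -> "HARResults":
        """Train with class-weighted cross-entropy, Adam and exponential
        learning-rate decay; fully reproducible given ``config.seed``."""
        config = config or TrainConfig(**kwargs)
        net = build_model(self.se_config, self.encoder_config, self.n_classes,
                          self.n_channels, self.window_length, config.seed)
        weights = class_weights(self.window_set) if config.use_class_weights else None
        history = _train(net, self.window_set, config, weights)
        return HARResults(self, net, config, history)


def _train(net: HARNetwork, window_set: WindowSet, config: TrainConfig,
           weights: np.ndarray | None) -> list[float]:
    rng = np.random.default_rng(config.seed + 1)
    optimizer = Adam(net.parameters(), lr=config.learning_rate)
    values = window_set.values.astype(np.float32)
    labels = window_set.labels
    n = len(window_set)
    history = []
    net.train()
    start_time = time.time()
    for epoch in range(config.epochs):
        optimizer.lr = config.learning_rate * config.lr_decay**epoch
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = net.forward(Tensor(values[idx]), dropout_rng=rng)
            loss = cross_entropy(logits, labels[idx], weights)
            if not np.isfinite(loss.data):
                raise FloatingPointError("training diverged: loss is not finite")
            net.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(idx)
            seen += len(idx)
        history.append(epoch_loss / seen)
        logger.info("epoch %3d/%d  loss %.4f  lr %.2e  (%.1fs)", epoch + 1,
                    config.epochs, history[-1], optimizer.lr,
                    time.time() - start_time)
    net.eval()
    return history


@dataclass
class HARResults:
    """A fitted model: trained parameters, loss history and evaluation."""

    model: HARTransformer
    network: HARNetwork
    config: TrainConfig
    loss_history: list[float] = field(default_factory=list)

    def predict(self, values: np.ndarray) -> np.ndarray:
        return self.network.predict(values)

    def predict_proba(self, values: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(values)

    def evaluate(self, window_set: WindowSet) -> MetricsReport:
        if len(window_set) == 0:
            raise ValueError("cannot evaluate on an empty window set")
        preds = self.network.predict(window_set.values)
        return evaluate_predictions(window_set.labels, preds,
                                    self.model.n_classes)

    def summary(self) -> str:
        net, flops = self.network, self.network.flops()
        train_metrics = self.evaluate(self.model.window_set)
        lines = [
            "Sparse-attention HAR Transformer",
            "=" * 48,
            f"parameters          {net.num_parameters():>12,d}",
            f"classes / channels  {self.model.n_classes} / {self.model.n_channels}",
            f"window length       {self.model.window_length}",
            f"d_model / heads     {net.encoder_config.d_model} / "
            f"{net.encoder_config.n_heads}",
            f"mask density        {net.mask.density:.3f}",
            f"attention FLOPs     sparse/dense = {flops['ratio']:.3f}",
            f"epochs trained      {len(self.loss_history)}",
            f"final train loss    {self.loss_history[-1]:.4f}" if self.loss_history
            else "final train loss    n/a",
            f"train accuracy      {train_metrics.accuracy:.4f}",
            f"train macro F1      {train_metrics.f1:.4f}",
        ]
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------

    def save(self, path):
        """Checkpoint: parameter arrays (.npz) plus a JSON config sidecar."""
        import os

        state = self.network.state_dict()
        np.savez(path if str(path).endswith(".npz") else f"{path}.npz", **state)
        sidecar = f"{os.path.splitext(str(path))[0]}.json"
        meta = {
            "train_config": asdict(self.config),
            "se_config": {**asdict(self.network.se_config)},
            "encoder_config": {**asdict(self.network.encoder_config)},
            "n_classes": self.model.n_classes,
            "n_channels": self.model.n_channels,
            "window_length": self.model.window_length,
            "loss_history": self.loss_history,
            "mask": self.network.mask.allowed.astype(int).tolist(),
        }
        with open(sidecar, "w") as f:
            json.dump(meta, f)

    @staticmethod
    def load_network(path) -> HARNetwork:
        import os

        base = os.path.splitext(str(path))[0]
        with open(f"{base}.json") as f:
            meta = json.load(f)
        se_cfg = SEConfig(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in meta["se_config"].items()})
        enc_cfg = EncoderConfig(**meta["encoder_config"])
        net = HARNetwork(meta["n_channels"], meta["n_classes"],
                         meta["window_length"], se_cfg, enc_cfg)
        with np.load(f"{base}.npz") as data:
            net.load_state_dict(dict(data))
        net.mask = AttentionMask(np.asarray(meta["mask"], dtype=bool))
        net.eval()
        return net

    def plot_confusion(self, window_set: WindowSet, ax=None):
        """Heatmap of the confusion matrix on a window set."""
        import matplotlib.pyplot as plt

        report = self.evaluate(window_set)
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(report.confusion, cmap="Blues")
        ax.set_xlabel("predicted class")
        ax.set_ylabel("true class")
        ax.figure.colorbar(im, ax=ax)
        return ax


def cross_validate(window_set: WindowSet, folds: int = 5,
                   se_config: SEConfig | None = None,
                   encoder_config: EncoderConfig | None = None,
                   train_config: TrainConfig | None = None,
                   seed: int = 0) -> CVReport:
    """Stratified k-fold cross-validation with a fresh model per fold."""
    train_config = train_config or TrainConfig(seed=seed)
    split = stratified_kfold(window_set, folds, seed)
    reports = []
    for fold in range(folds):
        train_idx, test_idx = split.train_test_indices(fold)
        model = HARTransformer(window_set.subset(train_idx), se_config,
                               encoder_config)
        result = model.fit(train_config)
        reports.append(result.evaluate(window_set.subset(test_idx)))
        logger.info("fold %d/%d  accuracy %.4f  f1 %.4f", fold + 1, folds,
                    reports[-1].accuracy, reports[-1].f1)
    return CVReport(reports)
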