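"""Nystagmus clip classifiers: CNN1D and CNN-LSTM1D, training, evaluation.

Both detectors consume one normalised 1000-sample horizontal gaze trace and
emit a nystagmus probability. CNN1D is a deliberately shallow 14-layer
network — input, three pairs of kernel-3 1D convolutions with max pooling
after the first two pairs, global average pooling, two fully connected
layers with batch normalisation before the last, and a sigmoid output.
CNN-LSTM1D swaps global average pooling for a third max pooling followed by
an LSTM, trading parameters for explicit temporal state. Training uses
Adam (lr 1e-5, batch 32), mean-absolute-error loss against the {0,1} clip
label, early stopping on validation loss, and best-model selection.

The layer widths are configurable: the reference figures of the source
architectures are not fully specified, so the defaults here
([16,16,32,32,64,64] filters, 64-unit FC/LSTM) are chosen for CPU
trainability and documented rather than matched to any printed parameter
total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_curve

from . import nn

__all__ = [
    "DetectorConfig", "TrainConfig", "EvalReport", "DetectorModel",
    "build_cnn1d", "build_cnn_lstm1d", "build_detector",
    "train_detector", "predict", "evaluate",
    "save_detector", "load_detector",
]


@dataclass
class DetectorConfig:
    """Architecture hyperparameters shared by both detectors."""

    architecture: str = "cnn1d"
    input_len: int = 1000
    conv_filters: tuple[int, ...] = (16, 16, 32, 32, 64, 64)
    kernel_size: int = 3
    pool_size: int = 2
    fc_units: int = 64
    lstm_units: int = 64

    @property
    def n_pools(self) -> int:
        return 2 if self.architecture == "cnn1d" else 3

    def validate(self) -> None:
        if self.architecture not in ("cnn1d", "cnn_lstm1d"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if len(self.conv_filters) != 6:
            raise ValueError("conv_filters must list 6 convolution widths")
        if self.input_len % self.pool_size ** self.n_pools:
            raise ValueError(
                f"input_len {self.input_len} not divisible by "
                f"pool_size^{self.n_pools}")

    @classmethod
    def test_profile(cls, architecture="cnn1d", input_len=1000):
        return cls(architecture=architecture, input_len=input_len,
                   conv_filters=(8, 8, 16, 16, 32, 32), fc_units=32,
                   lstm_units=32)


@dataclass
class TrainConfig:
    """Adam / MAE training recipe (defaults follow the reference setup)."""

    learning_rate: float = 1e-5
    batch_size: int = 32
    max_epochs: int = 200
    early_stopping_patience: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 \
                or self.max_epochs <= 0:
            raise ValueError("learning rate, batch size and epochs must be "
                             "positive")


@dataclass
class EvalReport:
    """Confusion-matrix metrics (percent), bootstrap spread, ROC and AUC."""

    tp: int
    fp: int
    tn: int
    fn: int
    metrics: dict[str, float]
    bootstrap_mean: dict[str, float]
    bootstrap_sd: dict[str, float]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    threshold: float = 0.5

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "counts": {"tp": self.tp, "fp": self.fp, "tn": self.tn,
                       "fn": self.fn},
            "metrics": self.metrics,
            "bootstrap_mean": self.bootstrap_mean,
            "bootstrap_sd": self.bootstrap_sd,
            "auc": self.auc,
            "threshold": self.threshold,
            "roc": {"fpr": self.roc_fpr.tolist(),
                    "tpr": self.roc_tpr.tolist()},
        }


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------

class DetectorModel:
    """A detector: engine layers plus the conceptual 14-layer description."""

    def __init__(self, config: DetectorConfig, net: nn.Sequential,
                 layer_names: list[str]):
        self.config = config
        self.net = net
        self.layer_names = layer_names

    @property
    def n_layers(self) -> int:
        """Conceptual depth, counting the input and the output activation."""
        return len(self.layer_names)

    def forward(self, clips: np.ndarray, train: bool = True) -> np.ndarray:
        return self.net.forward(clips[..., None].astype(np.float32), train)

    def n_params(self) -> int:
        return self.net.n_params()


def _conv_stack(cfg: DetectorConfig, rng, n_pools: int) -> list:
    f = cfg.conv_filters
    layers: list = []
    c_in = 1
    for i, c_out in enumerate(f):
        layers += [nn.Conv1D(c_in, c_out, cfg.kernel_size, rng), nn.ReLU()]
        c_in = c_out
        if i in (1, 3) or (i == 5 and n_pools == 3):
            layers.append(nn.MaxPool1D(cfg.pool_size))
    return layers


def build_cnn1d(config: DetectorConfig, seed: int = 0) -> DetectorModel:
    """14-layer CNN1D: conv pairs + pooling, GAP, FC, batch norm, FC, sigmoid."""
    config = _coerce(config, "cnn1d")
    config.validate()
    rng = np.random.default_rng(seed)
    f = config.conv_filters
    layers = _conv_stack(config, rng, n_pools=2)
    layers += [
        nn.GlobalAvgPool1D(),
        nn.Dense(f[5], config.fc_units, rng), nn.ReLU(),
        nn.BatchNorm(config.fc_units),
        nn.Dense(config.fc_units, 1, rng),
    ]
    names = ["input", "conv1", "conv2", "maxpool1", "conv3", "conv4",
             "maxpool2", "conv5", "conv6", "global_avg_pool", "fc1",
             "batch_norm", "fc2", "sigmoid"]
    return DetectorModel(config, nn.Sequential(layers), names)


def build_cnn_lstm1d(config: DetectorConfig, seed: int = 0) -> DetectorModel:
    """14-layer CNN-LSTM1D: GAP replaced by a third max pool and an LSTM."""
    config = _coerce(config, "cnn_lstm1d")
    config.validate()
    rng = np.random.default_rng(seed)
    f = config.conv_filters
    layers = _conv_stack(config, rng, n_pools=3)
    layers += [
        nn.LSTM(f[5], config.lstm_units, rng),
        nn.Dense(config.lstm_units, config.fc_units, rng), nn.ReLU(),
        nn.Dense(config.fc_units, 1, rng),
    ]
    names = ["input", "conv1", "conv2", "maxpool1", "conv3", "conv4",
             "maxpool2", "conv5", "conv6", "maxpool3", "lstm", "fc1", "fc2",
             "sigmoid"]
    return DetectorModel(config, nn.Sequential(layers), names)


def _coerce(config: DetectorConfig, arch: str) -> DetectorConfig:
    cfg = DetectorConfig(**{**asdict(config)})
    cfg.architecture = arch
    cfg.conv_filters = tuple(cfg.conv_filters)
    return cfg


def build_detector(config: DetectorConfig, seed: int = 0) -> DetectorModel:
    builder = build_cnn1d if config.architecture == "cnn1d" else build_cnn_lstm1d
    return builder(config, seed=seed)


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def train_detector(clips: np.ndarray, labels: np.ndarray,
                   detector_config: DetectorConfig,
                   train_config: TrainConfig,
                   val_clips: np.ndarray | None = None,
                   val_labels: np.ndarray | None = None):
    """Train a detector on normalised clips with MAE loss and early stopping.

    When no validation set is supplied, a seeded 10% of the training clips
    is held out to drive early stopping and best-model selection.

    Returns (model, history); history holds per-epoch train/val loss and
    the selected ``best_epoch``.
    """
    detector_config.validate()
    train_config.validate()
    clips = np.asarray(clips, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.float32)
    if clips.ndim != 2 or clips.shape[1] != detector_config.input_len:
        raise ValueError(f"clips must be (N, {detector_config.input_len})")
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(train_config.seed)
    if val_clips is None:
        order = rng.permutation(len(clips))
        n_val = max(1, len(clips) // 10)
        val_idx, train_idx = order[:n_val], order[n_val:]
        val_clips, val_labels = clips[val_idx], labels[val_idx]
        clips, labels = clips[train_idx], labels[train_idx]
    else:
        val_clips = np.asarray(val_clips, dtype=np.float32)
        val_labels = np.asarray(val_labels, dtype=np.float32)

    model = build_detector(detector_config, seed=int(rng.integers(2 ** 31)))
    opt = nn.Adam(model.net.parameters(), model.net.gradients(),
                  lr=train_config.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, None, -1)
    bs = train_config.batch_size
    since_best = 0
    for epoch in range(train_config.max_epochs):
        order = rng.permutation(len(clips))
        losses = []
        for start in range(0, len(clips), bs):
            idx = order[start:start + bs]
            logits = model.forward(clips[idx], train=True)
            loss, grad = nn.mae_on_sigmoid(logits, labels[idx, None])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            model.net.backward(grad)
            opt.step()
            losses.append(loss)
        val_loss = _mae_loss(model, val_clips, val_labels, bs)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, model.net.get_weights(), epoch)
            since_best = 0
        else:
            since_best += 1
            if since_best >= train_config.early_stopping_patience:
                break
    model.net.set_weights(best[1])
    history["best_epoch"] = best[2]
    return model, history


def _mae_loss(model: DetectorModel, clips, labels, batch_size) -> float:
    total = 0.0
    for start in range(0, len(clips), batch_size):
        batch = clips[start:start + batch_size]
        logits = model.forward(batch, train=False)
        loss, _ = nn.mae_on_sigmoid(logits, labels[start:start + batch_size,
                                                   None])
        total += loss * len(batch)
    return float(total / len(clips))


def predict(model: DetectorModel, clips: np.ndarray) -> np.ndarray:
    """Nystagmus scores in [0, 1], one per clip."""
    clips = np.asarray(clips, dtype=np.float32)
    if clips.ndim == 1:
        clips = clips[None]
    if clips.shape[1] != model.config.input_len:
        raise ValueError(f"clips must have length {model.config.input_len}")
    scores = []
    for start in range(0, len(clips), 256):
        logits = model.forward(clips[start:start + 256], train=False)
        scores.append(nn.sigmoid(logits[:, 0]))
    return np.concatenate(scores)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _confusion_metrics(tp, fp, tn, fn) -> dict[str, float]:
    def ratio(num, den):
        return 100.0 * num / den if den > 0 else np.nan

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    acc = ratio(tp + tn, tp + tn + fp + fn)
    f1 = (2 * prec * sens / (prec + sens)
          if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
          else np.nan)
    return {"sensitivity": sens, "specificity": spec, "precision": prec,
            "accuracy": acc, "f1": f1}


def evaluate(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5,
             bootstrap_reps: int = 1000, seed: int = 0) -> EvalReport:
    """Score a detector against clip labels.

    Hard calls at ``threshold`` give the confusion matrix and the percent
    metrics; their +/- spread is the standard deviation over bootstrap
    resamples of the evaluation set (replicates where a metric is undefined
    are excluded for that metric). The ROC sweeps the threshold over all
    distinct scores and the AUC is its trapezoid-rule area.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present (ROC undefined)")
    calls = scores > threshold
    pos = labels == 1
    tp = int(np.sum(calls & pos))
    fp = int(np.sum(calls & ~pos))
    fn = int(np.sum(~calls & pos))
    tn = int(np.sum(~calls & ~pos))
    metrics = _confusion_metrics(tp, fp, tn, fn)

    rng = np.random.default_rng(seed)
    boot = {k: [] for k in metrics}
    n = len(scores)
    for _ in range(bootstrap_reps):
        idx = rng.integers(0, n, n)
        c, p = calls[idx], pos[idx]
        m = _confusion_metrics(int(np.sum(c & p)), int(np.sum(c & ~p)),
                               int(np.sum(~c & ~p)), int(np.sum(~c & p)))
        for k, v in m.items():
            if np.isfinite(v):
                boot[k].append(v)
    bmean = {k: float(np.mean(v)) if v else np.nan for k, v in boot.items()}
    bsd = {k: float(np.std(v)) if v else np.nan for k, v in boot.items()}

    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, metrics=metrics,
                      bootstrap_mean=bmean, bootstrap_sd=bsd,
                      roc_fpr=fpr, roc_tpr=tpr, auc=auc, threshold=threshold)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_detector(path: str | Path, model: DetectorModel) -> None:
    """Single-file checkpoint: config JSON + flat weight arrays (npz)."""
    cfg = asdict(model.config)
    cfg["conv_filters"] = list(cfg["conv_filters"])
    arrays = {f"w{i}": w for i, w in enumerate(model.net.get_weights())}
    np.savez(path, config=json.dumps(cfg), **arrays)


def load_detector(path: str | Path) -> DetectorModel:
    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["config"]))
        cfg["conv_filters"] = tuple(cfg["conv_filters"])
        model = build_detector(DetectorConfig(**cfg))
        weights = [data[f"w{i}"] for i in range(len(model.net.get_weights()))]
    model.net.set_weights(weights)
    return model
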