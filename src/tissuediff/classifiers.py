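"""The three tissue classifiers and their training procedures.

* ``train_rf`` -- random forest baseline (100 Gini-split trees) on single
  9-feature measurement points.
* ``train_ae_nn`` -- fully connected network combining an autoencoder
  (9 -> 32 -> 9 latent -> 32 -> 9) with a classifier head (latent -> 4 -> 2),
  trained end to end with the combined loss
  ``loss = CE(logits, y) + alpha * MSE(reconstruction, input)``; the
  reconstruction term regularizes the latent space.  At inference the decoder
  is discarded and only the classifier output is used.
* ``train_cnn`` -- 1D residual network over sliding windows of 64 samples:
  a stem convolution (9 -> 16 channels) followed by three residual blocks of
  two convolutions each (16 -> 32 stride 2, 32 -> 32 stride 2, 32 -> 64
  stride 2; kernel 7 throughout; batch norm and dropout after every
  convolution), global average pooling and a fully connected layer to two
  logits.  A prediction is made for the last sample of each window, so the
  first 63 samples of a recording are never scored.

Both networks train with Adam (initial learning rate 0.01, weight decay
0.001), a x0.1 learning-rate drop on a training-loss plateau, batch size
16384 and early stopping on validation macro F1 with best-weights restore.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score

from ._nn import (
    Adam,
    BatchNorm1d,
    Conv1d,
    Dropout,
    EarlyStopper,
    GlobalAvgPool1d,
    Linear,
    PlateauScheduler,
    ReLU,
    cross_entropy,
    mse,
    softmax,
)

__all__ = [
    "RFConfig",
    "AEClassifierConfig",
    "CNNConfig",
    "TrainConfig",
    "TrainedClassifier",
    "combined_loss",
    "train_rf",
    "train_ae_nn",
    "train_cnn",
    "make_windows",
    "smoke_train_config",
]


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 100
    split_criterion: str = "gini"
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class AEClassifierConfig:
    input_dim: int = 9
    encoder_hidden: int = 32
    latent_dim: int = 9
    decoder_hidden: int = 32
    clf_hidden: int = 4
    n_classes: int = 2
    alpha: float = 0.3          # weight of the reconstruction loss
    dropout: float = 0.3
    input_noise_sigma: float = 0.1

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        for name in ("input_dim", "encoder_hidden", "latent_dim",
                     "decoder_hidden", "clf_hidden", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_parameters(self) -> int:
        """Closed-form parameter count implied by the layer sizes."""
        d, e, z, c, k = (self.input_dim, self.encoder_hidden, self.latent_dim,
                         self.decoder_hidden, self.clf_hidden)
        return (d * e + e) + (e * z + z) + (z * c + c) + (c * d + d) \
            + (z * k + k) + (k * self.n_classes + self.n_classes)


@dataclass(frozen=True)
class CNNConfig:
    window: int = 64
    in_channels: int = 9
    stem_channels: int = 16
    block_channels: tuple[int, ...] = (32, 32, 64)
    block_stride: int = 2
    kernel: int = 7
    dropout: float = 0.3
    n_classes: int = 2

    def __post_init__(self):
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        if self.window < self.block_stride ** len(self.block_channels):
            raise ValueError("window shorter than the total downsampling factor")

    @property
    def n_conv_layers(self) -> int:
        """Main-path convolutions: one stem + two per residual block."""
        return 1 + 2 * len(self.block_channels)


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.01
    lr_decay_factor: float = 0.1
    plateau_patience: int = 20
    plateau_rel_threshold: float = 1e-4
    early_stopping_patience: int = 50
    max_epochs: int = 2000
    batch_size: int = 16384
    weight_decay: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0 < self.lr_decay_factor < 1:
            raise ValueError("lr_decay_factor must be in (0, 1)")


def smoke_train_config(seed: int = 0, max_epochs: int = 25) -> TrainConfig:
    """Reduced training budget for quick end-to-end runs and CI."""
    return TrainConfig(max_epochs=max_epochs, batch_size=1024,
                       plateau_patience=5, early_stopping_patience=10,
                       seed=seed)


# ---------------------------------------------------------------------------
# Combined loss
# ---------------------------------------------------------------------------

def combined_loss(clf_logits: np.ndarray, labels: np.ndarray,
                  reconstruction: np.ndarray, target_input: np.ndarray,
                  alpha: float) -> float:
    """Cross-entropy of the classifier plus alpha times the autoencoder MSE.

    Both terms are batch-mean reduced; at ``alpha = 0`` or under perfect
    reconstruction the value equals the cross-entropy alone.
    """
    clf_logits = np.atleast_2d(np.asarray(clf_logits, dtype=float))
    labels = np.atleast_1d(np.asarray(labels))
    reconstruction = np.atleast_2d(np.asarray(reconstruction, dtype=float))
    target_input = np.atleast_2d(np.asarray(target_input, dtype=float))
    ce, _ = cross_entropy(clf_logits, labels)
    ae, _ = mse(reconstruction, target_input)
    return float(ce + alpha * ae)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class AENet:
    """Autoencoder + classifier sharing the latent layer (see module docstring)."""

    def __init__(self, cfg: AEClassifierConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.enc1 = Linear(cfg.input_dim, cfg.encoder_hidden, rng)
        self.enc_act = ReLU()
        self.enc_drop = Dropout(cfg.dropout, rng)
        self.enc2 = Linear(cfg.encoder_hidden, cfg.latent_dim, rng)
        self.dec1 = Linear(cfg.latent_dim, cfg.decoder_hidden, rng)
        self.dec_act = ReLU()
        self.dec2 = Linear(cfg.decoder_hidden, cfg.input_dim, rng)
        self.clf1 = Linear(cfg.latent_dim, cfg.clf_hidden, rng)
        self.clf_act = ReLU()
        self.clf_drop = Dropout(cfg.dropout, rng)
        self.clf2 = Linear(cfg.clf_hidden, cfg.n_classes, rng)
        self._linears = [self.enc1, self.enc2, self.dec1, self.dec2,
                         self.clf1, self.clf2]

    def params(self):
        return [p for layer in self._linears for p in layer.params()]

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x, train=False):
        h = self.enc_drop.forward(self.enc_act.forward(self.enc1.forward(x, train), train), train)
        z = self.enc2.forward(h, train)
        r = self.dec2.forward(self.dec_act.forward(self.dec1.forward(z, train), train), train)
        c = self.clf_drop.forward(self.clf_act.forward(self.clf1.forward(z, train), train), train)
        logits = self.clf2.forward(c, train)
        return logits, r

    def backward(self, dlogits, drecon):
        dz_clf = self.clf1.backward(
            self.clf_act.backward(self.clf_drop.backward(self.clf2.backward(dlogits)))
        )
        dz_dec = self.dec1.backward(self.dec_act.backward(self.dec2.backward(drecon)))
        dh = self.enc2.backward(dz_clf + dz_dec)
        return self.enc1.backward(self.enc_act.backward(self.enc_drop.backward(dh)))

    def get_state(self):
        return [p.value.copy() for p in self.params()]

    def set_state(self, state):
        for p, v in zip(self.params(), state):
            p.value = v.copy()


class ResBlock:
    """Two kernel-7 convolutions with a shortcut.

    The first convolution applies the block stride and (possibly) the channel
    change; the shortcut is the identity when shapes match and a 1x1
    stride-matched projection (plus batch norm) otherwise.  Layer order is
    conv -> batch norm -> ReLU -> dropout, with the residual addition before
    the second activation.
    """

    def __init__(self, c_in, c_out, kernel, stride, dropout, rng, dtype=np.float32):
        pad = kernel // 2
        self.conv1 = Conv1d(c_in, c_out, kernel, stride, pad, rng, dtype)
        self.bn1 = BatchNorm1d(c_out, dtype=dtype)
        self.act1 = ReLU()
        self.drop1 = Dropout(dropout, rng)
        self.conv2 = Conv1d(c_out, c_out, kernel, 1, pad, rng, dtype)
        self.bn2 = BatchNorm1d(c_out, dtype=dtype)
        self.act2 = ReLU()
        self.drop2 = Dropout(dropout, rng)
        if stride != 1 or c_in != c_out:
            self.proj = Conv1d(c_in, c_out, 1, stride, 0, rng, dtype)
            self.bn_proj = BatchNorm1d(c_out, dtype=dtype)
        else:
            self.proj = None
            self.bn_proj = None

    def layers(self):
        out = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.proj is not None:
            out += [self.proj, self.bn_proj]
        return out

    def params(self):
        return [p for layer in self.layers() for p in layer.params()]

    def bn_layers(self):
        return [l for l in self.layers() if isinstance(l, BatchNorm1d)]

    def forward(self, x, train=False):
        y = self.drop1.forward(
            self.act1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train),
            train,
        )
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        if self.proj is not None:
            s = self.bn_proj.forward(self.proj.forward(x, train), train)
        else:
            s = x
        return self.drop2.forward(self.act2.forward(y + s, train), train)

    def backward(self, d):
        d = self.act2.backward(self.drop2.backward(d))
        dmain = self.conv2.backward(self.bn2.backward(d))
        dmain = self.conv1.backward(
            self.bn1.backward(self.act1.backward(self.drop1.backward(dmain)))
        )
        if self.proj is not None:
            dskip = self.proj.backward(self.bn_proj.backward(d))
        else:
            dskip = d
        return dmain + dskip


class ResNet1d:
    """Seven-convolution 1D residual classifier over fixed-length windows."""

    def __init__(self, cfg: CNNConfig, rng: np.random.Generator, dtype=np.float32):
        # float32 by default: halves memory traffic of the im2col products
        # with no effect on classification quality at this scale
        self.cfg = cfg
        pad = cfg.kernel // 2
        self.stem = Conv1d(cfg.in_channels, cfg.stem_channels, cfg.kernel, 1, pad, rng, dtype)
        self.stem_bn = BatchNorm1d(cfg.stem_channels, dtype=dtype)
        self.stem_act = ReLU()
        self.stem_drop = Dropout(cfg.dropout, rng)
        self.blocks = []
        c_prev = cfg.stem_channels
        for c_out in cfg.block_channels:
            self.blocks.append(
                ResBlock(c_prev, c_out, cfg.kernel, cfg.block_stride, cfg.dropout,
                         rng, dtype)
            )
            c_prev = c_out
        self.pool = GlobalAvgPool1d()
        self.fc = Linear(c_prev, cfg.n_classes, rng, dtype)

    def params(self):
        out = self.stem.params() + self.stem_bn.params()
        for b in self.blocks:
            out += b.params()
        return out + self.fc.params()

    def bn_layers(self):
        out = [self.stem_bn]
        for b in self.blocks:
            out += b.bn_layers()
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def temporal_trace(self, window: int | None = None) -> list[int]:
        """Temporal length after the stem and after each residual block."""
        L = self.cfg.window if window is None else window
        pad = self.cfg.kernel // 2
        trace = [Conv1d.out_length(L, self.cfg.kernel, 1, pad)]
        for _ in self.cfg.block_channels:
            trace.append(
                Conv1d.out_length(trace[-1], self.cfg.kernel, self.cfg.block_stride, pad)
            )
        return trace

    def forward(self, x, train=False):
        y = self.stem_drop.forward(
            self.stem_act.forward(self.stem_bn.forward(self.stem.forward(x, train), train), train),
            train,
        )
        for b in self.blocks:
            y = b.forward(y, train)
        return self.fc.forward(self.pool.forward(y, train), train)

    def backward(self, dlogits):
        d = self.pool.backward(self.fc.backward(dlogits))
        for b in reversed(self.blocks):
            d = b.backward(d)
        return self.stem.backward(
            self.stem_bn.backward(self.stem_act.backward(self.stem_drop.backward(d)))
        )

    def get_state(self):
        state = [p.value.copy() for p in self.params()]
        for bn in self.bn_layers():
            state.append(bn.running_mean.copy())
            state.append(bn.running_var.copy())
        return state

    def set_state(self, state):
        n = len(self.params())
        for p, v in zip(self.params(), state[:n]):
            p.value = v.copy()
        rest = state[n:]
        for i, bn in enumerate(self.bn_layers()):
            bn.running_mean = rest[2 * i].copy()
            bn.running_var = rest[2 * i + 1].copy()


# ---------------------------------------------------------------------------
# Trained-model contract
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    """Uniform probabilistic-prediction wrapper for RF, NN and CNN.

    ``predict_proba`` takes per-sample feature vectors (RF/NN) or windows of
    shape (n, channels, window) (CNN) and returns class probabilities whose
    columns follow ``classes``.
    """

    kind: str
    classes: np.ndarray
    _predict: Callable[[np.ndarray], np.ndarray]
    config: object = None
    history: pd.DataFrame | None = None

    def predict_proba(self, inputs: np.ndarray) -> np.ndarray:
        probs = self._predict(np.asarray(inputs, dtype=float))
        return probs

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.predict_proba(inputs), axis=1)]


def _encode_labels(y, classes=None):
    y = np.asarray(y)
    if classes is None:
        classes = np.unique(y)
    index = {c: i for i, c in enumerate(classes)}
    return np.array([index[v] for v in y], dtype=int), np.asarray(classes)


# ---------------------------------------------------------------------------
# Random forest baseline
# ---------------------------------------------------------------------------

def train_rf(X: np.ndarray, y: Sequence, config: RFConfig = RFConfig()) -> TrainedClassifier:
    """Fit the 100-tree Gini random forest on per-sample feature vectors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least two classes")
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion=config.split_criterion,
        random_state=config.seed,
    )
    model.fit(X, y)

    def _predict(inputs):
        return model.predict_proba(inputs)

    return TrainedClassifier(kind="rf", classes=np.asarray(model.classes_),
                             _predict=_predict, config=config)


# ---------------------------------------------------------------------------
# Shared network-training loop pieces
# ---------------------------------------------------------------------------

def _minibatches(n, batch_size, rng):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _macro_f1(y_true_idx, y_pred_idx):
    return f1_score(y_true_idx, y_pred_idx, average="macro", zero_division=0)


def train_ae_nn(X_train, y_train, X_val, y_val,
                model_cfg: AEClassifierConfig = AEClassifierConfig(),
                train_cfg: TrainConfig = TrainConfig()) -> TrainedClassifier:
    """Train the autoencoder-regularized classifier end to end.

    Inputs are expected normalized; Gaussian noise with
    ``model_cfg.input_noise_sigma`` is added to training batches only, and
    the reconstruction target is the (noisy) network input.  Early stopping
    monitors validation macro F1 and restores the best weights; validation
    must be non-empty and recording-disjoint from training.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    if X_val.shape[0] == 0:
        raise ValueError("validation set must be non-empty (early stopping)")
    y_idx, classes = _encode_labels(y_train)
    yv_idx, _ = _encode_labels(y_val, classes)

    rng = np.random.default_rng(train_cfg.seed)
    net = AENet(model_cfg, rng)
    opt = Adam(net.params(), lr=train_cfg.lr, weight_decay=train_cfg.weight_decay)
    sched = PlateauScheduler(opt, factor=train_cfg.lr_decay_factor,
                             patience=train_cfg.plateau_patience,
                             rel_threshold=train_cfg.plateau_rel_threshold)
    stopper = EarlyStopper(patience=train_cfg.early_stopping_patience, mode="max")
    history = []

    n = X_train.shape[0]
    for epoch in range(train_cfg.max_epochs):
        losses = []
        for idx in _minibatches(n, train_cfg.batch_size, rng):
            xb = X_train[idx]
            if model_cfg.input_noise_sigma > 0:
                xb = xb + rng.normal(0.0, model_cfg.input_noise_sigma, size=xb.shape)
            yb = y_idx[idx]
            logits, recon = net.forward(xb, train=True)
            ce, dlogits = cross_entropy(logits, yb)
            ae, drecon = mse(recon, xb)
            opt.zero_grad()
            net.backward(dlogits, model_cfg.alpha * drecon)
            opt.step()
            losses.append(ce + model_cfg.alpha * ae)
        train_loss = float(np.mean(losses))

        logits_v, recon_v = net.forward(X_val, train=False)
        ce_v, _ = cross_entropy(logits_v, yv_idx)
        ae_v, _ = mse(recon_v, X_val)
        val_loss = float(ce_v + model_cfg.alpha * ae_v)
        val_f1 = _macro_f1(yv_idx, np.argmax(logits_v, axis=1))
        history.append((epoch, train_loss, val_loss, val_f1))

        sched.step(train_loss)
        if stopper.step(val_f1, net.get_state()):
            break
    if stopper.best_state is not None:
        net.set_state(stopper.best_state)

    def _predict(inputs):
        logits, _ = net.forward(np.atleast_2d(inputs), train=False)
        return softmax(logits)

    hist = pd.DataFrame(history, columns=["epoch", "train_loss", "val_loss", "val_f1"])
    clf = TrainedClassifier(kind="nn", classes=classes, _predict=_predict,
                            config=model_cfg, history=hist)
    clf.network = net
    return clf


# ---------------------------------------------------------------------------
# Sliding windows and the CNN
# ---------------------------------------------------------------------------

def make_windows(recording_samples: np.ndarray, window: int):
    """All contiguous windows ending at each predictable sample.

    Returns ``(windows, target_indices)`` where ``windows[i]`` is the slice
    ``[t - window + 1, t]`` for target ``t = target_indices[i]``; a sample is
    predictable only if ``window - 1`` previous samples exist, so a series of
    length T yields ``max(T - window + 1, 0)`` windows.  Windows never cross
    recording boundaries (the function sees one recording at a time).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    samples = np.asarray(recording_samples, dtype=float)
    C, T = samples.shape
    if T < window:
        return np.empty((0, C, window)), np.empty(0, dtype=int)
    win = np.lib.stride_tricks.sliding_window_view(samples, window, axis=1)
    windows = np.ascontiguousarray(win.transpose(1, 0, 2))
    targets = np.arange(window - 1, T)
    return windows, targets


def _stack_recording_windows(recordings, window):
    """(windows, labels, recording_ids, target_indices) pooled over recordings."""
    xs, ys, rids, tgts = [], [], [], []
    for samples, label, rid in recordings:
        w, t = make_windows(samples, window)
        if w.shape[0] == 0:
            continue
        xs.append(w)
        ys.append(np.repeat(label, w.shape[0]))
        rids.append(np.repeat(rid, w.shape[0]))
        tgts.append(t)
    if not xs:
        raise ValueError("no windows could be formed from the given recordings")
    return (np.concatenate(xs), np.concatenate(ys),
            np.concatenate(rids), np.concatenate(tgts))


def train_cnn(train_recordings, val_recordings,
              model_cfg: CNNConfig = CNNConfig(),
              train_cfg: TrainConfig = TrainConfig()) -> TrainedClassifier:
    """Train the residual CNN on pooled, shuffled windows from all recordings.

    ``train_recordings``/``val_recordings`` are sequences of
    ``(samples, label, recording_id)`` with ``samples`` of shape
    (channels, T), already filtered and normalized.  Cross-entropy loss;
    early stopping on validation macro F1 with best-weights restore.
    """
    Xtr, ytr, _, _ = _stack_recording_windows(train_recordings, model_cfg.window)
    Xva, yva, _, _ = _stack_recording_windows(val_recordings, model_cfg.window)
    y_idx, classes = _encode_labels(ytr)
    yv_idx, _ = _encode_labels(yva, classes)

    rng = np.random.default_rng(train_cfg.seed)
    net = ResNet1d(model_cfg, rng)
    opt = Adam(net.params(), lr=train_cfg.lr, weight_decay=train_cfg.weight_decay)
    sched = PlateauScheduler(opt, factor=train_cfg.lr_decay_factor,
                             patience=train_cfg.plateau_patience,
                             rel_threshold=train_cfg.plateau_rel_threshold)
    stopper = EarlyStopper(patience=train_cfg.early_stopping_patience, mode="max")
    history = []

    n = Xtr.shape[0]
    for epoch in range(train_cfg.max_epochs):
        losses = []
        for idx in _minibatches(n, train_cfg.batch_size, rng):
            logits = net.forward(Xtr[idx], train=True)
            ce, dlogits = cross_entropy(logits, y_idx[idx])
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(ce)
        train_loss = float(np.mean(losses))

        logits_v = _forward_chunked(net, Xva)
        ce_v, _ = cross_entropy(logits_v, yv_idx)
        val_f1 = _macro_f1(yv_idx, np.argmax(logits_v, axis=1))
        history.append((epoch, train_loss, float(ce_v), val_f1))

        sched.step(train_loss)
        if stopper.step(val_f1, net.get_state()):
            break
    if stopper.best_state is not None:
        net.set_state(stopper.best_state)

    def _predict(inputs):
        inputs = np.asarray(inputs, dtype=float)
        if inputs.ndim == 2:
            inputs = inputs[None]
        return softmax(_forward_chunked(net, inputs))

    hist = pd.DataFrame(history, columns=["epoch", "train_loss", "val_loss", "val_f1"])
    clf = TrainedClassifier(kind="cnn", classes=classes, _predict=_predict,
                            config=model_cfg, history=hist)
    clf.network = net
    return clf


def _forward_chunked(net, X, chunk=8192):
    outs = [net.forward(X[i : i + chunk], train=False) for i in range(0, X.shape[0], chunk)]
    return np.concatenate(outs) if len(outs) > 1 else outs[0]


def predict_recording_proba(model: TrainedClassifier, samples: np.ndarray,
                            window: int | None = None):
    """CNN probabilities for one recording, aligned to target sample indices.

    Returns ``(probs, target_indices)``; samples with fewer than
    ``window - 1`` predecessors receive no prediction.
    """
    if window is None:
        window = model.config.window
    windows, targets = make_windows(samples, window)
    if windows.shape[0] == 0:
        return np.empty((0, len(model.classes))), targets
    return model.predict_proba(windows), targets
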