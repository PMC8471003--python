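"""1-D convolutional network for spectra classification.

Topology (fixed across all studies): three Convolution -> ReLU -> MaxPooling
blocks with 8, 10, and 12 filters, kernel size 5, convolution stride 1, pool
size 2 (non-overlapping), no padding; a final affine projection from the
flattened features to the class scores; softmax output for multi-class
problems, sigmoid for binary. Inputs are mean-normalized per sample
(subtraction of the feature-vector mean) at the first layer.

Training protocol: full-batch ADAM at learning rate 1e-4 with cross-entropy
loss; 30% of the training samples (stratified) held out as a validation set
for monitoring; training stops when the training loss has not decreased for
400 epochs, or after 1000 epochs. Ten replicate networks are trained per
assessment, each from a distinct derived seed. Testing is subject-wise:
all spectra of one construct rebuild per class are withheld.

The implementation is NumPy throughout (sliding-window convolutions with
einsum contractions); networks of this size train in seconds on a CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .constructs import StudyDesign
from .io import Dataset
from .spectra import FeatureVector, fiber_index

FiberSpec = Union[str, Sequence[str]]


@dataclass
class CNNConfig:
    """Architecture and training protocol parameters."""

    conv_filters: Tuple[int, int, int] = (8, 10, 12)
    kernel_size: int = 5
    conv_stride: int = 1
    pool_size: int = 2
    head: str = "auto"  # "multiclass" | "binary" | "auto" (binary iff 2 classes)
    learning_rate: float = 1e-4
    max_epochs: int = 1000
    patience_epochs: int = 400
    validation_fraction: float = 0.30
    n_replicates: int = 10

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.conv_stride != 1:
            raise ValueError("only convolution stride 1 is supported")
        if self.max_epochs < 1 or self.patience_epochs < 1:
            raise ValueError("epoch limits must be >= 1")
        if self.head not in ("auto", "multiclass", "binary"):
            raise ValueError(f"unknown head {self.head!r}")


def _block_output_length(length: int, kernel: int, pool: int) -> int:
    return (length - kernel + 1) // pool


def parse_fiber_spec(spec: FiberSpec) -> Tuple[str, ...]:
    """Normalize a fiber spec ('R5', 'R1R5', ('R5','R1')) to an ordered tuple."""
    if isinstance(spec, str):
        parts = tuple("R" + p for p in spec.replace(" ", "").split("R") if p)
    else:
        parts = tuple(spec)
    parts = tuple(sorted(parts, key=fiber_index))
    if len(parts) not in (1, 2) or len(set(parts)) != len(parts):
        raise ValueError(f"fiber spec must name 1 or 2 distinct fibers: {spec!r}")
    return parts


def fiber_spec_name(spec: FiberSpec) -> str:
    return "".join(parse_fiber_spec(spec))


class CNN1D:
    """The three-block 1-D CNN with an affine head. See module docstring."""

    def __init__(self, config: CNNConfig, input_length: int, n_classes: int,
                 rng: np.random.Generator):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.config = config
        self.input_length = int(input_length)
        self.n_classes = int(n_classes)
        self.binary = (config.head == "binary") or (
            config.head == "auto" and n_classes == 2
        )
        if self.binary and n_classes != 2:
            raise ValueError("binary head requires exactly 2 classes")

        k, pool = config.kernel_size, config.pool_size
        lengths = [self.input_length]
        for _ in config.conv_filters:
            nxt = _block_output_length(lengths[-1], k, pool)
            if nxt < 1:
                raise ValueError(
                    f"input length {input_length} too short for "
                    f"{len(config.conv_filters)} conv/pool blocks"
                )
            lengths.append(nxt)
        self.block_lengths = lengths
        n_out = 1 if self.binary else n_classes
        channels = (1,) + tuple(config.conv_filters)
        self.params: Dict[str, np.ndarray] = {}
        for i in range(3):
            fan_in = channels[i] * k
            self.params[f"w{i}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (channels[i + 1], channels[i], k)
            ).astype(np.float32)
            self.params[f"b{i}"] = np.zeros(channels[i + 1], dtype=np.float32)
        flat = config.conv_filters[-1] * lengths[-1]
        self.params["wd"] = rng.normal(0.0, np.sqrt(2.0 / flat), (flat, n_out)).astype(
            np.float32
        )
        self.params["bd"] = np.zeros(n_out, dtype=np.float32)

    # -- forward/backward -------------------------------------------------

    def _forward(self, x: np.ndarray, cache: Optional[dict] = None) -> np.ndarray:
        """Logits for x of shape (N, input_length)."""
        if x.shape[1] != self.input_length:
            raise ValueError(
                f"feature length {x.shape[1]} != model input length {self.input_length}"
            )
        h = x.astype(np.float32) - x.mean(axis=1, keepdims=True).astype(np.float32)
        h = h[:, None, :]
        k, pool = self.config.kernel_size, self.config.pool_size
        for i in range(3):
            w, b = self.params[f"w{i}"], self.params[f"b{i}"]
            win = sliding_window_view(h, k, axis=2)  # (N, C, Lo, k)
            conv = np.einsum("nclk,fck->nfl", win, w, optimize=True) + b[:, None]
            relu = np.maximum(conv, 0.0)
            lo = (relu.shape[2] // pool) * pool
            blocks = relu[:, :, :lo].reshape(relu.shape[0], relu.shape[1], -1, pool)
            idx = blocks.argmax(axis=3)
            pooled = np.take_along_axis(blocks, idx[..., None], axis=3)[..., 0]
            if cache is not None:
                cache[i] = (h, win, conv, relu.shape, lo, idx)
            h = pooled
        flat = h.reshape(h.shape[0], -1)
        if cache is not None:
            cache["flat"] = flat
            cache["pooled_shape"] = h.shape
        return flat @ self.params["wd"] + self.params["bd"]

    def _backward(self, cache: dict, dlogits: np.ndarray) -> Dict[str, np.ndarray]:
        grads: Dict[str, np.ndarray] = {}
        flat = cache["flat"]
        grads["wd"] = flat.T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dh = (dlogits @ self.params["wd"].T).reshape(cache["pooled_shape"])
        k, pool = self.config.kernel_size, self.config.pool_size
        for i in (2, 1, 0):
            h_in, win, conv, relu_shape, lo, idx = cache[i]
            # unpool: route gradient to the argmax position of each window
            dblocks = np.zeros((dh.shape[0], dh.shape[1], dh.shape[2], pool), dtype=np.float32)
            np.put_along_axis(dblocks, idx[..., None], dh[..., None], axis=3)
            drelu = np.zeros(relu_shape, dtype=np.float32)
            drelu[:, :, :lo] = dblocks.reshape(dh.shape[0], dh.shape[1], lo)
            dconv = drelu * (conv > 0)
            w = self.params[f"w{i}"]
            grads[f"w{i}"] = np.einsum("nclk,nfl->fck", win, dconv, optimize=True)
            grads[f"b{i}"] = dconv.sum(axis=(0, 2))
            if i > 0:
                pad = np.zeros(
                    (dconv.shape[0], dconv.shape[1], dconv.shape[2] + 2 * (k - 1)),
                    dtype=np.float32,
                )
                pad[:, :, k - 1 : k - 1 + dconv.shape[2]] = dconv
                gwin = sliding_window_view(pad, k, axis=2)  # (N, F, L_in, k)
                dh = np.einsum("nflk,fck->ncl", gwin, w[:, :, ::-1], optimize=True)
        return grads

    def _loss_and_grad(self, logits: np.ndarray, y: np.ndarray) -> tuple:
        n = logits.shape[0]
        if self.binary:
            z = logits[:, 0]
            p = 1.0 / (1.0 + np.exp(-z))
            eps = 1e-12
            loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
            dlogits = ((p - y) / n)[:, None].astype(np.float32)
        else:
            shifted = logits - logits.max(axis=1, keepdims=True)
            logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
            loss = -np.mean(logp[np.arange(n), y])
            p = np.exp(logp)
            p[np.arange(n), y] -= 1.0
            dlogits = (p / n).astype(np.float32)
        return float(loss), dlogits

    # -- public API --------------------------------------------------------

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (N, n_classes); rows sum to 1."""
        logits = self._forward(np.atleast_2d(np.asarray(x, dtype=np.float32)))
        if self.binary:
            p1 = 1.0 / (1.0 + np.exp(-logits[:, 0]))
            return np.stack([1.0 - p1, p1], axis=1)
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=1, keepdims=True)

    def fit(self, x: np.ndarray, y: np.ndarray,
            x_val: Optional[np.ndarray] = None,
            y_val: Optional[np.ndarray] = None) -> pd.DataFrame:
        """Full-batch ADAM training with the early-stopping rule.

        Returns the per-epoch history (training loss/accuracy and, when a
        validation set is given, validation loss/accuracy).
        """
        cfg = self.config
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(va) for k, va in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best_loss, best_epoch = np.inf, 0
        history = []
        for epoch in range(cfg.max_epochs):
            cache: dict = {}
            logits = self._forward(x, cache)
            loss, dlogits = self._loss_and_grad(logits, y)
            grads = self._backward(cache, dlogits)
            t = epoch + 1
            for key, g in grads.items():
                m[key] = beta1 * m[key] + (1 - beta1) * g
                v[key] = beta2 * v[key] + (1 - beta2) * g * g
                mhat = m[key] / (1 - beta1**t)
                vhat = v[key] / (1 - beta2**t)
                self.params[key] -= (cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)).astype(
                    np.float32
                )
            rec = {"epoch": epoch, "train_loss": loss,
                   "train_accuracy": self._accuracy(logits, y)}
            if x_val is not None and len(x_val):
                vlogits = self._forward(np.asarray(x_val, dtype=np.float32))
                vloss, _ = self._loss_and_grad(vlogits, np.asarray(y_val))
                rec["val_loss"] = vloss
                rec["val_accuracy"] = self._accuracy(vlogits, np.asarray(y_val))
            history.append(rec)
            if loss < best_loss:
                best_loss, best_epoch = loss, epoch
            elif epoch - best_epoch >= cfg.patience_epochs:
                break
        return pd.DataFrame(history)

    def save(self, path) -> None:
        """Serialize parameters and architecture to a .npz checkpoint."""
        meta = dict(
            input_length=self.input_length,
            n_classes=self.n_classes,
            head="binary" if self.binary else "multiclass",
            conv_filters=np.asarray(self.config.conv_filters),
            kernel_size=self.config.kernel_size,
            pool_size=self.config.pool_size,
            learning_rate=self.config.learning_rate,
        )
        np.savez(path, **self.params, **{f"meta_{k}": v for k, v in meta.items()})

    @classmethod
    def load(cls, path) -> "CNN1D":
        """Restore a model from a checkpoint written by :meth:`save`."""
        data = np.load(path)
        config = CNNConfig(
            conv_filters=tuple(int(f) for f in data["meta_conv_filters"]),
            kernel_size=int(data["meta_kernel_size"]),
            pool_size=int(data["meta_pool_size"]),
            learning_rate=float(data["meta_learning_rate"]),
            head=str(data["meta_head"]),
        )
        model = cls(
            config,
            int(data["meta_input_length"]),
            int(data["meta_n_classes"]),
            np.random.default_rng(0),
        )
        for key in model.params:
            model.params[key] = data[key]
        return model

    def _accuracy(self, logits: np.ndarray, y: np.ndarray) -> float:
        if self.binary:
            pred = (logits[:, 0] >= 0.0).astype(int)
        else:
            pred = logits.argmax(axis=1)
        return float(np.mean(pred == y))


def build_model(config: CNNConfig, input_length: int, n_classes: int,
                seed: int = 0) -> CNN1D:
    """Untrained CNN for the given input length and class count."""
    return CNN1D(config, input_length, n_classes, np.random.default_rng(seed))


def predict(model: CNN1D, features, classes: Sequence[str]) -> tuple:
    """Probabilities and argmax class label for one feature vector.

    Ties in the argmax resolve to the lowest class index. ``features`` may be
    a :class:`FeatureVector` or a plain array.
    """
    values = features.values if isinstance(features, FeatureVector) else np.asarray(features)
    if values.ndim != 1:
        raise ValueError("predict takes a single flat feature vector")
    if values.size != model.input_length:
        raise ValueError(
            f"feature length {values.size} != model input length {model.input_length}"
        )
    probs = model.predict_proba(values[None, :])[0]
    return probs, classes[int(np.argmax(probs))]


# -- dataset -> features ----------------------------------------------------


def build_feature_matrix(dataset: Dataset, design: StudyDesign,
                         fiber_spec: FiberSpec) -> tuple:
    """Mean-normalized feature matrix for one fiber or fiber pair.

    Returns ``(X, y, rebuilds)`` where ``y`` indexes into ``design.classes``.
    For a pair, the k-th spectra of the two fibers within each class x
    rebuild cell are concatenated (lower fiber index first), matching the
    acquisition in which both fibers record each probe placement.
    """
    fibers = parse_fiber_spec(fiber_spec)
    mani = dataset.manifest
    tissue = mani["role"] == "tissue"
    for f in fibers:
        if not np.any(tissue & (mani["fiber_id"] == f)):
            raise ValueError(f"fiber {f!r} absent from the dataset manifest")
    class_index = {c: i for i, c in enumerate(design.classes)}
    norm = dataset.intensities / dataset.intensities.mean(axis=1, keepdims=True)

    def rows_for(f: str) -> pd.DataFrame:
        sel = mani[tissue & (mani["fiber_id"] == f)].copy()
        unknown = set(sel["construct_label"]) - set(design.classes)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} not in design {design.name!r}")
        return sel.sort_values(["construct_label", "rebuild_id", "spectrum_id"])

    if len(fibers) == 1:
        sel = rows_for(fibers[0])
        x = norm[sel.index.to_numpy()]
        y = sel["construct_label"].map(class_index).to_numpy()
        rebuilds = sel["rebuild_id"].to_numpy(dtype=int)
        return x, y, rebuilds

    a, b = (rows_for(f) for f in fibers)
    xs, ys, rbs = [], [], []
    groups_b = {k: g for k, g in b.groupby(["construct_label", "rebuild_id"])}
    for key, ga in a.groupby(["construct_label", "rebuild_id"]):
        gb = groups_b.get(key)
        if gb is None:
            raise ValueError(f"fiber {fibers[1]} has no spectra for cell {key}")
        n = min(len(ga), len(gb))
        ia, ib = ga.index.to_numpy()[:n], gb.index.to_numpy()[:n]
        xs.append(np.concatenate([norm[ia], norm[ib]], axis=1))
        ys.extend([class_index[key[0]]] * n)
        rbs.extend([int(key[1])] * n)
    return np.concatenate(xs, axis=0), np.asarray(ys), np.asarray(rbs)


def subject_wise_split(
    y: np.ndarray,
    rebuilds: np.ndarray,
    rng: np.random.Generator,
    validation_fraction: float = 0.30,
) -> tuple:
    """Subject-wise hold-out split: ``(train_idx, val_idx, test_idx)``.

    For each class one rebuild id is wholly assigned to the test set; 30% of
    the remaining samples, stratified by class, form the validation set. No
    rebuild of a class appears in both train and test.
    """
    y = np.asarray(y)
    rebuilds = np.asarray(rebuilds)
    train, val, test = [], [], []
    for cls in np.unique(y):
        in_cls = np.flatnonzero(y == cls)
        rbs = np.unique(rebuilds[in_cls])
        if rbs.size < 2:
            raise ValueError(f"class {cls} has a single rebuild; cannot hold out")
        held = rng.choice(rbs)
        test_idx = in_cls[rebuilds[in_cls] == held]
        pool = in_cls[rebuilds[in_cls] != held]
        n_val = int(round(validation_fraction * pool.size))
        val_idx = rng.choice(pool, size=n_val, replace=False)
        train_idx = np.setdiff1d(pool, val_idx)
        train.append(train_idx)
        val.append(val_idx)
        test.append(test_idx)
    return (np.sort(np.concatenate(train)),
            np.sort(np.concatenate(val)),
            np.sort(np.concatenate(test)))


@dataclass
class TrainedReplicate:
    """One trained network with its history and held-out test predictions."""

    model: CNN1D
    history: pd.DataFrame
    replicate_index: int
    classes: Tuple[str, ...]
    test_predictions: pd.DataFrame  # columns: truth, prediction, rebuild_id

    @property
    def n_epochs(self) -> int:
        return len(self.history)


def train_replicates(
    dataset: Dataset,
    design: StudyDesign,
    config: CNNConfig,
    fiber_spec: FiberSpec,
    base_seed: int = 0,
) -> List[TrainedReplicate]:
    """Train the replicate networks for one fiber spec under the protocol.

    Each replicate derives its own seed from ``base_seed``, draws its own
    subject-wise hold-out split (rotating the held-out rebuild across
    replicates), trains full-batch, and records argmax predictions on its
    held-out rebuilds. The test set never influences fitting.
    """
    x, y, rebuilds = build_feature_matrix(dataset, design, fiber_spec)
    replicates = []
    for r in range(config.n_replicates):
        rng = np.random.default_rng([base_seed, r])
        tr, va, te = subject_wise_split(y, rebuilds, rng, config.validation_fraction)
        model = CNN1D(config, x.shape[1], design.n_classes, rng)
        history = model.fit(x[tr], y[tr], x[va], y[va])
        probs = model.predict_proba(x[te])
        pred_idx = probs.argmax(axis=1)
        preds = pd.DataFrame(
            {
                "truth": [design.classes[i] for i in y[te]],
                "prediction": [design.classes[i] for i in pred_idx],
                "rebuild_id": rebuilds[te],
            }
        )
        replicates.append(
            TrainedReplicate(
                model=model,
                history=history,
                replicate_index=r,
                classes=design.classes,
                test_predictions=preds,
            )
        )
    return replicates
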