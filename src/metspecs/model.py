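"""The multitask CNN: shared feature blocks, a PAR head and an EE head.

Architecture. A stack of shared convolutional feature blocks — each block is
convolution (along time) -> ReLU -> average pooling -> batch normalisation
-> dropout — feeds two heads:

* Head-1 (physical-activity recognition) takes the final block's features,
  averaged along time for phase invariance, through dense layers to an
  M-way softmax;
* Head-2 (energy expenditure) concatenates pooled features of a
  configurable subset of blocks (default blocks 1 and 2) — each block's
  output is averaged along time and flattened over channel x feature, which
  keeps the head's input low-dimensional and stable to optimise — together
  with the participant's body mass, and maps them through dense layers to a
  single MET estimate, passed through softplus so predictions stay positive.

Losses. Classification uses categorical cross-entropy; regression uses mean
squared error; one-step multitask training combines them as
w1 * L_PAR + w2 * L_EE with w1 + w2 = 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, precision_recall_fscore_support

from .errors import ConfigError, MetspecsError
from .nn import (
    Adam,
    AvgPoolTime,
    BatchNorm,
    ConvTime,
    Dense,
    Dropout,
    Flatten,
    Layer,
    TimePoolFlatten,
    Param,
    ReLU,
    sigmoid,
    softmax,
    softplus,
)

LOG_CLAMP = 1e-12


@dataclass
class MultitaskConfig:
    """Architecture and routing parameters.

    ``head2_block_set`` uses 1-based block indices, matching the routing
    nomenclature "Block 1 + 2".
    """

    input_shape: tuple[int, int] = (1280, 6)  # (time samples, channels)
    n_blocks: int = 4
    kernel_counts: tuple[int, ...] = (16, 32, 64, 128)
    kernel_size: int = 9
    pool_size: int = 4
    dropout_rate: float = 0.2
    head1_dense: tuple[int, ...] = (128, 64)
    head2_dense: tuple[int, ...] = (128, 64)
    head2_block_set: tuple[int, ...] = (1, 2)
    n_classes: int = 6
    use_body_mass: bool = True

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")
        if len(self.kernel_counts) != self.n_blocks:
            raise ConfigError("kernel_counts must list one entry per block")
        if not self.head2_block_set:
            raise ConfigError("head2_block_set must be non-empty")
        bad = [b for b in self.head2_block_set if not 1 <= b <= self.n_blocks]
        if bad:
            raise ConfigError(
                f"head2_block_set indices {bad} outside 1..{self.n_blocks}"
            )
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")


class MultitaskNet:
    """Executable network built from a :class:`MultitaskConfig`."""

    def __init__(self, config: MultitaskConfig, rng: np.random.Generator):
        self.config = config
        T, C = config.input_shape
        self.blocks: list[list[Layer]] = []
        block_shapes: list[tuple[int, int, int]] = []  # (T, C, F) after block
        f_in = 1
        t = T
        for i in range(config.n_blocks):
            f_out = config.kernel_counts[i]
            layers: list[Layer] = [
                ConvTime(f_in, f_out, config.kernel_size, rng),
                ReLU(),
                AvgPoolTime(config.pool_size),
                BatchNorm(f_out),
                Dropout(config.dropout_rate),
            ]
            t = (t - config.kernel_size + 1) // config.pool_size
            if t < 1:
                raise ConfigError(
                    f"block {i + 1} collapses the time axis; fewer blocks or "
                    f"smaller pooling needed for input of {T} samples"
                )
            self.blocks.append(layers)
            block_shapes.append((t, C, f_out))
            f_in = f_out
        self.block_shapes = block_shapes

        # Head-1: final block (time-pooled) -> dense stack -> class logits
        self.head1: list[Layer] = [TimePoolFlatten()]
        n_in = int(np.prod(block_shapes[-1][1:]))
        for width in config.head1_dense:
            self.head1 += [Dense(n_in, width, rng), ReLU()]
            n_in = width
        self.head1.append(Dense(n_in, config.n_classes, rng))

        # Head-2: concat(time-pooled selected block features, body mass) -> dense -> 1
        self._h2_sizes = [int(np.prod(block_shapes[b - 1][1:]))
                          for b in config.head2_block_set]
        n_in = sum(self._h2_sizes) + (1 if config.use_body_mass else 0)
        self.head2: list[Layer] = []
        for width in config.head2_dense:
            self.head2 += [Dense(n_in, width, rng), ReLU()]
            n_in = width
        out = Dense(n_in, 1, rng)
        # start the softplus output near a mid-range MET level
        out.b.value[...] = 3.0
        self.head2.append(out)

    # -- parameter bookkeeping -------------------------------------------
    def shared_params(self) -> list[Param]:
        return [p for layers in self.blocks for l in layers for p in l.params()]

    def head1_params(self) -> list[Param]:
        return [p for l in self.head1 for p in l.params()]

    def head2_params(self) -> list[Param]:
        return [p for l in self.head2 for p in l.params()]

    def all_params(self) -> list[Param]:
        return self.shared_params() + self.head1_params() + self.head2_params()

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.all_params()))

    def state(self) -> list[np.ndarray]:
        """Copies of every parameter and batch-norm running statistic."""
        out = [p.value.copy() for p in self.all_params()]
        for layers in self.blocks:
            for l in layers:
                if isinstance(l, BatchNorm):
                    out += [l.running_mean.copy(), l.running_var.copy()]
        return out

    def frozen_state(self) -> list[np.ndarray]:
        """Copies of shared-block and Head-1 parameters and BN statistics."""
        out = [p.value.copy() for p in self.shared_params() + self.head1_params()]
        for layers in self.blocks:
            for l in layers:
                if isinstance(l, BatchNorm):
                    out += [l.running_mean.copy(), l.running_var.copy()]
        return out

    # -- execution --------------------------------------------------------
    def forward(
        self,
        x: np.ndarray,
        body_mass: np.ndarray | None,
        mode: str,
        rng: np.random.Generator,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Run the network; mode is 'train', 'train_head2' or 'eval'.

        In 'train_head2' mode the shared blocks run in inference mode (no
        dropout, frozen batch-norm statistics), which is what keeps the
        backbone bit-identical during progressive training's second step.

        ``x`` is (B, T, C) in [0, 1]; returns (class probabilities (B, M),
        MET estimates (B,)).
        """
        if mode not in ("train", "eval", "train_head2"):
            raise ConfigError(f"unknown forward mode {mode!r}")
        T, C = self.config.input_shape
        if x.ndim != 3 or x.shape[1:] != (T, C):
            raise ConfigError(
                f"input shape {x.shape[1:]} does not match configured {(T, C)}"
            )
        blocks_train = mode == "train"
        h = x.astype(np.float32)[..., None]  # (B, T, C, 1)
        self._block_out: list[np.ndarray] = []
        for layers in self.blocks:
            for l in layers:
                h = l.forward(h, blocks_train, rng)
            self._block_out.append(h)

        h1 = self._block_out[-1]
        for l in self.head1:
            h1 = l.forward(h1, blocks_train, rng)
        self._logits = h1
        probs = softmax(h1)

        feats = [
            self._block_out[b - 1].mean(axis=1).reshape(x.shape[0], -1)
            for b in self.config.head2_block_set
        ]
        if self.config.use_body_mass:
            if body_mass is None:
                raise ConfigError("model configured with use_body_mass but none given")
            feats.append(np.asarray(body_mass, dtype=np.float32).reshape(-1, 1))
        h2 = np.concatenate(feats, axis=1)
        head_train = mode in ("train", "train_head2")
        for l in self.head2:
            h2 = l.forward(h2, head_train, rng)
        self._z2 = h2[:, 0]
        mets = softplus(self._z2)
        return probs, mets

    def backward(
        self,
        d_logits: np.ndarray | None,
        d_z2: np.ndarray | None,
        backprop_blocks: bool = True,
    ) -> None:
        """Accumulate gradients given upstream loss gradients.

        ``d_logits`` is dL/d(class logits); ``d_z2`` is dL/d(pre-softplus EE
        output). Either may be None to skip that head. With
        ``backprop_blocks=False`` gradients stop at the block outputs
        (used when the backbone is frozen).
        """
        d_block = [None] * len(self.blocks)

        if d_logits is not None:
            g = d_logits
            for l in reversed(self.head1):
                g = l.backward(g)
            d_block[-1] = g

        if d_z2 is not None:
            g = np.asarray(d_z2, dtype=np.float32).reshape(-1, 1)
            for l in reversed(self.head2):
                g = l.backward(g)
            if backprop_blocks:
                offset = 0
                for b, size in zip(self.config.head2_block_set, self._h2_sizes):
                    out = self._block_out[b - 1]
                    B, T = out.shape[:2]
                    piece = g[:, offset : offset + size].reshape(
                        (B, 1) + out.shape[2:]
                    )
                    # undo the time average: spread the gradient over T
                    piece = np.broadcast_to(piece / T, out.shape).astype(np.float32)
                    idx = b - 1
                    d_block[idx] = (
                        piece if d_block[idx] is None else d_block[idx] + piece
                    )
                    offset += size

        if not backprop_blocks:
            return
        grad = None
        for i in reversed(range(len(self.blocks))):
            if d_block[i] is not None:
                grad = d_block[i] if grad is None else grad + d_block[i]
            if grad is None:
                continue
            for l in reversed(self.blocks[i]):
                grad = l.backward(grad)


def build_model(
    config: MultitaskConfig, seed: int | np.random.Generator = 0
) -> MultitaskNet:
    """Instantiate a :class:`MultitaskNet` with seeded weight init."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return MultitaskNet(config, rng)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def loss_par(targets_onehot: np.ndarray, probs: np.ndarray) -> float:
    """Batch-mean categorical cross-entropy; log clamped below at 1e-12."""
    y = np.asarray(targets_onehot, dtype=float)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape:
        raise MetspecsError("targets and probabilities must share a shape")
    per_sample = -(y * np.log(np.maximum(p, LOG_CLAMP))).sum(axis=1)
    return float(per_sample.mean())


def loss_ee(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean squared error between actual and predicted METs."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size == 0:
        raise MetspecsError("loss_ee requires at least one pair")
    return float(np.mean((y - y_hat) ** 2))


def loss_combined(w1: float, w2: float, loss_par_value: float,
                  loss_ee_value: float) -> float:
    """Weighted multitask loss w1 * L_PAR + w2 * L_EE with w1 + w2 = 1."""
    check_loss_weights(w1, w2)
    return w1 * loss_par_value + w2 * loss_ee_value


def check_loss_weights(w1: float, w2: float) -> None:
    if not (0.0 <= w1 <= 1.0 and 0.0 <= w2 <= 1.0):
        raise ConfigError("loss weights must lie in [0, 1]")
    if abs(w1 + w2 - 1.0) > 1e-9:
        raise ConfigError(f"loss weights must sum to 1, got {w1} + {w2}")


def onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.size, n_classes), dtype=np.float32)
    out[np.arange(labels.size), labels] = 1.0
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def regression_metrics(y: np.ndarray, y_hat: np.ndarray) -> tuple[float, float]:
    """(MSE, MAPE) over prediction pairs; MAPE as a fraction of actual."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size == 0:
        raise MetspecsError("regression_metrics requires at least one pair")
    zeros = np.nonzero(y == 0)[0]
    if zeros.size:
        raise MetspecsError(
            f"MAPE undefined for zero actual values at indices {zeros.tolist()}"
        )
    mse = float(np.mean((y - y_hat) ** 2))
    mape = float(np.mean(np.abs(y - y_hat) / np.abs(y)))
    return mse, mape


def classification_metrics(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float, float, float, float]:
    """(accuracy, macro precision, macro recall, macro F1).

    Classes absent from both truth and prediction do not enter the macro
    averages; a class with no predicted samples contributes zero precision.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise MetspecsError("classification_metrics requires at least one pair")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    acc = accuracy_score(y_true, y_pred)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    return float(acc), float(prec), float(rec), float(f1)
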