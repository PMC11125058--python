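"""Scikit-learn style estimator for the multitask activity/EE network.

:class:`MultitaskCNN` exposes the network through the familiar
``fit`` / ``predict`` surface so it composes with sklearn model selection.
``X`` is an array of grayscale sensor images (N, T, C) with values in
[0, 255]; ``y`` is (N, 2) with columns (class index, METs); body mass is a
per-sample side input passed as a fit/predict keyword.

Two training regimes are implemented:

* ``two_step`` (progressive): first the shared blocks and the activity head
  are trained under cross-entropy; then every shared and Head-1 parameter
  is held constant — bit-identical, including batch-norm statistics — while
  the EE head alone is trained under mean squared error.
* ``one_step`` (hard parameter sharing): everything is trained jointly
  under w1 * L_PAR + w2 * L_EE, w1 + w2 = 1.

Both regimes use Adam, a step-decayed learning rate, and early stopping on
the validation loss of whatever is being optimised.
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .errors import ConfigError, TrainingError
from .model import (
    MultitaskConfig,
    MultitaskNet,
    build_model,
    check_loss_weights,
    loss_ee,
    loss_par,
    onehot,
)
from .nn import Adam, sigmoid

_EVAL_BATCH = 256


class MultitaskCNN(BaseEstimator):
    """Multitask CNN classifier/regressor over sensor images.

    Parameters mirror :class:`metspecs.model.MultitaskConfig` plus the
    training hyperparameters (defaults: batch 100, initial learning rate
    2e-5 halved every 10 epochs, at most 200 epochs, patience 25).
    """

    def __init__(
        self,
        n_blocks: int = 4,
        kernel_counts: tuple[int, ...] = (16, 32, 64, 128),
        kernel_size: int = 9,
        pool_size: int = 4,
        dropout_rate: float = 0.2,
        head1_dense: tuple[int, ...] = (128, 64),
        head2_dense: tuple[int, ...] = (128, 64),
        head2_block_set: tuple[int, ...] = (1, 2),
        n_classes: int = 6,
        use_body_mass: bool = True,
        regime: str = "two_step",
        w1: float = 0.5,
        w2: float = 0.5,
        batch_size: int = 100,
        lr: float = 2e-5,
        lr_decay: float = 0.5,
        lr_decay_every: int = 10,
        max_epochs: int = 200,
        patience: int = 25,
        validation_fraction: float = 0.25,
        random_state: int = 0,
    ):
        self.n_blocks = n_blocks
        self.kernel_counts = kernel_counts
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.dropout_rate = dropout_rate
        self.head1_dense = head1_dense
        self.head2_dense = head2_dense
        self.head2_block_set = head2_block_set
        self.n_classes = n_classes
        self.use_body_mass = use_body_mass
        self.regime = regime
        self.w1 = w1
        self.w2 = w2
        self.batch_size = batch_size
        self.lr = lr
        self.lr_decay = lr_decay
        self.lr_decay_every = lr_decay_every
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _config(self, input_shape: tuple[int, int]) -> MultitaskConfig:
        return MultitaskConfig(
            input_shape=input_shape,
            n_blocks=self.n_blocks,
            kernel_counts=tuple(self.kernel_counts),
            kernel_size=self.kernel_size,
            pool_size=self.pool_size,
            dropout_rate=self.dropout_rate,
            head1_dense=tuple(self.head1_dense),
            head2_dense=tuple(self.head2_dense),
            head2_block_set=tuple(self.head2_block_set),
            n_classes=self.n_classes,
            use_body_mass=self.use_body_mass,
        )

    @staticmethod
    def _validate_X(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 3:
            raise ConfigError("X must be (n_samples, time, channels)")
        return X

    def _scale_X(self, X: np.ndarray) -> np.ndarray:
        return X.astype(np.float32) / 255.0

    def _scale_mass(self, body_mass, n: int) -> np.ndarray | None:
        if not self.use_body_mass:
            return None
        if body_mass is None:
            raise ConfigError("use_body_mass=True requires a body_mass array")
        m = np.asarray(body_mass, dtype=np.float32).reshape(-1)
        if m.size != n:
            raise ConfigError("body_mass length must match X")
        return (m - self.mass_mean_) / self.mass_std_

    # ------------------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        body_mass: np.ndarray | None = None,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        body_mass_val: np.ndarray | None = None,
    ) -> "MultitaskCNN":
        """Train under the configured regime.

        ``y`` is (N, 2): integer class index and MET value per window. If no
        explicit validation set is given, a class-stratified
        ``validation_fraction`` split of the training data is held out.
        """
        X = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ConfigError("y must be (n_samples, 2): class index, METs")
        if self.regime not in ("two_step", "one_step"):
            raise ConfigError(f"unknown regime {self.regime!r}")
        if self.regime == "one_step":
            check_loss_weights(self.w1, self.w2)

        rng = np.random.default_rng(self.random_state)
        if X_val is None:
            tr_idx, va_idx = _stratified_split(
                y[:, 0].astype(int), self.validation_fraction, rng
            )
            X, X_val = X[tr_idx], X[va_idx]
            y, y_val = y[tr_idx], y[va_idx]
            if body_mass is not None:
                body_mass = np.asarray(body_mass).reshape(-1)
                body_mass, body_mass_val = body_mass[tr_idx], body_mass[va_idx]
        else:
            X_val = self._validate_X(X_val)
            y_val = np.asarray(y_val, dtype=float)

        if self.use_body_mass:
            if body_mass is None:
                raise ConfigError("use_body_mass=True requires body_mass")
            m = np.asarray(body_mass, dtype=float).reshape(-1)
            self.mass_mean_ = float(m.mean())
            self.mass_std_ = float(m.std()) or 1.0
        else:
            self.mass_mean_, self.mass_std_ = 0.0, 1.0

        input_shape = (int(X.shape[1]), int(X.shape[2]))
        self.net_: MultitaskNet = build_model(self._config(input_shape), rng)
        self.classes_ = np.arange(self.n_classes)
        self.n_parameters_ = self.net_.n_parameters
        self.history_: list[dict] = []

        train = _Split(X, y, self._scale_mass(body_mass, len(X)))
        val = _Split(X_val, y_val, self._scale_mass(body_mass_val, len(X_val)))

        if self.regime == "two_step":
            self._fit_step(train, val, rng, step="head1", w1=1.0, w2=0.0)
            # snapshots for the frozen-backbone contract
            self.post_step1_state_ = self.net_.frozen_state()
            self.step1_val_probs_ = self._forward_eval(val.X, val.mass)[0]
            self._fit_step(train, val, rng, step="head2", w1=0.0, w2=1.0)
        else:
            self._fit_step(train, val, rng, step="joint", w1=self.w1, w2=self.w2)
        return self

    # ------------------------------------------------------------------
    def _fit_step(self, train: "_Split", val: "_Split",
                  rng: np.random.Generator, step: str,
                  w1: float, w2: float) -> None:
        net = self.net_
        if step == "head1":
            params = net.shared_params() + net.head1_params()
            mode = "train"
        elif step == "head2":
            params = net.head2_params()
            mode = "train_head2"
        else:
            params = net.all_params()
            if w2 == 0.0:
                params = net.shared_params() + net.head1_params()
            elif w1 == 0.0:
                params = net.shared_params() + net.head2_params()
            mode = "train"
        opt = Adam(params, self.lr)
        backprop_blocks = step != "head2"

        best_val = np.inf
        best_state = None
        bad_epochs = 0
        n = len(train.X)
        for epoch in range(self.max_epochs):
            opt.lr = self.lr * self.lr_decay ** (epoch // self.lr_decay_every)
            order = rng.permutation(n)
            tr_ce_sum = tr_mse_sum = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                ce, mse = self._train_batch(
                    train, idx, opt, rng, mode, w1, w2, backprop_blocks
                )
                tr_ce_sum += ce * idx.size
                tr_mse_sum += mse * idx.size
            tr_ce, tr_mse = tr_ce_sum / n, tr_mse_sum / n
            va_ce, va_mse = self._eval_losses(val)
            tr_loss = w1 * tr_ce + w2 * tr_mse
            va_loss = w1 * va_ce + w2 * va_mse
            if not np.isfinite(tr_loss) or not np.isfinite(va_loss):
                raise TrainingError(
                    f"non-finite loss in step {step!r} at epoch {epoch}: "
                    f"train={tr_loss}, val={va_loss}"
                )
            self.history_.append(
                {
                    "step": step,
                    "epoch": epoch,
                    "lr": opt.lr,
                    "w1": w1,
                    "w2": w2,
                    "train_ce": tr_ce,
                    "train_mse": tr_mse,
                    "train_loss": tr_loss,
                    "val_ce": va_ce,
                    "val_mse": va_mse,
                    "val_loss": va_loss,
                }
            )
            if va_loss < best_val - 1e-12:
                best_val = va_loss
                best_state = [p.value.copy() for p in params]
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= self.patience:
                    break
        if best_state is not None:
            for p, v in zip(params, best_state):
                p.value[...] = v

    def _train_batch(self, split: "_Split", idx: np.ndarray, opt: Adam,
                     rng: np.random.Generator, mode: str,
                     w1: float, w2: float, backprop_blocks: bool) -> tuple[float, float]:
        net = self.net_
        xb = self._scale_X(split.X[idx])
        mb = None if split.mass is None else split.mass[idx]
        yb_class = split.y[idx, 0].astype(int)
        yb_mets = split.y[idx, 1]
        probs, mets = net.forward(xb, mb, mode, rng)
        B = idx.size
        ce = loss_par(onehot(yb_class, self.n_classes), probs)
        mse = loss_ee(yb_mets, mets)

        d_logits = None
        if w1 != 0.0:
            d_logits = (
                w1 * (probs - onehot(yb_class, self.n_classes)) / B
            ).astype(np.float32)
        d_z2 = None
        if w2 != 0.0:
            d_z2 = (
                w2 * 2.0 * (mets - yb_mets) / B * sigmoid(net._z2)
            ).astype(np.float32)

        opt.zero_grad()
        net.backward(d_logits, d_z2, backprop_blocks=backprop_blocks)
        opt.step()
        return ce, mse

    def _eval_losses(self, split: "_Split") -> tuple[float, float]:
        probs, mets = self._forward_eval(split.X, split.mass, scaled_mass=True)
        y_class = split.y[:, 0].astype(int)
        ce = loss_par(onehot(y_class, self.n_classes), probs)
        mse = loss_ee(split.y[:, 1], mets)
        return ce, mse

    def _forward_eval(self, X, mass, scaled_mass=False):
        net = self.net_
        rng = np.random.default_rng(0)  # never consumed in eval mode
        probs_parts, mets_parts = [], []
        for start in range(0, len(X), _EVAL_BATCH):
            xb = self._scale_X(np.asarray(X[start : start + _EVAL_BATCH]))
            mb = None
            if self.use_body_mass:
                mb = mass[start : start + _EVAL_BATCH]
            p, m = net.forward(xb, mb, "eval", rng)
            probs_parts.append(p)
            mets_parts.append(m)
        return np.concatenate(probs_parts), np.concatenate(mets_parts)

    # ------------------------------------------------------------------
    def predict_proba(self, X: np.ndarray, body_mass=None) -> np.ndarray:
        X = self._validate_X(X)
        mass = self._scale_mass(body_mass, len(X))
        probs, _ = self._forward_eval(X, mass, scaled_mass=True)
        return probs

    def predict(self, X: np.ndarray, body_mass=None) -> np.ndarray:
        """Predicted class indices."""
        return np.argmax(self.predict_proba(X, body_mass), axis=1)

    def predict_mets(self, X: np.ndarray, body_mass=None) -> np.ndarray:
        """Predicted per-window energy expenditure in METs."""
        X = self._validate_X(X)
        mass = self._scale_mass(body_mass, len(X))
        _, mets = self._forward_eval(X, mass, scaled_mass=True)
        return mets


class _Split:
    __slots__ = ("X", "y", "mass")

    def __init__(self, X, y, mass):
        self.X, self.y, self.mass = X, y, mass


def _stratified_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled split into (train, validation) index arrays."""
    tr, va = [], []
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        idx = idx[rng.permutation(idx.size)]
        n_val = max(1, int(round(idx.size * val_fraction))) if idx.size > 1 else 0
        va.extend(idx[:n_val])
        tr.extend(idx[n_val:])
    return np.sort(np.array(tr, dtype=int)), np.sort(np.array(va, dtype=int))
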