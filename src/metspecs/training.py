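"""Leave-one-subject-out training and evaluation.

Every participant serves once as the held-out test subject; the remaining
participants' windows are split 3:1 into training and validation, stratified
by (participant, activity). Test sets contain sequential windows only.
Reported per fold: classification accuracy/precision/recall/F1 over
windows, regression MSE (METs^2) and MAPE over per-window MET predictions,
and a per-activity table of predicted vs. actual steady-state METs (the
steady-state prediction is the mean predicted EE across the activity's
windows). The cross-fold summary is the unweighted mean over folds.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataset import to_arrays
from .errors import ConfigError, InsufficientDataError, IntegrityError
from .estimator import MultitaskCNN
from .model import classification_metrics, regression_metrics
from .types import SensorImage

DEFAULT_W1_GRID = tuple(round(0.1 * k, 1) for k in range(1, 10))


@dataclass
class TrainConfig:
    """Training-regime hyperparameters (defaults as used in the study)."""

    regime: str = "two_step"
    w1: float = 0.3
    w2: float = 0.7
    batch_size: int = 100
    lr: float = 2e-5
    lr_decay: float = 0.5
    lr_decay_every: int = 10
    max_epochs: int = 200
    patience: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.lr <= 0:
            raise ConfigError("lr must be positive")
        if self.regime == "one_step" and abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ConfigError("one_step regime requires w1 + w2 == 1")


@dataclass
class FoldSplit:
    """Index sets of one leave-one-subject-out fold."""

    fold_id: int
    test_participant: str
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class FoldMetrics:
    fold_id: int
    test_participant: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    mse: float
    mape: float
    n_test: int
    per_activity: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def loso_folds(
    windows: list[SensorImage], seed: int = 0, train_fraction: float = 0.75
) -> list[FoldSplit]:
    """One fold per participant; train:val split 3:1 among the rest.

    The held-out participant's test set contains only sequential windows;
    the train/validation split is stratified by (participant, activity) and
    shuffled with ``seed``. Hygiene (no provenance overlap) is asserted.
    """
    pids = sorted({w.participant_id for w in windows})
    if len(pids) < 2:
        raise ConfigError("leave-one-subject-out requires >= 2 participants")
    rng = np.random.default_rng(seed)
    folds = []
    for k, pid in enumerate(pids):
        test_idx = np.array(
            [i for i, w in enumerate(windows)
             if w.participant_id == pid and w.kind == "sequential"],
            dtype=int,
        )
        rest = [i for i, w in enumerate(windows) if w.participant_id != pid]
        strata: dict[tuple[str, str], list[int]] = {}
        for i in rest:
            w = windows[i]
            strata.setdefault((w.participant_id, w.activity_label), []).append(i)
        train_idx, val_idx = [], []
        for key in sorted(strata):
            idx = np.array(strata[key], dtype=int)
            idx = idx[rng.permutation(idx.size)]
            n_train = int(round(idx.size * train_fraction))
            train_idx.extend(idx[:n_train])
            val_idx.extend(idx[n_train:])
        fold = FoldSplit(
            fold_id=k,
            test_participant=pid,
            train_idx=np.sort(np.array(train_idx, dtype=int)),
            val_idx=np.sort(np.array(val_idx, dtype=int)),
            test_idx=test_idx,
        )
        check_fold_hygiene(windows, fold)
        folds.append(fold)
    return folds


def check_fold_hygiene(windows: list[SensorImage], fold: FoldSplit) -> None:
    """No test window provenance in train/val; test is sequential-only."""
    train_val = {windows[i].provenance for i in
                 np.concatenate([fold.train_idx, fold.val_idx])}
    test = {windows[i].provenance for i in fold.test_idx}
    overlap = train_val & test
    if overlap:
        raise IntegrityError(
            f"fold {fold.fold_id}: {len(overlap)} test windows leak into "
            f"training/validation, e.g. {sorted(overlap)[:3]}"
        )
    bad_kind = [i for i in fold.test_idx if windows[i].kind != "sequential"]
    if bad_kind:
        raise IntegrityError(
            f"fold {fold.fold_id}: non-sequential windows in the test set"
        )


def _make_estimator(model_params: dict, cfg: TrainConfig) -> MultitaskCNN:
    return MultitaskCNN(
        **model_params,
        regime=cfg.regime,
        w1=cfg.w1,
        w2=cfg.w2,
        batch_size=cfg.batch_size,
        lr=cfg.lr,
        lr_decay=cfg.lr_decay,
        lr_decay_every=cfg.lr_decay_every,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        random_state=cfg.seed,
    )


def _fit_fold(
    windows: list[SensorImage], fold: FoldSplit,
    model_params: dict, cfg: TrainConfig,
) -> MultitaskCNN:
    X, y, mass = to_arrays(windows)
    est = _make_estimator(model_params, cfg)
    est.fit(
        X[fold.train_idx], y[fold.train_idx], body_mass=mass[fold.train_idx],
        X_val=X[fold.val_idx], y_val=y[fold.val_idx],
        body_mass_val=mass[fold.val_idx],
    )
    return est


def train_two_step(
    windows: list[SensorImage], fold: FoldSplit,
    model_params: dict, config: TrainConfig | None = None,
) -> MultitaskCNN:
    """Progressive training: PAR first, then the frozen-backbone EE head."""
    cfg = config or TrainConfig()
    cfg = TrainConfig(**{**asdict(cfg), "regime": "two_step"})
    return _fit_fold(windows, fold, model_params, cfg)


def train_one_step(
    windows: list[SensorImage], fold: FoldSplit,
    model_params: dict, config: TrainConfig | None = None,
) -> MultitaskCNN:
    """Hard parameter sharing under the combined weighted loss."""
    cfg = config or TrainConfig(regime="one_step")
    cfg = TrainConfig(**{**asdict(cfg), "regime": "one_step"})
    return _fit_fold(windows, fold, model_params, cfg)


def predict_steady_state(
    model: MultitaskCNN, windows: list[SensorImage]
) -> float:
    """Steady-state EE of one activity: mean per-window predicted METs."""
    if not windows:
        raise InsufficientDataError("no windows for steady-state prediction")
    X, _, mass = to_arrays(windows)
    return float(np.mean(model.predict_mets(X, body_mass=mass)))


def evaluate_fold(
    model: MultitaskCNN, windows: list[SensorImage], fold: FoldSplit
) -> FoldMetrics:
    """Test-set metrics of one fold plus the per-activity steady-state table."""
    test = [windows[i] for i in fold.test_idx]
    X, y, mass = to_arrays(test)
    pred_class = model.predict(X, body_mass=mass)
    pred_mets = model.predict_mets(X, body_mass=mass)
    acc, prec, rec, f1 = classification_metrics(y[:, 0].astype(int), pred_class)
    mse, mape = regression_metrics(y[:, 1], pred_mets)

    per_activity = []
    for activity in sorted({w.activity_label for w in test}):
        sel = [w for w in test if w.activity_label == activity]
        idx = [i for i, w in enumerate(test) if w.activity_label == activity]
        per_activity.append(
            {
                "activity": activity,
                "actual_mets": float(sel[0].mets),
                "predicted_mets": float(np.mean(pred_mets[idx])),
                "n_windows": len(sel),
            }
        )
    return FoldMetrics(
        fold_id=fold.fold_id,
        test_participant=fold.test_participant,
        accuracy=acc, precision=prec, recall=rec, f1=f1,
        mse=mse, mape=mape, n_test=len(test),
        per_activity=per_activity,
    )


def summarize(folds: list[FoldMetrics]) -> dict[str, float]:
    """Unweighted cross-fold means of every scalar metric."""
    if not folds:
        raise ConfigError("no folds to summarize")
    keys = ("accuracy", "precision", "recall", "f1", "mse", "mape")
    return {k: float(np.mean([getattr(f, k) for f in folds])) for k in keys}


def run_loso(
    windows: list[SensorImage], model_params: dict,
    config: TrainConfig | None = None, folds: list[FoldSplit] | None = None,
) -> tuple[list[FoldMetrics], dict[str, float]]:
    """Train and evaluate every leave-one-subject-out fold."""
    cfg = config or TrainConfig()
    folds = folds or loso_folds(windows, seed=cfg.seed)
    metrics = []
    for fold in folds:
        model = _fit_fold(windows, fold, model_params, cfg)
        metrics.append(evaluate_fold(model, windows, fold))
    return metrics, summarize(metrics)


def grid_search_w1(
    windows: list[SensorImage], fold: FoldSplit, model_params: dict,
    config: TrainConfig | None = None,
    values: tuple[float, ...] = DEFAULT_W1_GRID,
) -> tuple[pd.DataFrame, float]:
    """One-step training per w1 in the grid; returns (report, chosen w1).

    The report has one row per w1 (accuracy, precision, recall, F1, MSE,
    MAPE on the fold's test set). The balance rule picks, among the rows
    whose accuracy is in the top half, the w1 with the lowest MAPE.
    """
    if not values:
        raise ConfigError("empty w1 grid")
    bad = [v for v in values if not 0.0 < v < 1.0]
    if bad:
        raise ConfigError(f"w1 values outside (0, 1): {bad}")
    cfg = config or TrainConfig(regime="one_step")
    rows = []
    for w1 in values:
        run_cfg = TrainConfig(
            **{**asdict(cfg), "regime": "one_step",
               "w1": float(w1), "w2": round(1.0 - w1, 10)}
        )
        model = _fit_fold(windows, fold, model_params, run_cfg)
        fm = evaluate_fold(model, windows, fold)
        rows.append(
            {"w1": float(w1), "w2": round(1.0 - w1, 10),
             "accuracy": fm.accuracy, "precision": fm.precision,
             "recall": fm.recall, "f1": fm.f1,
             "mse": fm.mse, "mape": fm.mape}
        )
    report = pd.DataFrame(rows)
    acc_cut = report["accuracy"].median()
    top = report[report["accuracy"] >= acc_cut]
    best_w1 = float(top.sort_values(["mape", "w1"]).iloc[0]["w1"])
    return report, best_w1
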