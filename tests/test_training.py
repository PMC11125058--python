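"""Fold construction, hygiene, steady-state aggregation, and reporting."""
import numpy as np
import pandas as pd
import pytest

from metspecs.dataset import to_arrays
from metspecs.errors import ConfigError, InsufficientDataError, IntegrityError
from metspecs.training import (
    FoldMetrics,
    FoldSplit,
    TrainConfig,
    check_fold_hygiene,
    evaluate_fold,
    grid_search_w1,
    loso_folds,
    predict_steady_state,
    summarize,
)
from metspecs.types import SensorImage

from metspecs.bench import make_mini_windows


def _fake_windows(n_participants=6, n_activities=6, n_seq=5, n_rand=5):
    rng = np.random.default_rng(0)
    out = []
    for p in range(n_participants):
        for a in range(n_activities):
            for j in range(n_seq + n_rand):
                out.append(
                    SensorImage(
                        matrix=rng.integers(0, 256, size=(4, 6)),
                        participant_id=f"P{p}",
                        activity_label=f"a{a}",
                        window_start_s=float(600 * a + 10 * j),
                        combo="acc_gyr",
                        kind="sequential" if j < n_seq else "random",
                        body_mass_kg=70.0,
                        mets=2.0 + a,
                        class_index=a,
                    )
                )
    return out


class TestLosoFolds:
    def test_one_fold_per_participant(self):
        windows = _fake_windows()
        folds = loso_folds(windows, seed=0)
        assert len(folds) == 6
        for fold in folds:
            test_pids = {windows[i].participant_id for i in fold.test_idx}
            assert test_pids == {fold.test_participant}

    def test_disjoint_provenance_every_fold(self):
        windows = _fake_windows()
        for fold in loso_folds(windows, seed=1):
            tv = {windows[i].provenance
                  for i in np.concatenate([fold.train_idx, fold.val_idx])}
            te = {windows[i].provenance for i in fold.test_idx}
            assert not tv & te

    def test_test_sets_sequential_only(self):
        windows = _fake_windows()
        for fold in loso_folds(windows, seed=2):
            assert all(windows[i].kind == "sequential" for i in fold.test_idx)

    def test_single_participant_rejected(self):
        with pytest.raises(ConfigError):
            loso_folds(_fake_windows(n_participants=1))

    def test_split_ratio_on_large_set(self):
        """3:1 stratified split within 2% on a 10,000-window set."""
        windows = _fake_windows(n_participants=5, n_activities=5,
                                n_seq=200, n_rand=200)
        assert len(windows) == 10_000
        fold = loso_folds(windows, seed=3)[0]
        ratio = len(fold.train_idx) / (len(fold.train_idx) + len(fold.val_idx))
        assert abs(ratio - 0.75) < 0.02

    def test_hygiene_check_detects_leak(self):
        windows = _fake_windows(n_participants=2)
        fold = loso_folds(windows, seed=0)[0]
        leaked = FoldSplit(
            fold_id=0, test_participant=fold.test_participant,
            train_idx=np.concatenate([fold.train_idx, fold.test_idx[:1]]),
            val_idx=fold.val_idx, test_idx=fold.test_idx,
        )
        with pytest.raises(IntegrityError):
            check_fold_hygiene(windows, leaked)


class _StubModel:
    """Returns canned per-row predictions: class and METs read off labels."""

    def __init__(self, y):
        self._y = y
        self._row = 0

    def predict(self, X, body_mass=None):
        return self._y[: len(X), 0].astype(int)

    def predict_mets(self, X, body_mass=None):
        return self._y[: len(X), 1]


class TestSteadyStatePrediction:
    def test_mean_of_window_predictions(self, mini_windows):
        ws = [w for w in mini_windows if w.class_index == 2][:3]
        stub = _StubModel(np.column_stack([[2, 2, 2], [1.0, 2.0, 3.0]]))
        assert predict_steady_state(stub, ws) == pytest.approx(2.0)

    def test_order_invariance(self, mini_windows):
        ws = [w for w in mini_windows if w.class_index == 0][:4]
        vals = np.array([[0, 1.0], [0, 4.0], [0, 2.0], [0, 3.0]])
        a = predict_steady_state(_StubModel(vals), ws)
        b = predict_steady_state(_StubModel(vals), list(reversed(ws)))
        assert a == pytest.approx(b)

    def test_no_windows_rejected(self):
        with pytest.raises(InsufficientDataError):
            predict_steady_state(_StubModel(np.zeros((0, 2))), [])


class TestEvaluation:
    def test_perfect_model_perfect_metrics(self):
        windows = _fake_windows(n_participants=2)
        fold = loso_folds(windows, seed=0)[0]
        y_test = to_arrays([windows[i] for i in fold.test_idx])[1]
        fm = evaluate_fold(_StubModel(y_test), windows, fold)
        assert (fm.accuracy, fm.precision, fm.recall, fm.f1) == (1, 1, 1, 1)
        assert fm.mse == 0.0 and fm.mape == 0.0
        # steady-state table: exact agreement per activity
        for row in fm.per_activity:
            assert row["predicted_mets"] == pytest.approx(row["actual_mets"])

    def test_summary_of_identical_folds_is_that_fold(self):
        fm = FoldMetrics(0, "P0", 0.9, 0.8, 0.85, 0.82, 0.5, 0.1, 30)
        s = summarize([fm, fm, fm])
        assert s["accuracy"] == pytest.approx(0.9)
        assert s["mse"] == pytest.approx(0.5)
        assert s["mape"] == pytest.approx(0.1)

    def test_summarize_empty_rejected(self):
        with pytest.raises(ConfigError):
            summarize([])


class TestGridSearchW1:
    MODEL = dict(
        n_blocks=2, kernel_counts=(4, 8), kernel_size=9, pool_size=4,
        dropout_rate=0.0, head1_dense=(8,), head2_dense=(8,),
        head2_block_set=(1, 2), n_classes=6, use_body_mass=True,
    )

    @pytest.fixture(scope="class")
    def setup(self):
        windows = make_mini_windows(n_per_class=12, height=120, seed=5)
        fold = loso_folds(windows, seed=0)[0]
        cfg = TrainConfig(regime="one_step", batch_size=32, lr=1e-3,
                          max_epochs=1, patience=2, seed=0)
        return windows, fold, cfg

    def test_report_one_row_per_value_weights_sum_to_one(self, setup):
        windows, fold, cfg = setup
        report, best = grid_search_w1(windows, fold, self.MODEL, cfg,
                                      values=(0.2, 0.5, 0.8))
        assert len(report) == 3
        assert np.allclose(report["w1"] + report["w2"], 1.0)
        assert best in report["w1"].values

    def test_reproducible_given_seed(self, setup):
        windows, fold, cfg = setup
        r1, b1 = grid_search_w1(windows, fold, self.MODEL, cfg, values=(0.3, 0.7))
        r2, b2 = grid_search_w1(windows, fold, self.MODEL, cfg, values=(0.3, 0.7))
        pd.testing.assert_frame_equal(r1, r2)
        assert b1 == b2

    def test_invalid_grid_rejected(self, setup):
        windows, fold, cfg = setup
        with pytest.raises(ConfigError):
            grid_search_w1(windows, fold, self.MODEL, cfg, values=())
        with pytest.raises(ConfigError):
            grid_search_w1(windows, fold, self.MODEL, cfg, values=(0.0, 0.5))


class TestSeparabilityMonotonicity:
    """Held-out accuracy is non-decreasing (in expectation over seeds) as
    the class signal becomes more separable from the pixel noise."""

    MODEL = dict(
        n_blocks=2, kernel_counts=(4, 8), kernel_size=9, pool_size=4,
        dropout_rate=0.1, head1_dense=(16,), head2_dense=(16,),
        head2_block_set=(1, 2), n_classes=6, use_body_mass=True,
    )

    def _mean_accuracy(self, noise_sd):
        from metspecs.training import train_one_step
        accs = []
        for seed in (0, 1, 2):
            windows = make_mini_windows(n_per_class=20, height=200,
                                        seed=seed, noise_sd=noise_sd)
            fold = loso_folds(windows, seed=seed)[0]
            cfg = TrainConfig(regime="one_step", w1=1.0, w2=0.0,
                              batch_size=32, lr=2e-3, max_epochs=20,
                              patience=20, seed=seed)
            model = train_one_step(windows, fold, self.MODEL, cfg)
            accs.append(evaluate_fold(model, windows, fold).accuracy)
        return float(np.mean(accs))

    def test_accuracy_improves_with_separability(self):
        hard, mid, easy = (self._mean_accuracy(n) for n in (300.0, 90.0, 15.0))
        assert hard <= mid + 0.05
        assert mid <= easy + 0.05
        assert easy > hard


def test_train_config_validation():
    with pytest.raises(ConfigError):
        TrainConfig(batch_size=0)
    with pytest.raises(ConfigError):
        TrainConfig(regime="one_step", w1=0.8, w2=0.8)
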