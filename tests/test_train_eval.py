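"""Metric suite (confusion-matrix arithmetic, macro/micro aggregation, AUC vs a
pairwise oracle), schedule callbacks, training smoke behaviour, trials and
cross-validation, activation maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import renalnet.synthetic_data as sd
import renalnet.train_eval as te
from renalnet.model_assembly import build_variant
from renalnet.nn import Adam, EarlyStopping, ReduceLROnPlateau, Tensor


# ------------------------------------------------------------------- metrics

def test_perfect_predictions_score_one():
    y = np.array([0, 1, 2, 3] * 5)
    rep = te.metrics_from_predictions(y, y, scores=np.eye(4)[y])
    assert np.allclose(rep.per_class[["precision", "recall", "f1", "accuracy", "auc"]], 1.0)
    assert all(np.isclose(v, 1.0) for v in rep.overall.values())


def test_hand_binary_confusion_example():
    # confusion [[2,1],[0,3]]: class0 precision 1.0, recall 2/3
    y_true = np.array([0, 0, 0, 1, 1, 1])
    y_pred = np.array([0, 0, 1, 1, 1, 1])
    rep = te.metrics_from_predictions(y_true, y_pred, class_names=("c0", "c1"))
    assert np.array_equal(rep.confusion, [[2, 1], [0, 3]])
    assert rep.per_class.loc["c0", "precision"] == 1.0
    assert np.isclose(rep.per_class.loc["c0", "recall"], 2 / 3)


def test_confusion_conservation_and_balanced_identity(rng):
    y_true = np.repeat(np.arange(4), 25)
    y_pred = rng.integers(0, 4, size=100)
    rep = te.metrics_from_predictions(y_true, y_pred)
    assert rep.confusion.sum() == 100
    assert np.array_equal(rep.confusion.sum(axis=1), np.bincount(y_true, minlength=4))
    assert np.array_equal(rep.confusion.sum(axis=0), np.bincount(y_pred, minlength=4))
    # balanced classes: micro accuracy == macro recall
    assert np.isclose(rep.overall["accuracy"], rep.overall["recall"])


def test_macro_precision_aggregation_worked_example():
    # unweighted mean of the four per-class precisions, reported at 4 decimals
    assert te.macro_average([0.9327, 0.9477, 0.8651, 0.9244]) == 0.9175


def test_absent_class_reported_undefined_and_excluded():
    y_true = np.array([0, 0, 1, 1])
    y_pred = np.array([0, 0, 1, 1])
    with pytest.warns(UserWarning, match="absent"):
        rep = te.metrics_from_predictions(y_true, y_pred)
    assert np.isnan(rep.per_class.loc["KIRP", "precision"])
    assert np.isclose(rep.overall["precision"], 1.0)   # mean over defined classes only


# ----------------------------------------------------------------------- AUC

def _pairwise_auc(pos_scores, neg_scores):
    wins = sum((p > n) + 0.5 * (p == n) for p in pos_scores for n in neg_scores)
    return wins / (len(pos_scores) * len(neg_scores))


def test_separable_scores_auc_one_and_reversal_symmetry():
    labels = np.array([0] * 5 + [1] * 5)
    scores = np.zeros((10, 4))
    scores[:5, 0] = np.linspace(0.9, 1.0, 5)
    scores[5:, 0] = np.linspace(0.0, 0.4, 5)
    scores[:, 1] = 1 - scores[:, 0]
    aucs = te.roc_auc(scores, labels)
    assert aucs["Normal"] == 1.0
    rev = te.roc_auc(-scores, labels)
    assert np.isclose(rev["Normal"], 1.0 - aucs["Normal"])


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 1), st.floats(0, 1, allow_nan=False)),
                min_size=4, max_size=50))
def test_auc_equals_mann_whitney_pair_statistic(pairs):
    labels = np.array([p[0] for p in pairs])
    s = np.array([p[1] for p in pairs])
    if labels.min() == labels.max():
        return  # single-class: undefined, covered below
    scores = np.stack([1 - s, s], axis=1)
    auc = te.roc_auc(scores, labels, class_names=("neg", "pos"))["pos"]
    oracle = _pairwise_auc(s[labels == 1], s[labels == 0])
    assert np.isclose(auc, oracle, atol=1e-12)


def test_single_class_auc_undefined():
    out = te.roc_auc(np.random.default_rng(0).uniform(size=(5, 4)), np.zeros(5, dtype=int))
    assert np.isnan(out["KIRC"])


# ----------------------------------------------------------------- callbacks

def test_plateau_schedule_halves_after_patience():
    opt = Adam([Tensor(np.zeros(1), requires_grad=True)], lr=1e-3)
    sched = ReduceLROnPlateau(opt, factor=0.5, patience=5, min_delta=1e-4)
    sched.step(0.80)
    for _ in range(4):
        sched.step(0.80)      # four stalls: not yet
        assert opt.lr == 1e-3
    sched.step(0.80)          # fifth stall
    assert opt.lr == 5e-4


def test_plateau_schedule_untouched_under_improvement():
    opt = Adam([Tensor(np.zeros(1), requires_grad=True)], lr=1e-3)
    sched = ReduceLROnPlateau(opt, factor=0.5, patience=5, min_delta=1e-4)
    for i in range(20):
        sched.step(0.5 + 0.01 * i)
    assert opt.lr == 1e-3


class _StubModel:
    def __init__(self):
        self.v = 0.0

    def state_dict(self):
        return {"v": np.array(self.v)}

    def load_state_dict(self, s):
        self.v = float(s["v"])


def test_early_stop_restores_best_epoch_weights():
    stop = EarlyStopping(patience=2, min_delta=1e-4, restore_best=True)
    model = _StubModel()
    metrics = [0.5, 0.8, 0.7, 0.7, 0.7]
    stopped_at = None
    for epoch, m in enumerate(metrics):
        model.v = float(epoch)
        if stop.step(m, model, epoch):
            stopped_at = epoch
            break
    stop.finalize(model)
    assert stopped_at == 3          # two stalls after the epoch-1 best
    assert model.v == 1.0 and stop.best_epoch == 1


# ------------------------------------------------------------------ training

@pytest.fixture(scope="module")
def smoke():
    """A small trained model shared by the behavioural tests below."""
    recs = sd.generate_dataset(15, 5, seed=21)      # 60 patches
    X, y = sd.load_arrays(recs, 21, size=32)
    model = build_variant("Proposed", seed=2)
    cfg = te.TrainConfig(epochs=3, seed=2)
    model, hist = te.train(model, (X, y), None, cfg)
    return model, hist, (X, y)


def test_smoke_training_reduces_loss(smoke):
    _, hist, _ = smoke
    assert hist["loss"].iloc[-1] < hist["loss"].iloc[0]
    assert (pd.Series(hist["lr"]).diff().dropna() <= 0).all()  # lr non-increasing


def test_empty_training_set_raises():
    with pytest.raises(ValueError, match="empty"):
        te.train(build_variant("CNN-1", seed=0), (np.zeros((0, 3, 16, 16)), np.zeros(0, int)))


def test_evaluate_report_structure(smoke):
    model, _, (X, y) = smoke
    rep = te.evaluate(model, X, y)
    assert rep.confusion.sum() == len(y)
    assert set(rep.per_class.index) == set(sd.CLASSES)
    assert 0.0 <= rep.overall["accuracy"] <= 1.0


def test_identical_trials_average_equals_single(smoke):
    _, _, (X, y) = smoke
    cfg = te.TrainConfig(epochs=1, seed=3)
    mean, reports, _ = te.run_trials(lambda s: build_variant("CNN-1", seed=s),
                                     (X[:16], y[:16]), None, (X[:16], y[:16]),
                                     n_trials=2, seeds=[7, 7], cfg=cfg)
    assert np.allclose(reports[0].confusion, reports[1].confusion)
    assert np.allclose(mean.confusion, reports[0].confusion)
    for k, v in mean.overall.items():
        lo = min(r.overall[k] for r in reports)
        hi = max(r.overall[k] for r in reports)
        assert lo - 1e-12 <= v <= hi + 1e-12


def test_cross_validation_rotates_folds(small_records):
    cfg = te.TrainConfig(epochs=1, seed=0)
    reports, mean = te.cross_validate(lambda s: build_variant("CNN-1", seed=s),
                                      small_records, base_seed=11, k=4, cfg=cfg, size=16)
    assert len(reports) == 4
    # each fold is the test set exactly once: test sizes sum to the dataset
    assert sum(int(r.confusion.sum()) for r in reports) == len(small_records)
    accs = [r.overall["accuracy"] for r in reports]
    assert np.isclose(mean.overall["accuracy"], np.mean(accs))


def test_validation_split_is_case_respecting(small_records):
    X, y = sd.load_arrays(small_records, 11, size=16)
    cases = [r.case_id for r in small_records]
    (Xtr, ytr), (Xv, yv) = te.split_validation(X, y, cases, frac=0.2, seed=0)
    assert len(yv) and len(ytr) and len(ytr) + len(yv) == len(y)
    idx = {id: i for i, id in enumerate(cases)}
    # rebuild membership by matching rows
    val_rows = {tuple(np.round(r.reshape(-1)[:8], 5)) for r in Xv}
    val_cases = {c for c, x in zip(cases, X) if tuple(np.round(x.reshape(-1)[:8], 5)) in val_rows}
    train_cases = {c for c, x in zip(cases, X)
                   if tuple(np.round(x.reshape(-1)[:8], 5)) not in val_rows}
    assert not (val_cases & train_cases)


# ------------------------------------------------------------ activation maps

def test_activation_map_range_bands_and_overlay(smoke):
    model, _, (X, y) = smoke
    cam = te.activation_map(model, X[0], int(y[0]))
    assert cam.cam.min() >= 0.0 and cam.cam.max() <= 1.0
    assert cam.cam.shape == X[0].shape[1:]
    assert set(np.unique(cam.bands)) <= {0, 1, 2}
    assert np.all(cam.bands[cam.cam >= 0.7] == 2)
    assert np.all(cam.bands[cam.cam < 0.4] == 0)
    assert cam.overlay.dtype == np.uint8 and cam.overlay.shape == (32, 32, 3)


def test_degenerate_model_gives_uniform_map_with_warning():
    model = build_variant("CNN-1", seed=0)
    for p in model.parameters():
        p.data[...] = 0.0
    x = np.random.default_rng(0).normal(size=(3, 16, 16)).astype(np.float32)
    with pytest.warns(UserWarning, match="uniform"):
        cam = te.activation_map(model, x, 0)
    assert cam.uniform and np.all(cam.bands == 0)
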