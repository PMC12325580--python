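"""Training protocol, metric suite, trials/cross-validation, activation maps.

Training follows the reference schedule: Adam at 1e-3, batch size 4,
categorical cross-entropy, 65 epochs, learning rate halved when validation
accuracy plateaus (patience 5, min-delta 1e-4) and early stopping
(patience 30, min-delta 1e-4) with best-weight restoration.

Metric conventions: per-class precision/recall/F1 from the confusion matrix,
per-class accuracy one-vs-rest; "overall" precision/recall/F1 are unweighted
(macro) means over classes while overall accuracy is micro (trace / n) — with
balanced classes micro accuracy equals macro recall.  A class absent from
both truth and prediction has undefined metrics: reported as NaN and excluded
from the macro means with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize
from sklearn.metrics import roc_auc_score

from .nn import Adam, EarlyStopping, ReduceLROnPlateau, Tensor, softmax, softmax_cross_entropy
from .synthetic_data import CLASSES, load_arrays, make_folds

BAND_THRESHOLDS = (0.7, 0.4)   # red above 0.7, orange above 0.4, light blue below
BAND_COLORS = {"red": (1.0, 0.1, 0.1), "orange": (1.0, 0.65, 0.0),
               "lightblue": (0.68, 0.85, 0.95)}


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 4
    epochs: int = 65
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    plateau_min_delta: float = 1e-4
    early_stop_patience: int = 30
    early_stop_min_delta: float = 1e-4
    restore_best: bool = True
    val_frac: float = 0.1
    seed: int = 0


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    confusion: np.ndarray
    per_class: pd.DataFrame            # rows = classes; precision/recall/f1/accuracy/auc
    overall: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = self.per_class.copy()
        df.loc["Overall"] = [self.overall.get(k, np.nan)
                             for k in ["precision", "recall", "f1", "accuracy", "auc"]]
        return df


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (np.asarray(y_true), np.asarray(y_pred)), 1)
    return cm


def metrics_from_predictions(y_true, y_pred, scores=None, class_names=CLASSES) -> MetricsReport:
    n_classes = len(class_names)
    cm = confusion_matrix(y_true, y_pred, n_classes)
    n = cm.sum()
    rows = {}
    for i, name in enumerate(class_names):
        tp = cm[i, i]
        row, col = cm[i].sum(), cm[:, i].sum()
        if row == 0 and col == 0:
            warnings.warn(f"class {name} absent from truth and prediction; metrics undefined")
            rows[name] = dict(precision=np.nan, recall=np.nan, f1=np.nan,
                              accuracy=np.nan, auc=np.nan)
            continue
        prec = tp / col if col else 0.0
        rec = tp / row if row else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        tn = n - row - col + tp
        acc = (tp + tn) / n
        auc = np.nan
        if scores is not None:
            pos = np.asarray(y_true) == i
            if 0 < pos.sum() < len(pos):
                auc = roc_auc_score(pos, np.asarray(scores)[:, i])
        rows[name] = dict(precision=prec, recall=rec, f1=f1, accuracy=acc, auc=auc)
    per_class = pd.DataFrame(rows).T[["precision", "recall", "f1", "accuracy", "auc"]]
    defined = per_class.dropna(subset=["precision"])
    overall = {
        "precision": float(defined["precision"].mean()),
        "recall": float(defined["recall"].mean()),
        "f1": float(defined["f1"].mean()),
        "accuracy": float(np.trace(cm) / n) if n else np.nan,       # micro
        "auc": float(defined["auc"].mean()) if scores is not None else np.nan,
    }
    return MetricsReport(confusion=cm, per_class=per_class, overall=overall)


def macro_average(values, decimals: int = 4) -> float:
    """Unweighted mean of per-class values, rounded as reported."""
    return round(float(np.mean(values)), decimals)


def roc_auc(scores, labels, class_names=CLASSES) -> dict:
    """One-vs-rest area under the ROC curve per class (trapezoidal)."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    out = {}
    for i, name in enumerate(class_names):
        pos = labels == i
        out[name] = (roc_auc_score(pos, scores[:, i])
                     if 0 < pos.sum() < len(pos) else np.nan)
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _predict_scores(model, X, batch: int = 16) -> np.ndarray:
    model.eval()
    outs = []
    for i in range(0, len(X), batch):
        outs.append(softmax(model(Tensor(X[i:i + batch])).data))
    return np.concatenate(outs, axis=0)


def evaluate(model, X, y, class_names=CLASSES) -> MetricsReport:
    """Confusion matrix and the full metric suite on held-out data."""
    scores = _predict_scores(model, X)
    return metrics_from_predictions(y, scores.argmax(axis=1), scores, class_names)


def split_validation(X, y, case_ids=None, frac: float = 0.1, seed: int = 0):
    """Carve a validation subset, case-respecting when case ids are given."""
    rng = np.random.default_rng(seed)
    n = len(y)
    if case_ids is not None:
        cases = pd.unique(np.asarray(case_ids))
        rng.shuffle(cases)
        val_cases, count = set(), 0
        for c in cases:
            if count >= frac * n:
                break
            val_cases.add(c)
            count += int((np.asarray(case_ids) == c).sum())
        mask = np.asarray([c in val_cases for c in case_ids])
    else:
        idx = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[idx[: max(1, int(frac * n))]] = True
    return (X[~mask], y[~mask]), (X[mask], y[mask])


def train(model, train_data, val_data=None, cfg: TrainConfig | None = None):
    """Train a model; returns (model, history DataFrame).

    ``train_data``/``val_data`` are (X, y) arrays, X in NCHW layout.  The
    schedule monitors validation accuracy (training accuracy when no
    validation set is supplied).
    """
    cfg = cfg or TrainConfig()
    X, y = train_data
    if len(X) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    sched = ReduceLROnPlateau(opt, cfg.plateau_factor, cfg.plateau_patience, cfg.plateau_min_delta)
    stopper = EarlyStopping(cfg.early_stop_patience, cfg.early_stop_min_delta, cfg.restore_best)
    hist = {"epoch": [], "loss": [], "acc": [], "val_loss": [], "val_acc": [], "lr": []}

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(X))
        losses, hits = [], 0
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            xb = Tensor(X[sel], requires_grad=False)
            loss = softmax_cross_entropy(model(xb), y[sel])
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            logits = loss._prev[0]
            hits += int((logits.data.argmax(axis=1) == y[sel]).sum())
        tr_loss, tr_acc = float(np.mean(losses)), hits / len(X)

        if val_data is not None and len(val_data[1]):
            scores = _predict_scores(model, val_data[0])
            val_acc = float((scores.argmax(axis=1) == val_data[1]).mean())
            val_loss = float(-np.log(np.clip(
                scores[np.arange(len(val_data[1])), val_data[1]], 1e-12, None)).mean())
        else:
            val_acc, val_loss = tr_acc, tr_loss

        hist["epoch"].append(epoch + 1)
        hist["loss"].append(tr_loss)
        hist["acc"].append(tr_acc)
        hist["val_loss"].append(val_loss)
        hist["val_acc"].append(val_acc)
        hist["lr"].append(opt.lr)

        stop = stopper.step(val_acc, model, epoch)
        sched.step(val_acc)
        if stop:
            break
    stopper.finalize(model)
    return model, pd.DataFrame(hist)


def run_trials(build_fn, train_data, val_data, test_data, n_trials: int = 3,
               seeds=None, cfg: TrainConfig | None = None):
    """Average of independent trials with fresh random weights each time.

    ``build_fn(seed)`` must return a new model.  Returns (mean report,
    per-trial reports, histories)."""
    cfg = cfg or TrainConfig()
    seeds = list(seeds) if seeds is not None else list(range(n_trials))
    reports, histories = [], []
    for s in seeds[:n_trials] if n_trials else []:
        model = build_fn(s)
        trial_cfg = TrainConfig(**{**vars(cfg), "seed": s})
        model, h = train(model, train_data, val_data, trial_cfg)
        reports.append(evaluate(model, *test_data))
        histories.append(h)
    return average_reports(reports), reports, histories


def average_reports(reports) -> MetricsReport:
    """Element-wise mean of several reports."""
    if not reports:
        raise ValueError("no reports to average")
    conf = np.mean([r.confusion for r in reports], axis=0)
    per_class = sum((r.per_class for r in reports), start=reports[0].per_class * 0) / len(reports)
    keys = reports[0].overall
    overall = {k: float(np.mean([r.overall[k] for r in reports])) for k in keys}
    return MetricsReport(confusion=conf, per_class=per_class, overall=overall)


def cross_validate(build_fn, records, base_seed: int, k: int = 5,
                   cfg: TrainConfig | None = None, size: int = 224,
                   model_factory_seed: int = 0, appearance=None):
    """k-fold, case-respecting cross-validation over a record collection.

    Run r trains on every fold but r and tests on fold r.  Returns the per-
    fold reports and their element-wise mean."""
    cfg = cfg or TrainConfig()
    folds = make_folds(records, k=k, seed=base_seed)
    reports = []
    for r in range(1, k + 1):
        tr = [rec for rec in records if folds[rec.case_id] != r]
        te = [rec for rec in records if folds[rec.case_id] == r]
        Xtr, ytr = load_arrays(tr, base_seed, appearance, size=size)
        Xte, yte = load_arrays(te, base_seed, appearance, size=size)
        model = build_fn(model_factory_seed + r)
        model, _ = train(model, (Xtr, ytr), None, cfg)
        reports.append(evaluate(model, Xte, yte))
    return reports, average_reports(reports)


# ---------------------------------------------------------------------------
# Activation maps
# ---------------------------------------------------------------------------

@dataclass
class ActivationMap:
    cam: np.ndarray          # normalised [0,1], image-sized
    bands: np.ndarray        # 2 = red (high), 1 = orange (medium), 0 = light blue (low)
    overlay: np.ndarray      # uint8 RGB
    uniform: bool = False


def activation_map(model, image: np.ndarray, target_class: int,
                   feature: str = "feat", alpha: float = 0.45) -> ActivationMap:
    """Gradient-weighted class-activation map over the pre-classifier features.

    Channel weights are the spatial means of d(class logit)/d(feature map);
    the weighted, rectified sum is min-max normalised, upsampled to the input
    size and banded into high (red), medium (orange) and low (light blue)
    regions at 0.7 / 0.4.
    """
    model.eval()
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3:
        raise ValueError("expected a single CHW image")
    x = Tensor(img[None], requires_grad=True)
    logits, feats = model(x, return_features=True)
    fmap = feats[feature]
    onehot = np.zeros_like(logits.data)
    onehot[0, target_class] = 1.0
    (logits * Tensor(onehot)).sum().backward()
    if fmap.grad is None:
        raise RuntimeError("feature map received no gradient")
    w = fmap.grad[0].mean(axis=(1, 2))                       # (C,)
    cam = np.maximum((w[:, None, None] * fmap.data[0]).sum(axis=0), 0.0)
    rng_span = cam.max() - cam.min()
    uniform = bool(rng_span < 1e-12)
    if uniform:
        warnings.warn("activation map is spatially uniform (degenerate/untrained model)")
        cam = np.zeros_like(cam)
    else:
        cam = (cam - cam.min()) / rng_span
    H, W = img.shape[1], img.shape[2]
    cam_up = resize(cam, (H, W), order=1, mode="reflect", anti_aliasing=False)
    cam_up = np.clip(cam_up, 0.0, 1.0)
    bands = np.where(cam_up >= BAND_THRESHOLDS[0], 2,
                     np.where(cam_up >= BAND_THRESHOLDS[1], 1, 0)).astype(np.int8)
    color = np.empty((H, W, 3), dtype=np.float32)
    for b, name in ((2, "red"), (1, "orange"), (0, "lightblue")):
        color[bands == b] = BAND_COLORS[name]
    base = img.transpose(1, 2, 0)
    base = (base - base.min()) / max(base.max() - base.min(), 1e-8)
    overlay = ((1 - alpha) * base + alpha * color)
    overlay = (np.clip(overlay, 0, 1) * 255 + 0.5).astype(np.uint8)
    return ActivationMap(cam=cam_up, bands=bands, overlay=overlay, uniform=uniform)
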