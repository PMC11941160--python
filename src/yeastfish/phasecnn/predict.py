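"""Prediction, per-class confidence filtering and cross-validated metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as sk_confusion, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from yeastfish.phasecnn import layers as L
from yeastfish.phasecnn.model import CLASSES, CnnConfig, build_model
from yeastfish.phasecnn.train import softmax, train


@dataclass
class PhasePrediction:
    cell_id: int
    class_scores: np.ndarray  # 9 probabilities summing to 1
    label: str
    confidence: float
    retained: bool = True


def predict_scores(
    model: L.Sequential, x: np.ndarray, batch_size: int = 128
) -> np.ndarray:
    """Softmax class scores for an array of composites (NHWC or NCHW)."""
    if x.shape[-1] in (1, 3) and x.shape[1] not in (1, 3):
        x = x.transpose(0, 3, 1, 2)
    x = np.ascontiguousarray(x, dtype=np.float32)
    out = []
    for i in range(0, len(x), batch_size):
        out.append(softmax(model.forward(x[i : i + batch_size], train=False)))
    return np.vstack(out)


def predict_filtered(
    model: L.Sequential,
    x: np.ndarray,
    cell_ids: np.ndarray | None = None,
    filter_fraction: float = 0.2,
    batch_size: int = 128,
) -> list[PhasePrediction]:
    """Predictions with the least-confident fraction of each predicted
    class marked as not retained.

    For every predicted class, the floor(filter_fraction * n_class) cells
    with the lowest confidence are dropped; ties at the cutoff are broken
    by cell id, so the result is deterministic.
    """
    if not 0.0 <= filter_fraction < 1.0:
        raise ValueError("filter_fraction must lie in [0, 1)")
    scores = predict_scores(model, x, batch_size)
    if cell_ids is None:
        cell_ids = np.arange(len(scores))
    labels = scores.argmax(axis=1)
    conf = scores[np.arange(len(scores)), labels]
    preds = [
        PhasePrediction(
            cell_id=int(cid),
            class_scores=s,
            label=CLASSES[l],
            confidence=float(c),
        )
        for cid, s, l, c in zip(cell_ids, scores, labels, conf)
    ]
    for cls in range(len(CLASSES)):
        members = [i for i in range(len(preds)) if labels[i] == cls]
        n_drop = int(np.floor(filter_fraction * len(members)))
        if n_drop == 0:
            continue
        members.sort(key=lambda i: (preds[i].confidence, preds[i].cell_id))
        for i in members[:n_drop]:
            preds[i].retained = False
    return preds


@dataclass
class EvalReport:
    accuracy: float
    macro_f1: float
    auc_per_class: dict[str, float]
    confusion: np.ndarray  # 9 x 9 counts, rows = truth
    per_fold_accuracy: list[float] = field(default_factory=list)
    filtered_accuracy: float | None = None
    filtered_macro_f1: float | None = None
    per_fold_filtered_accuracy: list[float] = field(default_factory=list)


def _metrics(y_true, y_pred, scores, n_classes):
    acc = float((y_true == y_pred).mean())
    f1 = float(f1_score(y_true, y_pred, average="macro", zero_division=0))
    aucs = {}
    for c in range(n_classes):
        mask = y_true == c
        if mask.any() and (~mask).any():
            aucs[CLASSES[c]] = float(roc_auc_score(mask.astype(int), scores[:, c]))
        else:
            aucs[CLASSES[c]] = float("nan")
    conf = sk_confusion(y_true, y_pred, labels=range(n_classes))
    return acc, f1, aucs, conf


def evaluate_cv(
    x: np.ndarray,
    y: np.ndarray,
    cfg: CnnConfig,
    k: int = 5,
    filter_fraction: float = 0.2,
) -> EvalReport:
    """Stratified k-fold cross-validation, before and after filtering.

    Each fold trains a fresh model on the remaining folds and evaluates on
    the held-out cells; metrics are averaged over folds.  Post-filter
    metrics are computed on the retained cells only.
    """
    y = np.asarray(y)
    counts = np.bincount(y, minlength=cfg.n_classes)
    k_eff = min(k, int(counts[counts > 0].min()))
    if k_eff < k:
        import warnings

        warnings.warn(
            f"smallest class has {k_eff} examples; folds merged from {k} to {k_eff}"
        )
    skf = StratifiedKFold(n_splits=max(k_eff, 2), shuffle=True, random_state=cfg.seed)
    accs, f1s, auc_list, confs = [], [], [], []
    f_accs, f_f1s = [], []
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold_cfg = CnnConfig(**{**cfg.__dict__, "seed": cfg.seed + fold})
        model = build_model(fold_cfg)
        train(model, x[tr], y[tr], fold_cfg)
        scores = predict_scores(model, x[va])
        y_pred = scores.argmax(axis=1)
        acc, f1, aucs, conf = _metrics(y[va], y_pred, scores, cfg.n_classes)
        accs.append(acc)
        f1s.append(f1)
        auc_list.append(aucs)
        confs.append(conf)
        preds = predict_filtered(model, x[va], filter_fraction=filter_fraction)
        keep = np.array([p.retained for p in preds])
        if keep.any():
            facc = float((y[va][keep] == y_pred[keep]).mean())
            ff1 = float(
                f1_score(y[va][keep], y_pred[keep], average="macro", zero_division=0)
            )
            f_accs.append(facc)
            f_f1s.append(ff1)
    mean_aucs = {
        cls: float(np.nanmean([a[cls] for a in auc_list])) for cls in CLASSES
    }
    return EvalReport(
        accuracy=float(np.mean(accs)),
        macro_f1=float(np.mean(f1s)),
        auc_per_class=mean_aucs,
        confusion=np.sum(confs, axis=0),
        per_fold_accuracy=[float(a) for a in accs],
        filtered_accuracy=float(np.mean(f_accs)) if f_accs else None,
        filtered_macro_f1=float(np.mean(f_f1s)) if f_f1s else None,
        per_fold_filtered_accuracy=[float(a) for a in f_accs],
    )
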