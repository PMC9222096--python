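"""Metrics, stratified cross-validation, and result plots.

The report carries both macro- and micro-averaged figures for every metric.
Micro-averaged recall over the argmax confusion matrix equals overall
accuracy by construction; macro averages weight the five distribution
classes equally.  Multi-class AUC is the macro one-vs-rest AUC computed on
the raw sigmoid scores (a softmax-renormalized variant is reported
alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as _np
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve

from .exceptions import StratificationError
from .io import CLASS_NAMES
from . import gnn


@dataclass
class EvalReport:
    """Per-class and aggregate classification metrics."""

    class_names: tuple
    confusion: _np.ndarray  # rows = truth, cols = prediction
    per_class: dict  # name -> {precision, recall, specificity, f1, auc, support}
    accuracy: float
    macro: dict
    micro: dict
    auc_macro: float
    auc_macro_softmax: float
    undefined_auc: list
    y_true: _np.ndarray
    y_prob: _np.ndarray
    folds: list = field(default_factory=list)  # per-fold summaries
    fold_assignments: _np.ndarray | None = None
    summary: dict = field(default_factory=dict)  # metric -> (mean, sd) across folds

    def to_dict(self):
        return {
            "class_names": list(self.class_names),
            "confusion": self.confusion.tolist(),
            "per_class": {k: {m: _none_if_nan(v) for m, v in d.items()}
                          for k, d in self.per_class.items()},
            "accuracy": self.accuracy,
            "macro": self.macro,
            "micro": self.micro,
            "auc_macro": _none_if_nan(self.auc_macro),
            "auc_macro_softmax": _none_if_nan(self.auc_macro_softmax),
            "undefined_auc": self.undefined_auc,
            "folds": self.folds,
            "summary": self.summary,
        }


def _none_if_nan(v):
    return None if isinstance(v, float) and _np.isnan(v) else v


def _softmax(scores):
    z = scores - scores.max(axis=1, keepdims=True)
    e = _np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def compute_metrics(y_true, y_prob, class_names=CLASS_NAMES):
    """Metrics from true labels and an (n, 5) score matrix.

    Predictions are the argmax of the scores.  Per-class precision, recall
    (sensitivity), specificity and F1 come from the one-vs-rest reading of
    the confusion matrix; AUC for a class absent from ``y_true`` is reported
    as undefined (NaN) and listed in ``undefined_auc``.
    """
    y_true = _np.asarray(y_true, dtype=int)
    y_prob = _np.asarray(y_prob, dtype=float)
    if y_true.shape[0] != y_prob.shape[0]:
        raise ValueError("y_true and y_prob lengths differ")
    if not _np.all(_np.isfinite(y_prob)):
        raise ValueError("scores must be finite")
    k = len(class_names)
    y_pred = y_prob.argmax(axis=1)
    cm = confusion_matrix(y_true, y_pred, labels=_np.arange(k))
    total = cm.sum()
    tp = _np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn

    def safe(num, den):
        return _np.where(den > 0, num / _np.maximum(den, 1), _np.nan)

    precision = safe(tp, tp + fp)
    recall = safe(tp, tp + fn)
    specificity = safe(tn, tn + fp)
    f1 = _np.where(_np.nan_to_num(precision) + _np.nan_to_num(recall) > 0,
                   2 * _np.nan_to_num(precision) * _np.nan_to_num(recall)
                   / _np.maximum(_np.nan_to_num(precision) + _np.nan_to_num(recall), 1e-300),
                   0.0)

    softmax_prob = _softmax(y_prob)
    aucs, undefined = [], []
    for c in range(k):
        pos = y_true == c
        if pos.any() and (~pos).any():
            aucs.append(roc_auc_score(pos, y_prob[:, c]))
        else:
            aucs.append(_np.nan)
            undefined.append(class_names[c])
    aucs_soft = []
    for c in range(k):
        pos = y_true == c
        aucs_soft.append(roc_auc_score(pos, softmax_prob[:, c])
                         if pos.any() and (~pos).any() else _np.nan)

    support = cm.sum(axis=1)
    per_class = {
        class_names[c]: {
            "precision": float(precision[c]),
            "recall": float(recall[c]),
            "specificity": float(specificity[c]),
            "f1": float(f1[c]),
            "auc": float(aucs[c]),
            "support": int(support[c]),
        }
        for c in range(k)
    }
    present = support > 0
    accuracy = float(tp.sum() / total) if total else _np.nan
    macro = {
        "precision": float(_np.nanmean(precision[present])),
        "recall": float(_np.nanmean(recall[present])),
        "specificity": float(_np.nanmean(specificity[present])),
        "f1": float(_np.mean(f1[present])),
    }
    micro = {
        "precision": float(tp.sum() / max(tp.sum() + fp.sum(), 1)),
        "recall": float(tp.sum() / max(tp.sum() + fn.sum(), 1)),
        "specificity": float(tn.sum() / max(tn.sum() + fp.sum(), 1)),
    }
    micro["f1"] = (2 * micro["precision"] * micro["recall"]
                   / max(micro["precision"] + micro["recall"], 1e-300))
    return EvalReport(
        class_names=tuple(class_names),
        confusion=cm,
        per_class=per_class,
        accuracy=accuracy,
        macro=macro,
        micro=micro,
        auc_macro=float(_np.nanmean([a for a in aucs])),
        auc_macro_softmax=float(_np.nanmean([a for a in aucs_soft])),
        undefined_auc=undefined,
        y_true=y_true,
        y_prob=y_prob,
    )


# ---------------------------------------------------------------------------
# cross-validation


def make_folds(labels, case_ids, n_folds, seed):
    """Stratified case-level fold assignment (every image of a case shares a
    fold).  Returns an integer fold index per sample."""
    labels = _np.asarray(labels, dtype=int)
    case_ids = _np.asarray(case_ids)
    cases, first_idx = _np.unique(case_ids, return_index=True)
    case_labels = labels[first_idx]
    for c in _np.unique(case_labels):
        count = int((case_labels == c).sum())
        if count < n_folds:
            raise StratificationError(
                f"class {CLASS_NAMES[c]!r} has only {count} cases; "
                f"{n_folds}-fold stratification needs at least {n_folds}")
    rng = _np.random.default_rng(seed)
    case_fold = _np.empty(cases.size, dtype=int)
    for c in _np.unique(case_labels):
        idx = _np.nonzero(case_labels == c)[0]
        idx = idx[rng.permutation(idx.size)]
        case_fold[idx] = _np.arange(idx.size) % n_folds
    lookup = dict(zip(cases.tolist(), case_fold.tolist()))
    return _np.array([lookup[c] for c in case_ids.tolist()])


def cross_validate(dataset, model_config=None, train_config=None,
                   loss_config=None, n_folds=5, seed=0, case_ids=None,
                   verbose=False):
    """Stratified k-fold cross-validation of the graph classifier.

    ``dataset`` is a list of labeled CalcificationGraphs; ``case_ids`` groups
    graphs belonging to one patient (defaults to one case per graph).
    Returns an EvalReport pooled over the held-out folds, with per-fold
    metric summaries and mean +- sd in ``summary``.
    """
    model_config = model_config or gnn.GnnConfig()
    train_config = train_config or gnn.TrainConfig()
    labels = [g.label for g in dataset]
    if case_ids is None:
        case_ids = [g.provenance.get("image_id", str(i))
                    for i, g in enumerate(dataset)]
    folds = make_folds(labels, case_ids, n_folds, seed)
    y_true_all, y_prob_all, fold_reports = [], [], []
    for fold in range(n_folds):
        test_idx = _np.nonzero(folds == fold)[0]
        train_idx = _np.nonzero(folds != fold)[0]
        fold_seed = (train_config.seed * 1009 + fold) % (2**31 - 1)
        model = gnn.train([dataset[i] for i in train_idx],
                          model_config=model_config,
                          train_config=replace(train_config, seed=fold_seed),
                          loss_config=loss_config)
        probs = _np.stack([gnn.predict(model, dataset[i]).probs for i in test_idx])
        truth = _np.array([labels[i] for i in test_idx])
        rep = compute_metrics(truth, probs, class_names=model_config.class_names)
        fold_reports.append({
            "fold": fold,
            "n_test": int(test_idx.size),
            "accuracy": rep.accuracy,
            "macro_f1": rep.macro["f1"],
            "auc_macro": _none_if_nan(rep.auc_macro),
        })
        y_true_all.append(truth)
        y_prob_all.append(probs)
        if verbose:
            print(f"fold {fold}: accuracy {rep.accuracy:.3f}")
    pooled = compute_metrics(_np.concatenate(y_true_all),
                             _np.concatenate(y_prob_all),
                             class_names=model_config.class_names)
    pooled.folds = fold_reports
    pooled.fold_assignments = folds
    accs = _np.array([f["accuracy"] for f in fold_reports])
    f1s = _np.array([f["macro_f1"] for f in fold_reports])
    pooled.summary = {
        "accuracy": (float(accs.mean()), float(accs.std(ddof=1))),
        "macro_f1": (float(f1s.mean()), float(f1s.std(ddof=1))),
    }
    return pooled


# ---------------------------------------------------------------------------
# plots


def plot_outputs(report, out_dir):
    """Write confusion-matrix heatmap and one-vs-rest ROC curves as PNGs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    k = len(report.class_names)

    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(report.confusion, cmap="Blues")
    ax.set_xticks(range(k), report.class_names, rotation=45, ha="right")
    ax.set_yticks(range(k), report.class_names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    vmax = report.confusion.max() or 1
    for i in range(k):
        for j in range(k):
            ax.text(j, i, str(report.confusion[i, j]), ha="center", va="center",
                    color="white" if report.confusion[i, j] > vmax / 2 else "black")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    cm_path = out_dir / "confusion_matrix.png"
    fig.savefig(cm_path, dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4.5))
    for c, name in enumerate(report.class_names):
        pos = report.y_true == c
        if pos.any() and (~pos).any():
            fpr, tpr, _ = roc_curve(pos, report.y_prob[:, c])
            auc = report.per_class[name]["auc"]
            ax.plot(fpr, tpr, label=f"{name} (AUC {auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    roc_path = out_dir / "roc_curves.png"
    fig.savefig(roc_path, dpi=120)
    plt.close(fig)
    return cm_path, roc_path
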