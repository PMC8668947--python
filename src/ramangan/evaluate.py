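"""Leave-one-out evaluation with per-fold augmentation, metrics and reports.

Each of the n folds holds out exactly one measured sample; augmentation (GAN
training and sampling, or SMOTE) happens on the training fold only, so
synthetic samples never leak information about the held-out spectrum and are
never test items themselves. A ``global_augment`` switch reproduces the
train-once reading where the generators see the full dataset before the
cross-validation loop; it is off by default and clearly labelled in reports.

Metrics: accuracy, macro-F1 (unweighted per-class F1, 0/0 -> 0) and macro
one-vs-rest AUC (rank-based, ties counted 1/2), reported for all samples and
for the treated / untreated subgroups. Empty subgroups yield ``None`` rather
than 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.manifold import TSNE

from .augment import AugmentationSpec, augment_dataset, train_class_gans
from .classifiers import ClassifierSpec, predict_proba, train_classifier
from .dataset import SpectraDataset

__all__ = [
    "EvalReport",
    "accuracy",
    "macro_f1",
    "macro_auc",
    "confusion_matrix",
    "subgroup_metrics",
    "loo_evaluate",
    "tsne_embed",
]

METRIC_NAMES = ("accuracy", "macro_f1", "auc")
SUBGROUPS = ("All", "Treated", "Untreated")


def accuracy(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal length")
    return float(np.mean(y_true == y_pred))


def macro_f1(y_true, y_pred, classes=None) -> float:
    """Unweighted mean of per-class F1 with the 0/0 -> 0 convention."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    f1s = []
    for c in classes:
        tp = np.sum((y_true == c) & (y_pred == c))
        fp = np.sum((y_true != c) & (y_pred == c))
        fn = np.sum((y_true == c) & (y_pred != c))
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    return float(np.mean(f1s))


def macro_auc(y_true, proba, classes) -> float | None:
    """Macro-averaged one-vs-rest ranking AUC (Mann-Whitney form, ties 1/2).

    Classes without both a positive and a negative sample are skipped; returns
    None if no class is scorable.
    """
    y_true = np.asarray(y_true, dtype=object)
    proba = np.asarray(proba, dtype=float)
    if proba.shape[0] != y_true.shape[0]:
        raise ValueError("probability rows must match label count")
    aucs = []
    for j, c in enumerate(classes):
        pos = y_true == c
        n_pos = int(pos.sum())
        n_neg = int(len(y_true) - n_pos)
        if n_pos == 0 or n_neg == 0:
            continue
        ranks = rankdata(proba[:, j])
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
        aucs.append(u / (n_pos * n_neg))
    return float(np.mean(aucs)) if aucs else None


def confusion_matrix(y_true, y_pred, classes) -> np.ndarray:
    """K x K counts: entry (i, j) = true class i predicted as class j."""
    lut = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in lut or p not in lut:
            raise ValueError(f"label outside class set: {t!r} / {p!r}")
        M[lut[t], lut[p]] += 1
    return M


@dataclass
class EvalReport:
    """Per-sample leave-one-out predictions plus subgroup metric table."""

    classes: tuple[str, ...]
    sample_ids: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    proba: np.ndarray
    treated: np.ndarray
    fold: np.ndarray
    metrics: dict[str, dict[str, float | None]]
    confusion: np.ndarray
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "metrics": self.metrics,
            "confusion": self.confusion.tolist(),
            "config": self.config,
            "per_sample": [
                {
                    "sample_id": str(s),
                    "true": str(t),
                    "predicted": str(p),
                    "proba": list(map(float, pr)),
                    "treated": str(tr),
                    "fold": int(f),
                }
                for s, t, p, pr, tr, f in zip(
                    self.sample_ids, self.y_true, self.y_pred,
                    self.proba, self.treated, self.fold,
                )
            ],
        }


def subgroup_metrics(y_true, y_pred, proba, treated, classes) -> dict:
    """Accuracy / macro-F1 / AUC for All, Treated and Untreated subsets.

    Unknown treatment flags count toward All only. Empty subgroups report
    None for every metric rather than a coerced 0.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    proba = np.asarray(proba, dtype=float)
    treated = np.asarray(treated, dtype=object)
    masks = {
        "All": np.ones(len(y_true), dtype=bool),
        "Treated": treated == "treated",
        "Untreated": treated == "untreated",
    }
    out: dict[str, dict[str, float | None]] = {}
    for name, mask in masks.items():
        if not mask.any():
            out[name] = {m: None for m in METRIC_NAMES}
            continue
        out[name] = {
            "accuracy": accuracy(y_true[mask], y_pred[mask]),
            "macro_f1": macro_f1(y_true[mask], y_pred[mask], classes),
            "auc": macro_auc(y_true[mask], proba[mask], classes),
        }
    return out


def loo_evaluate(
    data: SpectraDataset,
    aug: AugmentationSpec | None = None,
    clf: ClassifierSpec | None = None,
    seed: int = 0,
    global_augment: bool = False,
) -> EvalReport:
    """Leave-one-out cross-validation with per-fold augmentation.

    For every sample: exclude it, augment the remaining training fold per
    ``aug`` (leakage-safe default; ``global_augment=True`` trains the
    generators once on the full dataset first), train the classifier on
    original + synthetic fold data, and predict the held-out sample.
    """
    aug = aug if aug is not None else AugmentationSpec()
    clf = clf if clf is not None else ClassifierSpec()
    from .dataset import class_counts

    counts = class_counts(data)
    if data.n < len(data.class_set):
        raise ValueError("need at least one sample per class")
    singles = [c for c, v in counts.items() if v < 2]
    if singles:
        raise ValueError(
            f"leave-one-out with augmentation requires >= 2 samples per class; "
            f"classes with one sample: {singles}"
        )

    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(data.n * 2 + 1) % (2**31)
    shared_models = None
    if global_augment and aug.strategy != "none" and aug.generator == "gan":
        shared_models = train_class_gans(data, aug.gan_config, seed=int(fold_seeds[-1]))

    K = len(data.class_set)
    proba = np.zeros((data.n, K))
    y_pred = np.empty(data.n, dtype=object)
    folds = np.arange(data.n)
    for i in range(data.n):
        train_idx = np.setdiff1d(np.arange(data.n), [i])
        train_fold = data.subset(train_idx)
        train_fold = augment_dataset(
            train_fold, aug, random_state=int(fold_seeds[2 * i]),
            models=shared_models,
        )
        model = train_classifier(clf, train_fold, seed=int(fold_seeds[2 * i + 1]))
        p, lab = predict_proba(model, data.subset([i]))
        proba[i] = p[0]
        y_pred[i] = lab[0]

    metrics = subgroup_metrics(data.labels, y_pred, proba, data.treated, data.class_set)
    conf = confusion_matrix(data.labels, y_pred, data.class_set)
    return EvalReport(
        classes=data.class_set,
        sample_ids=data.sample_ids.copy(),
        y_true=data.labels.copy(),
        y_pred=y_pred,
        proba=proba,
        treated=data.treated.copy(),
        fold=folds,
        metrics=metrics,
        confusion=conf,
        config={
            "augmentation": {
                "strategy": aug.strategy,
                "generator": aug.generator,
                "n_prime": aug.n_prime,
                "m": aug.m,
            },
            "classifier": clf.kind,
            "seed": seed,
            "global_augment": global_augment,
        },
    )


def tsne_embed(data: SpectraDataset, seed: int = 0, perplexity: float | None = None) -> np.ndarray:
    """2-D t-SNE embedding of the spectra (visualization only)."""
    if data.n < 5:
        raise ValueError("t-SNE embedding requires at least 5 samples")
    if perplexity is None:
        perplexity = min(30.0, (data.n - 1) / 3.0)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    )
    return tsne.fit_transform(data.X)
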