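"""Cross-validated evaluation and report generation.

k-fold (default 5) cross-validation with stratified, seeded splits;
per-class and support-weighted precision/recall/F1; and a report row in
the style "mean CV accuracy +/- margin (ci_low, ci_high)" where the
confidence interval is literally mean -/+ margin. The margin estimator is
configurable — sample standard deviation across folds (default), standard
error, or a t-based 95% half-width — and the chosen estimator is stamped
into every report.

Entangler comparisons (CNOT vs CZ) are paired by construction: identical
fold splits and identical classical initialization seeds, so differences
in accuracy or dispersion are attributable to the entangling gate alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support

from .hybrid_model import ClassifierConfig, HybridModel, init_hybrid_model, predict, train

__all__ = [
    "CVReport",
    "kfold_split",
    "classification_metrics",
    "cv_confidence",
    "run_cv_experiment",
    "compare_entanglers",
    "report_to_table_row",
]

_MARGIN_ESTIMATORS = ("std", "sem", "t95")


def kfold_split(
    n: int,
    k: int,
    seed: int,
    labels: np.ndarray | None = None,
    stratified: bool = True,
) -> list[np.ndarray]:
    """k disjoint validation index sets covering 0..n-1, sizes differing by <= 1.

    With ``labels`` and ``stratified=True`` each class is spread as evenly
    as possible across folds. Deterministic for a given seed.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if labels is not None and stratified:
        labels = np.asarray(labels)
        cursor = 0  # global round-robin pointer keeps total fold sizes balanced
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            for i in idx:
                folds[cursor % k].append(int(i))
                cursor += 1
    else:
        order = rng.permutation(n)
        for pos, i in enumerate(order):
            folds[pos % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def classification_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> dict:
    """Accuracy plus per-class and weighted/macro precision, recall, F1.

    Zero-denominator precision/recall are defined as 0 (and the class still
    counts in the aggregates).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    labels = np.arange(n_classes)
    p, r, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    wp, wr, wf1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="weighted", zero_division=0
    )
    mp, mr, mf1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    return {
        "accuracy": float(np.mean(y_true == y_pred)),
        "per_class": {
            str(int(c)): {
                "precision": float(p[c]),
                "recall": float(r[c]),
                "f1": float(f1[c]),
                "support": int(support[c]),
            }
            for c in labels
        },
        "weighted": {"precision": float(wp), "recall": float(wr), "f1": float(wf1)},
        "macro": {"precision": float(mp), "recall": float(mr), "f1": float(mf1)},
    }


def cv_confidence(
    fold_accuracies: np.ndarray, estimator: str = "std"
) -> tuple[float, float, float, float]:
    """(mean, margin, ci_low, ci_high) with ci = mean -/+ margin.

    Margin estimators: 'std' (sample standard deviation, ddof=1), 'sem'
    (standard error of the mean), 't95' (t-distribution 95% half-width).
    """
    acc = np.asarray(fold_accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least 2 fold accuracies")
    if estimator not in _MARGIN_ESTIMATORS:
        raise ValueError(f"estimator must be one of {_MARGIN_ESTIMATORS}")
    mean = float(np.mean(acc))
    sd = float(np.std(acc, ddof=1))
    if estimator == "std":
        margin = sd
    elif estimator == "sem":
        margin = sd / np.sqrt(acc.size)
    else:
        margin = sd / np.sqrt(acc.size) * float(stats.t.ppf(0.975, acc.size - 1))
    return mean, margin, mean - margin, mean + margin


@dataclass
class CVReport:
    """Cross-validation results for one model configuration."""

    model_name: str
    entangler: str
    n_layers: int
    optimizer: str
    k: int
    seed: int
    margin_estimator: str
    fold_accuracies: list
    mean: float
    margin: float
    ci_low: float
    ci_high: float
    per_class: dict
    weighted: dict
    macro: dict
    train_accuracy: float
    test_accuracy: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError("confidence interval does not bracket the mean")
        if abs(self.mean - float(np.mean(self.fold_accuracies))) > 1e-12:
            raise ValueError("mean does not match the fold accuracies")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "CVReport":
        return cls(**d)

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "CVReport":
        p = Path(text_or_path)
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls.from_dict(json.loads(text))


def report_to_table_row(report: CVReport) -> dict:
    """One row in the published comparison-table format."""
    return {
        "Model": report.model_name,
        "Train Acc.": round(report.train_accuracy, 4),
        "Test Acc.": round(report.test_accuracy, 4),
        "Precision": round(report.weighted["precision"], 4),
        "Recall": round(report.weighted["recall"], 4),
        "F1 Score": round(report.weighted["f1"], 4),
        "Mean CV Acc.": f"{report.mean:.4f} ± {report.margin:.4f}",
        "Confidence Interval (CI)": f"({report.ci_low:.4f}, {report.ci_high:.4f})",
    }


def run_cv_experiment(
    images: np.ndarray,
    labels: np.ndarray,
    config: ClassifierConfig,
    entangler: str = "CZ",
    n_layers: int = 1,
    k: int = 5,
    seed: int = 0,
    margin_estimator: str = "std",
    stratified: bool = True,
    frozen_quantum: bool = False,
    splits: list[np.ndarray] | None = None,
    model_name: str | None = None,
) -> CVReport:
    """Train k models, each validated on its held-out fold, and aggregate.

    ``splits`` may be supplied to reuse a split across configurations (the
    paired-comparison contract); otherwise folds are derived from ``seed``.
    """
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if splits is None:
        splits = kfold_split(len(images), k, seed, labels=labels, stratified=stratified)
    if len(splits) != k:
        raise ValueError(f"expected {k} folds, got {len(splits)}")
    all_idx = np.arange(len(images))
    fold_accs, train_accs = [], []
    y_true_all, y_pred_all = [], []
    for fold_id, val_idx in enumerate(splits):
        train_idx = np.setdiff1d(all_idx, val_idx)
        fold_cfg = ClassifierConfig(**{**config.to_dict(), "seed": config.seed})
        model = init_hybrid_model(
            fold_cfg, images.shape[1:], entangler=entangler, n_layers=n_layers
        )
        history = train(
            model,
            images[train_idx],
            labels[train_idx],
            frozen_quantum=frozen_quantum,
        )
        train_accs.append(history[-1]["accuracy"])
        y_pred = predict(model, images[val_idx])
        y_true_all.append(labels[val_idx])
        y_pred_all.append(y_pred)
        fold_accs.append(float(np.mean(y_pred == labels[val_idx])))
    mean, margin, lo, hi = cv_confidence(fold_accs, margin_estimator)
    metrics = classification_metrics(
        np.concatenate(y_true_all), np.concatenate(y_pred_all), config.n_classes
    )
    name = model_name or f"NNQE_{'v1' if entangler == 'CNOT' else 'v2'} ({entangler})"
    return CVReport(
        model_name=name,
        entangler=entangler,
        n_layers=n_layers,
        optimizer=config.optimizer,
        k=k,
        seed=seed,
        margin_estimator=margin_estimator,
        fold_accuracies=[float(a) for a in fold_accs],
        mean=mean,
        margin=margin,
        ci_low=lo,
        ci_high=hi,
        per_class=metrics["per_class"],
        weighted=metrics["weighted"],
        macro=metrics["macro"],
        train_accuracy=float(np.mean(train_accs)),
        test_accuracy=metrics["accuracy"],
    )


def compare_entanglers(
    images: np.ndarray,
    labels: np.ndarray,
    config: ClassifierConfig,
    n_layers: int = 1,
    k: int = 5,
    seed: int = 0,
    margin_estimator: str = "std",
    frozen_quantum: bool = False,
) -> dict:
    """Paired CNOT-vs-CZ cross-validation: identical splits, identical seeds."""
    labels = np.asarray(labels, dtype=int)
    splits = kfold_split(len(images), k, seed, labels=labels, stratified=True)
    reports = {}
    for entangler in ("CNOT", "CZ"):
        reports[entangler] = run_cv_experiment(
            images,
            labels,
            config,
            entangler=entangler,
            n_layers=n_layers,
            k=k,
            seed=seed,
            margin_estimator=margin_estimator,
            frozen_quantum=frozen_quantum,
            splits=splits,
        )
    return reports


def entangler_stability(
    images: np.ndarray,
    labels: np.ndarray,
    config: ClassifierConfig,
    n_runs: int = 10,
    n_layers: int = 1,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> dict:
    """Spread of final validation accuracy across seeded runs, per entangler.

    Trains ``n_runs`` models per entangler on a fixed train/validation
    split, varying only the initialization/shuffling seed, and reports the
    per-entangler mean and standard deviation of final validation
    accuracy. Exposes the stability comparison as a measurable without
    asserting which gate is steadier.
    """
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(images))
    n_val = max(1, int(round(val_fraction * len(images))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    out = {}
    for entangler in ("CNOT", "CZ"):
        finals = []
        for run in range(n_runs):
            run_cfg = ClassifierConfig(**{**config.to_dict(), "seed": config.seed + run})
            model = init_hybrid_model(
                run_cfg, images.shape[1:], entangler=entangler, n_layers=n_layers
            )
            history = train(
                model,
                images[train_idx],
                labels[train_idx],
                val_images=images[val_idx],
                val_labels=labels[val_idx],
            )
            finals.append(history[-1]["val_accuracy"])
        out[entangler] = {
            "final_val_accuracies": [float(a) for a in finals],
            "mean": float(np.mean(finals)),
            "std": float(np.std(finals, ddof=1)) if len(finals) > 1 else 0.0,
        }
    return out


def reports_to_csv(reports: list[CVReport], path: str | Path) -> pd.DataFrame:
    """Comparison-table CSV: one row per report."""
    df = pd.DataFrame([report_to_table_row(r) for r in reports])
    df.to_csv(path, index=False)
    return df
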