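"""Repeated nested stratified 5-fold cross-validation and metrics.

Five shuffled repetitions of a stratified 5-fold split yield 25
held-out test scores per feature/model combination.  The fold plan is a
deterministic function of the labels and the master seed, so every
feature dataset evaluated under one master seed sees identical splits.
Outlier removal is never invoked inside this procedure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score, f1_score, recall_score
from sklearn.model_selection import StratifiedKFold

from .classifiers import FnnConfig, SvmConfig, fit_fnn, fit_svm, predict
from .feature_assembly import FeatureMatrix
from .go_dataset import LabeledDataset

__all__ = [
    "CvPlan",
    "EvaluationReport",
    "stratified_folds",
    "build_cv_plan",
    "metrics",
    "nested_cv_evaluate",
    "aggregate",
    "N_FOLDS",
    "N_REPETITIONS",
]

N_FOLDS = 5
N_REPETITIONS = 5


def stratified_folds(labels: np.ndarray, n_folds: int = N_FOLDS, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (0..n_folds-1 per sample).

    Per-fold class counts are within one of exact proportionality.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, need >= {n_folds}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


@dataclass(frozen=True)
class CvPlan:
    """Fold assignments for every repetition, shared across features."""

    master_seed: int
    fold_assignments: tuple[tuple[int, ...], ...]  # (repetition, sample)
    n_folds: int = N_FOLDS

    @property
    def n_repetitions(self) -> int:
        return len(self.fold_assignments)


def build_cv_plan(
    labels: np.ndarray,
    master_seed: int,
    n_folds: int = N_FOLDS,
    n_repetitions: int = N_REPETITIONS,
) -> CvPlan:
    """One stratified fold assignment per repetition, with repetition
    seeds ``master_seed + r``."""
    assignments = tuple(
        tuple(stratified_folds(labels, n_folds, master_seed + r).tolist())
        for r in range(n_repetitions)
    )
    return CvPlan(master_seed=master_seed, fold_assignments=assignments, n_folds=n_folds)


def metrics(y_true, y_pred) -> dict:
    """Balanced accuracy, per-class F1, and macro F1.

    Balanced accuracy is the mean per-class recall; a class with zero
    predicted positives gets precision 0 and F1 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    classes = sorted(np.unique(y_true).tolist())
    if len(classes) < 2:
        raise ValueError("both classes must be present in y_true")
    f1s = f1_score(y_true, y_pred, labels=classes, average=None, zero_division=0)
    recalls = recall_score(y_true, y_pred, labels=classes, average=None, zero_division=0)
    return {
        "balanced_accuracy": float(np.mean(recalls)),
        "f1_per_class": {c: float(f) for c, f in zip(classes, f1s)},
        "macro_f1": float(np.mean(f1s)),
    }


@dataclass
class EvaluationReport:
    """The 25 held-out test scores plus their aggregates."""

    rows: pd.DataFrame
    feature_id: str = ""
    model_kind: str = ""
    aggregates: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def aggregates_to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.aggregates, indent=2))

    def long_format(self) -> pd.DataFrame:
        """Box-plot-ready long format: one row per (split, metric)."""
        keep = [c for c in self.rows.columns if c.startswith(("balanced", "f1", "macro"))]
        return self.rows.melt(
            id_vars=["repetition", "fold"],
            value_vars=keep,
            var_name="metric",
            value_name="score",
        )


def aggregate(rows: pd.DataFrame) -> dict:
    """Mean and sample (n-1) standard deviation per metric column."""
    if len(rows) == 0:
        raise ValueError("cannot aggregate an empty report")
    out = {}
    for col in rows.columns:
        if col.startswith(("balanced", "f1", "macro")):
            out[col] = {
                "mean": float(rows[col].mean()),
                "std": float(rows[col].std(ddof=1)) if len(rows) > 1 else 0.0,
            }
    return out


def nested_cv_evaluate(
    dataset: LabeledDataset,
    feature: FeatureMatrix,
    model: str = "svm",
    master_seed: int = 0,
    svm_config: SvmConfig | None = None,
    fnn_config: FnnConfig | None = None,
    plan: CvPlan | None = None,
) -> EvaluationReport:
    """Run the 5x5 evaluation protocol for one feature and model.

    For every repetition and outer fold, the SVM performs its inner
    stratified grid search on the outer-training split only; the
    network trains with fixed hyperparameters.  Returns exactly
    ``n_repetitions x n_folds`` rows.
    """
    if model not in ("svm", "fnn"):
        raise ValueError("model must be 'svm' or 'fnn'")
    accs = dataset.accessions()
    missing = set(accs) - set(feature.sample_ids)
    if missing:
        raise ValueError(
            f"feature matrix missing samples: {sorted(missing)[:5]}"
        )
    X = feature.subset(accs)
    y = np.asarray([label for _, label in dataset.samples])
    if plan is None:
        plan = build_cv_plan(y, master_seed)

    records = []
    for rep, assignment in enumerate(plan.fold_assignments):
        assignment = np.asarray(assignment)
        rep_seed = plan.master_seed + rep
        for fold in range(plan.n_folds):
            test_mask = assignment == fold
            train_ids = [a for a, m in zip(accs, test_mask) if not m]
            test_ids = [a for a, m in zip(accs, test_mask) if m]
            X_train, X_test = X.subset(train_ids), X.subset(test_ids)
            y_train, y_test = y[~test_mask], y[test_mask]
            if model == "svm":
                cfg = svm_config or SvmConfig()
                cfg = SvmConfig(
                    C_grid=cfg.C_grid, k_grid=cfg.k_grid, k_cap=cfg.k_cap,
                    n_inner_folds=cfg.n_inner_folds, seed=rep_seed,
                )
                fitted = fit_svm(X_train, y_train, cfg)
            else:
                cfg = fnn_config or FnnConfig()
                cfg = FnnConfig(
                    hidden_sizes=cfg.hidden_sizes, dropout_rate=cfg.dropout_rate,
                    batch_size=cfg.batch_size, epochs=cfg.epochs,
                    learning_rate=cfg.learning_rate,
                    decision_threshold=cfg.decision_threshold, seed=rep_seed,
                )
                fitted = fit_fnn(X_train, y_train, cfg)
            y_pred = predict(fitted, X_test)
            scores = metrics(y_test, y_pred)
            row = {
                "repetition": rep,
                "fold": fold,
                "n_test": int(test_mask.sum()),
                "balanced_accuracy": scores["balanced_accuracy"],
                "macro_f1": scores["macro_f1"],
            }
            for c, f in scores["f1_per_class"].items():
                row[f"f1_{c}"] = f
            for k, v in fitted.chosen_params.items():
                if isinstance(v, (int, float, str)):
                    row[f"param_{k}"] = v
            records.append(row)
    rows = pd.DataFrame.from_records(records)
    report = EvaluationReport(
        rows=rows, feature_id=feature.feature_id, model_kind=model
    )
    report.aggregates = aggregate(rows)
    return report
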