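"""The SVM pipeline and the dropout-regularized feedforward network.

SVM pipeline per candidate (k, C): zero-variance filter -> ANOVA top-k
selection -> column z-scoring -> RBF SVM with gamma = 1 / (var(X) * m)
and per-class weight n / (K * n_i); (k, C) chosen by mean balanced
accuracy in a stratified 5-fold search on the training split.

The feedforward network (implemented here on NumPy) has three ReLU
hidden layers of 512, 256, and 128 units, each followed by dropout 0.5,
a single sigmoid output, and is trained with Adam on binary
cross-entropy for 50 epochs at batch size 8, with no inner
hyperparameter search.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .feature_assembly import FeatureMatrix

__all__ = [
    "SvmConfig",
    "FnnConfig",
    "FittedModel",
    "variance_filter",
    "anova_f_scores",
    "select_top_k",
    "rbf_gamma",
    "class_weights",
    "fit_svm",
    "fit_fnn",
    "predict",
    "save_model",
    "load_model",
    "DEFAULT_K_GRID",
]

DEFAULT_C_GRID = (0.1, 1.0, 10.0)
DEFAULT_K_GRID = (10, 25, 50, 100, 200)
K_CAP = 200


@dataclass(frozen=True)
class SvmConfig:
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    k_cap: int = K_CAP
    n_inner_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if any(k > self.k_cap for k in self.k_grid):
            raise ValueError(f"k_grid values must not exceed k_cap={self.k_cap}")


@dataclass(frozen=True)
class FnnConfig:
    hidden_sizes: tuple[int, ...] = (512, 256, 128)
    dropout_rate: float = 0.5
    batch_size: int = 8
    epochs: int = 50
    learning_rate: float = 1e-3
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")


def variance_filter(X: FeatureMatrix) -> tuple[FeatureMatrix, tuple[str, ...]]:
    """Remove columns with exactly zero variance on the given rows."""
    sd = X.values.std(axis=0)
    mask = sd > 0
    if not mask.any():
        raise ValueError("variance filter removed every feature column")
    kept = tuple(n for n, m in zip(X.feature_names, mask) if m)
    return (
        FeatureMatrix(
            sample_ids=X.sample_ids,
            feature_names=kept,
            values=X.values[:, mask],
            feature_id=X.feature_id,
        ),
        kept,
    )


def anova_f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic per column.

    F = (between-class SS / (K - 1)) / (within-class SS / (n - K)).
    Columns with zero within-class variance get ``inf`` when the class
    means differ and 0 otherwise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    n = len(y)
    K = len(classes)
    if K < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        mean_c = Xc.mean(axis=0)
        ss_between += len(Xc) * (mean_c - grand) ** 2
        ss_within += ((Xc - mean_c) ** 2).sum(axis=0)
    ms_between = ss_between / (K - 1)
    ms_within = ss_within / (n - K)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ms_between / ms_within
    F[np.isnan(F)] = 0.0  # 0/0: no variance anywhere
    return F


def select_top_k(
    scores: np.ndarray,
    feature_names: tuple[str, ...],
    k: int,
    k_cap: int = K_CAP,
) -> tuple[str, ...]:
    """Names of the k highest-scoring features; ties broken by
    lexicographic feature-name order.  k must not exceed
    min(k_cap, number of features)."""
    m_prime = len(feature_names)
    if not 1 <= k <= min(k_cap, m_prime):
        raise ValueError(f"k={k} out of bounds 1..min({k_cap}, {m_prime})")
    order = sorted(range(m_prime), key=lambda i: (-scores[i], feature_names[i]))
    return tuple(feature_names[i] for i in order[:k])


def rbf_gamma(X: np.ndarray) -> float:
    """gamma = 1 / (var(X) * m), with var pooled over all entries."""
    X = np.asarray(X, dtype=float)
    var = X.var()
    if var == 0:
        raise ValueError("pooled variance of the training matrix is zero")
    return 1.0 / (var * X.shape[1])


def class_weights(y: np.ndarray) -> dict:
    """weight_i = n / (K * n_i) for every class label."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if (counts == 0).any():
        raise ValueError("empty class")
    n, K = len(y), len(classes)
    return {c: n / (K * ni) for c, ni in zip(classes, counts)}


@dataclass
class FittedModel:
    """A trained classifier plus the preprocessing state derived from
    the training split only."""

    kind: str  # "svm" | "fnn"
    kept_names: tuple[str, ...]  # after zero-variance filter
    selected_names: tuple[str, ...]  # after ANOVA selection (svm) / = kept (fnn)
    means: np.ndarray
    sds: np.ndarray
    classes: tuple  # sorted labels; classes[1] is the positive class
    model: object
    chosen_params: dict = field(default_factory=dict)
    decision_threshold: float = 0.5

    def transform(self, X: FeatureMatrix) -> np.ndarray:
        missing = set(self.selected_names) - set(X.feature_names)
        if missing:
            raise KeyError(f"feature matrix missing columns: {sorted(missing)[:5]}")
        index = {n: i for i, n in enumerate(X.feature_names)}
        cols = [index[n] for n in self.selected_names]
        Z = X.values[:, cols]
        return (Z - self.means) / self.sds


def _fit_svm_once(
    X: FeatureMatrix, y: np.ndarray, k: int, C: float
) -> FittedModel:
    Xf, kept = variance_filter(X)
    scores = anova_f_scores(Xf.values, y)
    k_eff = min(k, len(kept))
    selected = select_top_k(scores, kept, k_eff)
    index = {n: i for i, n in enumerate(Xf.feature_names)}
    cols = [index[n] for n in selected]
    Z = Xf.values[:, cols]
    means, sds = Z.mean(axis=0), Z.std(axis=0)
    Zs = (Z - means) / sds
    gamma = rbf_gamma(Zs)
    weights = class_weights(y)
    svc = SVC(kernel="rbf", C=C, gamma=gamma, class_weight=weights)
    svc.fit(Zs, y)
    return FittedModel(
        kind="svm",
        kept_names=kept,
        selected_names=selected,
        means=means,
        sds=sds,
        classes=tuple(np.unique(y)),
        model=svc,
        chosen_params={"k": k, "C": C, "gamma": gamma},
    )


def fit_svm(
    train: FeatureMatrix, y: np.ndarray, config: SvmConfig = SvmConfig()
) -> FittedModel:
    """Grid search (k, C) by stratified inner cross-validation, then
    refit the whole pipeline on the full training split.

    The candidate maximizing mean inner-fold balanced accuracy wins;
    ties go to the smallest k, then the smallest C.
    """
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("fit_svm requires exactly 2 classes in the training split")
    _, kept = variance_filter(train)
    m_prime = len(kept)
    k_candidates = sorted({min(k, m_prime) for k in config.k_grid if k <= config.k_cap})
    inner = StratifiedKFold(
        n_splits=config.n_inner_folds, shuffle=True, random_state=config.seed
    )
    best = None
    for k in k_candidates:
        for C in sorted(config.C_grid):
            fold_scores = []
            for tr_idx, va_idx in inner.split(train.values, y):
                tr_ids = [train.sample_ids[i] for i in tr_idx]
                va_ids = [train.sample_ids[i] for i in va_idx]
                model = _fit_svm_once(train.subset(tr_ids), y[tr_idx], k, C)
                pred = predict(model, train.subset(va_ids))
                fold_scores.append(balanced_accuracy_score(y[va_idx], pred))
            mean_score = float(np.mean(fold_scores))
            key = (-mean_score, k, C)
            if best is None or key < best[0]:
                best = (key, k, C)
    _, k_best, C_best = best
    model = _fit_svm_once(train, y, k_best, C_best)
    model.chosen_params["inner_cv_balanced_accuracy"] = -best[0][0]
    return model


class NumpyFnn:
    """Minimal dense network: ReLU hidden layers with inverted dropout,
    sigmoid output, Adam on binary cross-entropy.  Deterministic per
    machine given the seed."""

    def __init__(self, n_inputs: int, config: FnnConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        sizes = [n_inputs, *config.hidden_sizes, 1]
        self.W = [
            self.rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        # Adam state
        self._mW = [np.zeros_like(w) for w in self.W]
        self._vW = [np.zeros_like(w) for w in self.W]
        self._mb = [np.zeros_like(b) for b in self.b]
        self._vb = [np.zeros_like(b) for b in self.b]
        self._t = 0

    def _forward(self, X: np.ndarray, train: bool):
        acts = [X]
        masks = []
        h = X
        p = self.config.dropout_rate
        for i in range(len(self.W) - 1):
            h = np.maximum(h @ self.W[i] + self.b[i], 0.0)
            if train and p > 0:
                mask = (self.rng.random(h.shape) >= p) / (1.0 - p)
                h = h * mask
            else:
                mask = None
            masks.append(mask)
            acts.append(h)
        logits = (h @ self.W[-1] + self.b[-1]).ravel()
        return logits, acts, masks

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _, _ = self._forward(X, train=False)
        return 1.0 / (1.0 + np.exp(-logits))

    def _adam_step(self, gW, gb):
        c = self.config
        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i in range(len(self.W)):
            self._mW[i] = b1 * self._mW[i] + (1 - b1) * gW[i]
            self._vW[i] = b2 * self._vW[i] + (1 - b2) * gW[i] ** 2
            self._mb[i] = b1 * self._mb[i] + (1 - b1) * gb[i]
            self._vb[i] = b2 * self._vb[i] + (1 - b2) * gb[i] ** 2
            mW = self._mW[i] / (1 - b1 ** self._t)
            vW = self._vW[i] / (1 - b2 ** self._t)
            mb = self._mb[i] / (1 - b1 ** self._t)
            vb = self._vb[i] / (1 - b2 ** self._t)
            self.W[i] -= c.learning_rate * mW / (np.sqrt(vW) + eps)
            self.b[i] -= c.learning_rate * mb / (np.sqrt(vb) + eps)

    def fit(self, X: np.ndarray, y01: np.ndarray) -> None:
        c = self.config
        n = len(y01)
        for _ in range(c.epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, c.batch_size):
                idx = order[start : start + c.batch_size]
                Xb, yb = X[idx], y01[idx]
                logits, acts, masks = self._forward(Xb, train=True)
                probs = 1.0 / (1.0 + np.exp(-logits))
                # d(BCE)/d(logit)
                delta = ((probs - yb) / len(yb))[:, None]
                gW = [None] * len(self.W)
                gb = [None] * len(self.b)
                grad = delta
                for i in range(len(self.W) - 1, -1, -1):
                    gW[i] = acts[i].T @ grad
                    gb[i] = grad.sum(axis=0)
                    if i > 0:
                        grad = grad @ self.W[i].T
                        if masks[i - 1] is not None:
                            grad = grad * masks[i - 1]
                        grad = grad * (acts[i] > 0)
                self._adam_step(gW, gb)


def fit_fnn(
    train: FeatureMatrix, y: np.ndarray, config: FnnConfig = FnnConfig()
) -> FittedModel:
    """Train the feedforward network on z-scored training columns.

    Labels are binarized by sorted order (the second label is the
    positive class).  No hyperparameter search is performed.
    """
    y = np.asarray(y)
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) != 2:
        raise ValueError("fit_fnn requires exactly 2 classes")
    Xf, kept = variance_filter(train)
    means, sds = Xf.values.mean(axis=0), Xf.values.std(axis=0)
    Z = (Xf.values - means) / sds
    y01 = (y == classes[1]).astype(float)
    net = NumpyFnn(Z.shape[1], config)
    net.fit(Z, y01)
    return FittedModel(
        kind="fnn",
        kept_names=kept,
        selected_names=kept,
        means=means,
        sds=sds,
        classes=classes,
        model=net,
        chosen_params={"epochs": config.epochs, "batch_size": config.batch_size},
        decision_threshold=config.decision_threshold,
    )


def predict(model: FittedModel, X: FeatureMatrix, return_proba: bool = False):
    """Predict labels with a fitted model; strictly greater than the
    decision threshold maps to the positive class for the network."""
    Z = model.transform(X)
    if model.kind == "svm":
        labels = model.model.predict(Z)
        if return_proba:
            raise ValueError("probabilities are only available for the fnn")
        return labels
    probs = model.model.predict_proba(Z)
    labels = np.where(
        probs > model.decision_threshold, model.classes[1], model.classes[0]
    )
    if return_proba:
        return labels, probs
    return labels


def save_model(model: FittedModel, path: str | Path) -> None:
    """Persist a fitted model: JSON metadata next to pickled learned
    parameters (runtime artifact, not a text deliverable)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "kind": model.kind,
        "classes": list(model.classes),
        "chosen_params": {
            k: v for k, v in model.chosen_params.items() if isinstance(v, (int, float, str))
        },
        "decision_threshold": model.decision_threshold,
        "n_selected": len(model.selected_names),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    with (path / "model.pkl").open("wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str | Path) -> FittedModel:
    with (Path(path) / "model.pkl").open("rb") as fh:
        return pickle.load(fh)
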