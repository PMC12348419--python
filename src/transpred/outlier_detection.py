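"""Anomalous-protein screening: per-feature-dataset PCA + isolation
forest, and a cross-feature consensus rule.

Outlier removal is a dataset-construction step only; the evaluation
harness never invokes it inside cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import IsolationForest

from .feature_assembly import FeatureMatrix

__all__ = [
    "OutlierReport",
    "detect_outliers_single",
    "pca_reduce",
    "consensus_outliers",
    "detect_outliers",
    "EXPLAINED_VARIANCE_TARGET",
    "N_TREES",
    "MAX_SUBSAMPLE",
]

EXPLAINED_VARIANCE_TARGET = 0.95
N_TREES = 100
MAX_SUBSAMPLE = 256


@dataclass
class OutlierReport:
    per_feature_flags: dict[str, set[str]]
    consensus: set[str]
    fraction_threshold: float = 0.5

    def to_tsv(self, path: str | Path) -> None:
        feature_ids = sorted(self.per_feature_flags)
        accessions = sorted(set().union(*self.per_feature_flags.values(), self.consensus))
        with Path(path).open("w") as fh:
            fh.write("accession\t" + "\t".join(feature_ids) + "\tconsensus\n")
            for acc in accessions:
                flags = [
                    str(int(acc in self.per_feature_flags[f])) for f in feature_ids
                ]
                fh.write(f"{acc}\t" + "\t".join(flags) + f"\t{int(acc in self.consensus)}\n")


def pca_reduce(X: np.ndarray, target: float = EXPLAINED_VARIANCE_TARGET):
    """Project standardized data onto the smallest number of principal
    components whose cumulative explained variance is >= ``target``.

    Returns ``(projected, cumulative_explained_variance)``.
    """
    pca = PCA()
    Z = pca.fit_transform(X)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    n_components = int(np.searchsorted(cumvar, target) + 1)
    n_components = min(n_components, Z.shape[1])
    return Z[:, :n_components], float(cumvar[n_components - 1])


def detect_outliers_single(
    feature_matrix: FeatureMatrix,
    seed: int = 0,
    return_explained_variance: bool = False,
):
    """Flag outliers within one feature dataset.

    Pipeline: z-score each non-constant column, project onto principal
    components explaining >= 95% of variance, score with a 100-tree
    isolation forest (subsample min(256, n), automatic threshold).
    Deterministic given ``seed``.
    """
    n = len(feature_matrix.sample_ids)
    if n < 2:
        raise ValueError("need at least 2 samples for outlier detection")
    X = feature_matrix.values
    sd = X.std(axis=0)
    X = X[:, sd > 0]
    if X.shape[1] == 0:
        raise ValueError("all feature columns are constant")
    X = (X - X.mean(axis=0)) / X[:, :].std(axis=0)
    Z, cumvar = pca_reduce(X)
    forest = IsolationForest(
        n_estimators=N_TREES,
        max_samples=min(MAX_SUBSAMPLE, n),
        contamination="auto",
        random_state=seed,
    )
    labels = forest.fit_predict(Z)
    flagged = {
        acc for acc, lab in zip(feature_matrix.sample_ids, labels) if lab == -1
    }
    if return_explained_variance:
        return flagged, cumvar
    return flagged


def consensus_outliers(
    per_feature_flags: dict[str, set[str]],
    n_feature_datasets: int | None = None,
    fraction: float = 0.5,
) -> set[str]:
    """Accessions flagged in at least ``fraction`` of feature datasets
    (inclusive)."""
    if n_feature_datasets is None:
        n_feature_datasets = len(per_feature_flags)
    if n_feature_datasets < 1:
        raise ValueError("need at least one feature dataset")
    counts: dict[str, int] = {}
    for flags in per_feature_flags.values():
        for acc in flags:
            counts[acc] = counts.get(acc, 0) + 1
    return {
        acc for acc, c in counts.items() if c >= fraction * n_feature_datasets
    }


def detect_outliers(
    feature_matrices: dict[str, FeatureMatrix],
    seed: int = 0,
    fraction: float = 0.5,
) -> OutlierReport:
    """Run single-feature detection on every matrix and apply the
    consensus rule across them."""
    per_feature = {
        fid: detect_outliers_single(fm, seed=seed)
        for fid, fm in feature_matrices.items()
    }
    consensus = consensus_outliers(per_feature, len(per_feature), fraction)
    return OutlierReport(
        per_feature_flags=per_feature, consensus=consensus, fraction_threshold=fraction
    )
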