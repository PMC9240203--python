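"""SVM classification of patients vs controls from cluster-mean NH features.

An RBF-kernel SVM is grid-searched over the penalty C and kernel width
gamma (powers of two, the conventional LIBSVM-style grid) under
cross-validation — leave-one-out by default.  Features are z-scored inside
each fold using training rows only, so held-out subjects never leak into
the scaling.  The positive class is the patient group: sensitivity is the
correct-classification rate among patients, specificity among controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.svm import SVC

from .homogeneity import NHMap
from .stats import ClusterResult, extract_cluster_means

__all__ = [
    "ClassificationResult",
    "build_feature_table",
    "cv_svm_grid",
    "performance_report",
    "default_c_grid",
    "default_gamma_grid",
]

POSITIVE = "patient"
NEGATIVE = "control"


def default_c_grid() -> np.ndarray:
    return 2.0 ** np.arange(-5, 16, 2)


def default_gamma_grid() -> np.ndarray:
    return 2.0 ** np.arange(-15, 4, 2)


@dataclass
class ClassificationResult:
    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float  # percent
    sensitivity: float  # percent
    specificity: float  # percent
    best_c: float
    best_gamma: float
    scheme: str
    grid_surface: pd.DataFrame  # accuracy per (C, gamma)

    def summary(self) -> str:
        return (
            f"SVM ({self.scheme}): accuracy {self.accuracy:.2f}% "
            f"({self.tp + self.tn}/{self.tp + self.fn + self.tn + self.fp}), "
            f"sensitivity {self.sensitivity:.2f}% ({self.tp}/{self.tp + self.fn}), "
            f"specificity {self.specificity:.2f}% ({self.tn}/{self.tn + self.fp}); "
            f"best C = {self.best_c:g}, gamma = {self.best_gamma:g}"
        )


def performance_report(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """Accuracy, sensitivity, specificity as percentages from confusion counts."""
    for v in (tp, fn, tn, fp):
        if v < 0:
            raise ValueError("counts must be non-negative")
    total = tp + fn + tn + fp
    if total == 0 or tp + fn == 0 or tn + fp == 0:
        raise ValueError("zero denominator in performance report")
    accuracy = 100.0 * (tp + tn) / total
    sensitivity = 100.0 * tp / (tp + fn)
    specificity = 100.0 * tn / (tn + fp)
    return accuracy, sensitivity, specificity


def build_feature_table(
    nh_maps: list[NHMap],
    clusters: list[ClusterResult],
    phenotype: pd.DataFrame,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """One row per subject: id, group, and mean NH per selected cluster.

    Maps are aligned to phenotype rows by subject id; column order follows
    the cluster list.
    """
    if not clusters:
        raise ValueError("no clusters selected")
    by_id = {m.subject_id: m for m in nh_maps}
    missing = [s for s in phenotype["subject_id"] if s not in by_id]
    if missing:
        raise ValueError(f"NH maps missing for subjects: {missing[:5]}")
    ordered = [by_id[s] for s in phenotype["subject_id"]]
    names = feature_names or [
        f"cluster{i + 1}_{c.direction.replace('>', '_gt_').replace('<', '_lt_')}"
        for i, c in enumerate(clusters)
    ]
    table = pd.DataFrame(
        {
            "subject_id": phenotype["subject_id"].to_numpy(),
            "group": phenotype["group"].to_numpy(),
        }
    )
    for name, cluster in zip(names, clusters):
        table[name] = extract_cluster_means(ordered, cluster)
    return table


def _folds(scheme: str, y: np.ndarray):
    if scheme == "loocv":
        return list(LeaveOneOut().split(np.zeros((y.size, 1)), y))
    if scheme.startswith("kfold"):
        k = int(scheme.split(":")[1]) if ":" in scheme else 5
        skf = StratifiedKFold(n_splits=k, shuffle=False)
        return list(skf.split(np.zeros((y.size, 1)), y))
    raise ValueError(f"unknown scheme {scheme!r}; use 'loocv' or 'kfold:k'")


def cv_svm_grid(
    table: pd.DataFrame,
    c_grid=None,
    gamma_grid=None,
    scheme: str = "loocv",
) -> ClassificationResult:
    """Cross-validated RBF-SVM over a (C, gamma) grid.

    The best pair is chosen by pooled held-out accuracy; ties break toward
    the smaller C, then the smaller gamma, so the result is deterministic.
    Features are standardized per fold on training rows only.
    """
    c_grid = np.asarray(default_c_grid() if c_grid is None else c_grid, dtype=float)
    gamma_grid = np.asarray(
        default_gamma_grid() if gamma_grid is None else gamma_grid, dtype=float
    )
    if c_grid.size == 0 or gamma_grid.size == 0:
        raise ValueError("grids must be non-empty")
    feature_cols = [c for c in table.columns if c not in ("subject_id", "group")]
    if not feature_cols:
        raise ValueError("no feature columns")
    X = table[feature_cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing feature values")
    y = (table["group"].to_numpy() == POSITIVE).astype(int)
    if y.min() == y.max():
        raise ValueError("feature table contains a single class")

    folds = _folds(scheme, y)
    # precompute per-fold standardized data once; reused across the grid
    prepared = []
    for train, test in folds:
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        prepared.append(((X[train] - mu) / sd, y[train], (X[test] - mu) / sd, test))

    n = y.size
    best = None
    surface = []
    for C in c_grid:
        for gamma in gamma_grid:
            pred = np.empty(n, dtype=int)
            for Xtr, ytr, Xte, test in prepared:
                clf = SVC(C=C, gamma=gamma, kernel="rbf")
                clf.fit(Xtr, ytr)
                pred[test] = clf.predict(Xte)
            acc = float((pred == y).mean())
            surface.append({"C": C, "gamma": gamma, "accuracy_pct": 100.0 * acc})
            key = (-acc, C, gamma)
            if best is None or key < best[0]:
                best = (key, C, gamma, pred.copy())

    _, best_c, best_gamma, pred = best
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    accuracy, sensitivity, specificity = performance_report(tp, fn, tn, fp)
    return ClassificationResult(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        best_c=float(best_c),
        best_gamma=float(best_gamma),
        scheme=scheme,
        grid_surface=pd.DataFrame(surface),
    )
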