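"""One-versus-all classification with 10-fold cross-validation.

Each diagnostic class is turned into an independent binary task
(class vs rest). Folds are stratified on the multiclass labels with a
recorded seed so every OVA task sees the same partition; per fold a
confusion matrix is accumulated on the held-out fold and the four
metrics (accuracy, sensitivity/recall, precision, F1) are computed from
it. Reports carry fold-level records so the mean +/- sd summaries can
always be recomputed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import ContractError, StratificationError
from .quantify import META_COLUMNS

ALGORITHMS = ("knn", "naive_bayes", "svm_rbf", "adaboost")


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters for the four supported algorithms."""

    algorithm: str = "knn"
    k_neighbors: int = 5
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    n_estimators: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ContractError(f"unknown algorithm {self.algorithm!r}")
        if self.k_neighbors < 1:
            raise ContractError("k_neighbors must be >= 1")


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    """Accuracy, sensitivity, precision and F1 in [0, 1]."""

    accuracy: float
    sensitivity: float
    precision: float
    f1: float
    zero_division_flags: list[str] = field(default_factory=list)


@dataclass
class CVReport:
    """Fold-level records plus mean/sd summary and the config snapshot."""

    records: pd.DataFrame  # class, algorithm, fold, counts, metrics
    summary: pd.DataFrame  # class, algorithm, metric means and sds
    config: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "records": self.records.to_dict(orient="records"),
            "summary": self.summary.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def make_estimator(cfg: ClassifierConfig):
    """Instantiate the scikit-learn estimator for a config."""
    if cfg.algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=cfg.k_neighbors)
    if cfg.algorithm == "naive_bayes":
        return GaussianNB()
    if cfg.algorithm == "svm_rbf":
        return SVC(kernel="rbf", C=cfg.svm_c, gamma=cfg.svm_gamma)
    return AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=1),
        n_estimators=cfg.n_estimators,
        random_state=cfg.seed,
    )


def ova_binarize(labels: np.ndarray | pd.Series, positive_class) -> np.ndarray:
    """Binary one-versus-all labels: 1 for the positive class, else 0."""
    labels = np.asarray(labels)
    if positive_class not in labels:
        raise ContractError(f"class {positive_class!r} absent from labels")
    return (labels == positive_class).astype(int)


def compute_metrics(cc: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, sensitivity and F1 from confusion counts.

    Undefined ratios (empty denominator) are reported as 0 and flagged.
    """
    n = cc.n_evaluated
    if n == 0:
        raise ContractError("all confusion counts are zero")
    flags: list[str] = []
    accuracy = (cc.tp + cc.tn) / n
    if cc.tp + cc.fp > 0:
        precision = cc.tp / (cc.tp + cc.fp)
    else:
        precision, flags = 0.0, flags + ["precision"]
    if cc.tp + cc.fn > 0:
        sensitivity = cc.tp / (cc.tp + cc.fn)
    else:
        sensitivity, flags = 0.0, flags + ["sensitivity"]
    if precision + sensitivity > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        f1, flags = 0.0, flags + ["f1"]
    return MetricSet(accuracy, sensitivity, precision, f1, flags)


def _feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    feat_cols = [c for c in table.columns if c not in META_COLUMNS]
    if not feat_cols:
        raise ContractError("feature table has no feature columns")
    X = table[feat_cols].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ContractError("feature matrix contains NaN/Inf")
    y = table["label"].to_numpy()
    groups = table["subject_id"].to_numpy()
    return X, y, groups


def crossval_evaluate(
    table: pd.DataFrame,
    cfg: ClassifierConfig = ClassifierConfig(),
    n_folds: int = 10,
    grouping: str = "segment",
) -> CVReport:
    """10-fold one-versus-all cross-validation of one algorithm.

    ``grouping="segment"`` folds rows independently; ``"subject"`` keeps
    all segments of one subject in the same fold (no identity leakage).
    Folds are stratified on the multiclass label with the config seed.
    """
    X, y, groups = _feature_matrix(table)
    classes = sorted(pd.unique(y))
    if len(classes) < 2:
        raise StratificationError("need at least two classes to cross-validate")
    counts = pd.Series(y).value_counts()
    if counts.min() < n_folds:
        raise StratificationError(
            f"class {counts.idxmin()!r} has {counts.min()} samples < {n_folds} folds; "
            "use fewer folds or segment grouping"
        )
    if grouping == "segment":
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed)
        splits = list(splitter.split(X, y))
    elif grouping == "subject":
        splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed)
        splits = list(splitter.split(X, y, groups=groups))
    else:
        raise ContractError(f"unknown grouping {grouping!r}")

    records = []
    for positive in classes:
        y_bin = ova_binarize(y, positive)
        for fold, (train, test) in enumerate(splits):
            if len(np.unique(y_bin[train])) < 2:
                raise StratificationError(
                    f"fold {fold} training split lacks both classes for OVA "
                    f"{positive!r}; use subject grouping or fewer folds"
                )
            est = make_estimator(cfg)
            est.fit(X[train], y_bin[train])
            pred = est.predict(X[test])
            truth = y_bin[test]
            cc = ConfusionCounts(
                tp=int(np.sum((pred == 1) & (truth == 1))),
                tn=int(np.sum((pred == 0) & (truth == 0))),
                fp=int(np.sum((pred == 1) & (truth == 0))),
                fn=int(np.sum((pred == 0) & (truth == 1))),
            )
            ms = compute_metrics(cc)
            records.append(
                {
                    "class": positive, "algorithm": cfg.algorithm, "fold": fold,
                    "tp": cc.tp, "tn": cc.tn, "fp": cc.fp, "fn": cc.fn,
                    "accuracy": ms.accuracy, "sensitivity": ms.sensitivity,
                    "precision": ms.precision, "f1": ms.f1,
                    "zero_division": ",".join(ms.zero_division_flags),
                }
            )
    rec = pd.DataFrame(records)
    metric_cols = ["accuracy", "sensitivity", "precision", "f1"]
    summary = (
        rec.groupby(["class", "algorithm"], as_index=False)[metric_cols]
        .agg(["mean", "std"])
    )
    summary.columns = [
        "_".join(c).rstrip("_") if isinstance(c, tuple) else c for c in summary.columns
    ]
    config = asdict(cfg) | {"n_folds": n_folds, "grouping": grouping}
    return CVReport(records=rec, summary=summary, config=config)


def evaluate_all(
    table: pd.DataFrame,
    base_cfg: ClassifierConfig = ClassifierConfig(),
    algorithms: tuple[str, ...] = ALGORITHMS,
    n_folds: int = 10,
    grouping: str = "segment",
) -> CVReport:
    """Run every algorithm under one fold partition; concatenated report."""
    from dataclasses import replace

    reports = [
        crossval_evaluate(table, replace(base_cfg, algorithm=a), n_folds, grouping)
        for a in algorithms
    ]
    records = pd.concat([r.records for r in reports], ignore_index=True)
    summary = pd.concat([r.summary for r in reports], ignore_index=True)
    config = asdict(base_cfg) | {
        "n_folds": n_folds, "grouping": grouping, "algorithms": list(algorithms),
    }
    return CVReport(records=records, summary=summary, config=config)


def summary_percent(report: CVReport, decimals: int = 2) -> pd.DataFrame:
    """Summary table with metrics as 'mean ± sd' percent strings."""
    out = report.summary[["class", "algorithm"]].copy()
    for metric in ("accuracy", "sensitivity", "f1", "precision"):
        mean = report.summary[f"{metric}_mean"] * 100
        sd = report.summary[f"{metric}_std"].fillna(0.0) * 100
        out[metric] = [
            f"{m:.{decimals}f} ± {s:.{decimals}f}" for m, s in zip(mean, sd)
        ]
    return out
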