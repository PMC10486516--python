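"""Benchmark of seven classifier families on De Bruijn k-mer features.

The benchmark reproduces a fixed protocol per k-mer length: featurize the
cohort, make one stratified 80/20 split shared by every model (so later
paired comparisons are valid), tune each family by grid search with
stratified cross-validation on the training rows only, refit on the full
training set, and score the common held-out test set with accuracy,
precision, F-score, Cohen's kappa and ROC AUC.

Families: Random Forest (RF), Support Vector Machine (SVM), XGBoost
(XGB), LightGBM (LGBM), Gaussian Naive Bayes (GNB), Logistic Regression
(LR) and k-Nearest Neighbors (KNN).  Default grids are modest and fully
overridable; grid search selects by mean CV accuracy with ties broken by
grid order.  Features enter the models as raw counts by default — the
scale-sensitive families (SVM, LR, KNN) can be given standardized inputs
via a flag.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    cohen_kappa_score,
    confusion_matrix,
    f1_score,
    precision_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .debruijn import FeatureMatrix, featurize_cohort
from .fastq_io import CleanSample

__all__ = [
    "MODEL_FAMILIES",
    "SplitSpec",
    "ModelSpec",
    "GridResult",
    "EvalReport",
    "BenchConfig",
    "BenchmarkResult",
    "default_model_specs",
    "make_estimator",
    "split",
    "grid_search",
    "train_predict",
    "evaluate",
    "run_benchmark",
]

MODEL_FAMILIES = ("RF", "SVM", "XGB", "LGBM", "GNB", "LR", "KNN")

DEFAULT_GRIDS: dict[str, dict[str, list[Any]]] = {
    "RF": {"n_estimators": [100, 300, 500], "max_depth": [None, 10, 20]},
    "SVM": {"C": [0.1, 1.0, 10.0], "kernel": ["rbf", "linear"]},
    "XGB": {
        "learning_rate": [0.05, 0.1],
        "n_estimators": [100, 300],
        "max_depth": [3, 6],
    },
    "LGBM": {
        "learning_rate": [0.05, 0.1],
        "n_estimators": [100, 300],
        "max_depth": [-1, 3, 6],
    },
    "GNB": {},
    "LR": {"C": [0.1, 1.0, 10.0]},
    "KNN": {"n_neighbors": [3, 5, 11]},
}


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split protocol: 80/20, stratified, seeded."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class ModelSpec:
    """A classifier family plus its hyperparameter grid."""

    family: str
    grid: dict[str, list[Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {MODEL_FAMILIES}"
            )

    def grid_points(self) -> list[dict[str, Any]]:
        """Enumerate the grid in deterministic grid order: parameters in
        insertion order, with the last parameter varying fastest."""
        if not self.grid:
            return [{}]
        keys = list(self.grid)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.grid[k] for k in keys))
        ]


def default_model_specs(
    grids: Optional[dict[str, dict[str, list[Any]]]] = None,
) -> list[ModelSpec]:
    """The seven benchmark families with default (or overridden) grids."""
    grids = grids or {}
    return [
        ModelSpec(family=f, grid=grids.get(f, DEFAULT_GRIDS[f]))
        for f in MODEL_FAMILIES
    ]


def make_estimator(family: str, params: dict[str, Any], seed: int = 0):
    """Instantiate one classifier with fixed seed and single-threaded fit."""
    if family == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "SVM":
        return SVC(random_state=seed, **params)
    if family == "XGB":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, n_jobs=1, tree_method="hist",
            eval_metric="logloss", verbosity=0, **params,
        )
    if family == "LGBM":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            random_state=seed, n_jobs=1, verbose=-1,
            deterministic=True, force_row_wise=True, **params,
        )
    if family == "GNB":
        return GaussianNB(**params)
    if family == "LR":
        return LogisticRegression(random_state=seed, max_iter=2000, **params)
    if family == "KNN":
        return KNeighborsClassifier(n_jobs=1, **params)
    raise ValueError(f"unknown family {family!r}")


def split(
    matrix: FeatureMatrix, spec: SplitSpec = SplitSpec()
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Split a labeled FeatureMatrix into disjoint train/test matrices.

    Stratification keeps per-class proportions within one sample of the
    split fraction.  Deterministic given the spec's seed.
    """
    if matrix.labels is None or matrix.labels.isna().any():
        raise ValueError("every row must be labeled before splitting")
    labels = matrix.labels.astype(int)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present")
    if (counts < 2).any():
        raise ValueError(f"a class has < 2 samples: {counts.to_dict()}")
    idx_train, idx_test = train_test_split(
        np.arange(matrix.n_samples),
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=labels.to_numpy() if spec.stratified else None,
        shuffle=True,
    )
    idx_train.sort()
    idx_test.sort()

    def take(idx: np.ndarray) -> FeatureMatrix:
        return FeatureMatrix(
            k=matrix.k,
            data=matrix.data.iloc[idx],
            labels=labels.iloc[idx],
        )

    return take(idx_train), take(idx_test)


@dataclass
class GridResult:
    """Outcome of a grid search over one family."""

    family: str
    best_params: dict[str, Any]
    best_cv_accuracy: float
    cv_results: list[dict[str, Any]] = field(default_factory=list)
    failed_points: list[dict[str, Any]] = field(default_factory=list)


def grid_search(
    spec: ModelSpec,
    train: FeatureMatrix,
    folds: int = 5,
    seed: int = 0,
) -> GridResult:
    """Select hyperparameters by stratified CV accuracy on training rows.

    Every grid point is scored by mean accuracy across ``folds``
    stratified folds of the training set (the test set is never seen).
    The first grid point attaining the maximum wins; points that fail to
    fit are recorded and excluded, and an all-failed grid is an error.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = train.data.to_numpy(dtype=float)
    y = train.labels.to_numpy(dtype=int)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_indices = list(cv.split(X, y))
    results: list[dict[str, Any]] = []
    failures: list[dict[str, Any]] = []
    best_idx, best_score = -1, -np.inf
    for point_idx, params in enumerate(spec.grid_points()):
        try:
            base = make_estimator(spec.family, params, seed=seed)
            scores = []
            for tr_idx, va_idx in fold_indices:
                est = clone(base)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[tr_idx], y[tr_idx])
                    pred_va = est.predict(X[va_idx])
                scores.append(accuracy_score(y[va_idx], pred_va))
            mean_acc = float(np.mean(scores))
        except Exception as exc:  # noqa: BLE001 - any fit failure disqualifies
            failures.append({"params": params, "error": str(exc)})
            continue
        results.append({"params": params, "mean_cv_accuracy": mean_acc})
        if mean_acc > best_score:  # strict '>' keeps the first of a tie
            best_score, best_idx = mean_acc, len(results) - 1
    if not results:
        raise RuntimeError(
            f"{spec.family}: every grid point failed to fit: {failures}"
        )
    return GridResult(
        family=spec.family,
        best_params=results[best_idx]["params"],
        best_cv_accuracy=best_score,
        cv_results=results,
        failed_points=failures,
    )


def train_predict(
    family: str,
    params: dict[str, Any],
    train: FeatureMatrix,
    test: FeatureMatrix,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit on the training matrix, return (hard labels, scores) on test.

    Scores are class-1 probabilities where the model provides them and
    the signed decision value otherwise (SVM without calibration).
    """
    est = make_estimator(family, params, seed=seed)
    X_tr = train.data.to_numpy(dtype=float)
    X_te = test.data.to_numpy(dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X_tr, train.labels.to_numpy(dtype=int))
    except Exception as exc:
        raise RuntimeError(f"{family}: fit failed: {exc}") from exc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = np.asarray(est.predict(X_te), dtype=int)
        if hasattr(est, "predict_proba"):
            score = np.asarray(est.predict_proba(X_te))[:, 1]
        else:
            score = np.asarray(est.decision_function(X_te), dtype=float)
    return pred, score


@dataclass
class EvalReport:
    """Test-set metrics for one model, with the counts behind them."""

    family: str
    accuracy: float
    precision: float
    fscore: float
    kappa: float
    auc: Optional[float]
    tn: int
    fp: int
    fn: int
    tp: int
    chosen_params: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "family": self.family,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "fscore": self.fscore,
            "kappa": self.kappa,
            "auc": self.auc,
            "confusion": {"tn": self.tn, "fp": self.fp, "fn": self.fn, "tp": self.tp},
            "chosen_params": self.chosen_params,
        }


def evaluate(
    pred: np.ndarray,
    score: np.ndarray,
    truth: np.ndarray,
    family: str = "",
    chosen_params: Optional[dict[str, Any]] = None,
) -> EvalReport:
    """Compute the five benchmark metrics with positive class = diseased.

    AUC is the rank statistic: the probability a random positive outscores
    a random negative, ties counted half.  If the truth is single-class
    AUC is undefined and reported as None with a warning.
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    score = np.asarray(score, dtype=float)
    if not (len(pred) == len(truth) == len(score)):
        raise ValueError("pred, score and truth must have equal lengths")
    tn, fp, fn, tp = confusion_matrix(truth, pred, labels=[0, 1]).ravel()
    if len(np.unique(truth)) < 2:
        warnings.warn("single-class truth: AUC undefined", stacklevel=2)
        auc = None
    else:
        auc = float(roc_auc_score(truth, score))
    return EvalReport(
        family=family,
        accuracy=float(accuracy_score(truth, pred)),
        precision=float(precision_score(truth, pred, pos_label=1, zero_division=0)),
        fscore=float(f1_score(truth, pred, pos_label=1, zero_division=0)),
        kappa=float(cohen_kappa_score(truth, pred)),
        auc=auc,
        tn=int(tn), fp=int(fp), fn=int(fn), tp=int(tp),
        chosen_params=dict(chosen_params or {}),
    )


@dataclass
class BenchConfig:
    """Everything a benchmark run needs beyond the data."""

    ks: Sequence[int] = (3, 4, 5)
    folds: int = 5
    split: SplitSpec = field(default_factory=SplitSpec)
    model_seed: int = 0
    standardize: bool = False
    normalize: bool = False
    grids: Optional[dict[str, dict[str, list[Any]]]] = None
    families: Sequence[str] = MODEL_FAMILIES


@dataclass
class BenchmarkResult:
    """Nested benchmark report: k -> family -> EvalReport, plus the
    per-model test predictions needed for paired model comparison."""

    reports: dict[int, dict[str, EvalReport]]
    predictions: dict[int, pd.DataFrame]
    grid_results: dict[int, dict[str, GridResult]]
    config: BenchConfig

    def metrics_frame(self) -> pd.DataFrame:
        """Flat (k, model, metric, value) table."""
        rows = []
        for k, by_model in self.reports.items():
            for family, rep in by_model.items():
                for metric in ("accuracy", "precision", "fscore", "kappa", "auc"):
                    rows.append(
                        {"k": k, "model": family, "metric": metric,
                         "value": getattr(rep, metric)}
                    )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict[str, Any]:
        return {
            str(k): {f: rep.to_dict() for f, rep in by_model.items()}
            for k, by_model in self.reports.items()
        }

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(self.to_json_dict(), indent=2) + "\n"
        )
        self.metrics_frame().to_csv(out_dir / "metrics.csv", index=False)
        for k, preds in self.predictions.items():
            for family, grp in preds.groupby("model", sort=False):
                grp[["sample_id", "truth", "pred", "score"]].to_csv(
                    out_dir / f"predictions_k{k}_{family}.csv", index=False
                )


def _maybe_transform(train: FeatureMatrix, test: FeatureMatrix,
                     config: BenchConfig) -> tuple[FeatureMatrix, FeatureMatrix]:
    if config.normalize:
        train, test = train.normalized(), test.normalized()
    if config.standardize:
        scaler = StandardScaler().fit(train.data.to_numpy(dtype=float))
        train = FeatureMatrix(
            train.k,
            pd.DataFrame(scaler.transform(train.data), index=train.data.index,
                         columns=train.data.columns),
            train.labels,
        )
        test = FeatureMatrix(
            test.k,
            pd.DataFrame(scaler.transform(test.data), index=test.data.index,
                         columns=test.data.columns),
            test.labels,
        )
    return train, test


def run_benchmark(
    samples: Sequence[CleanSample],
    config: BenchConfig = BenchConfig(),
) -> BenchmarkResult:
    """Run the full per-k benchmark on a labeled cohort.

    For each k: featurize, split once (the same split serves all models,
    making their test predictions paired), grid-search each family on the
    training rows, refit with the chosen configuration, and evaluate on
    the common test set.
    """
    if not config.ks:
        raise ValueError("ks must be nonempty")
    specs = [
        s for s in default_model_specs(config.grids)
        if s.family in set(config.families)
    ]
    reports: dict[int, dict[str, EvalReport]] = {}
    predictions: dict[int, pd.DataFrame] = {}
    grid_results: dict[int, dict[str, GridResult]] = {}
    for k in config.ks:
        matrix = featurize_cohort(samples, k)
        train, test = split(matrix, config.split)
        train, test = _maybe_transform(train, test, config)
        truth = test.labels.to_numpy(dtype=int)
        reports[k], grid_results[k] = {}, {}
        pred_rows = []
        for spec in specs:
            gres = grid_search(spec, train, folds=config.folds,
                               seed=config.model_seed)
            pred, score = train_predict(
                spec.family, gres.best_params, train, test,
                seed=config.model_seed,
            )
            reports[k][spec.family] = evaluate(
                pred, score, truth, family=spec.family,
                chosen_params=gres.best_params,
            )
            grid_results[k][spec.family] = gres
            pred_rows.append(pd.DataFrame({
                "model": spec.family,
                "sample_id": test.sample_ids,
                "truth": truth,
                "pred": pred,
                "score": score,
            }))
        predictions[k] = pd.concat(pred_rows, ignore_index=True)
    return BenchmarkResult(
        reports=reports, predictions=predictions,
        grid_results=grid_results, config=config,
    )
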