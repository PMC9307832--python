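"""Logistic-regression classifier and the repeated-holdout workflow.

The classifier is a binary L2-regularized logistic regression (class II
encoded 0, class III encoded 1): p(III | x) = 1 / (1 + exp(-(b0 + b.x))).
Hyperparameters mirror the tuned grid — solver (newton-cg, lbfgs, sag,
saga), max_iter (1000, 5000, 10000) and class_weight (balanced, None) —
with the regularization left at the default strength C = 1.0 (tunable).

The selection workflow repeats, ``n_runs`` times: a uniform random
80/20 train/test split, a fit on the training split, and an accuracy
score on the held-out 20%.  Runs whose holdout accuracy exceeds the 80%
gate (strict) are "kept": a 10-fold cross-validation on the full data
set is then recorded to check that accuracy does not collapse under CV,
and the kept runs' coefficients are averaged into the reported model.
The mean holdout accuracy is reported over all runs; the mean CV
accuracy and coefficients over kept runs only.  Running CV on the full
set after the holdout gate is an optimistic-bias choice inherited from
the original protocol and is documented as such.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, KFold, cross_val_score, train_test_split

logger = logging.getLogger(__name__)

LABEL_ENCODING = {"II": 0, "III": 1}

DEFAULT_GRID = {
    "class_weight": ["balanced", None],
    "solver": ["newton-cg", "lbfgs", "sag", "saga"],
    "max_iter": [1000, 5000, 10000],
}


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class Hyperparams:
    solver: str = "newton-cg"
    max_iter: int = 1000
    class_weight: str | None = None
    C: float = 1.0

    def estimator(self) -> LogisticRegression:
        # L2 penalty is the estimator default; only its strength is exposed
        return LogisticRegression(
            solver=self.solver, max_iter=self.max_iter,
            class_weight=self.class_weight, C=self.C)


@dataclass
class TrainedModel:
    feature_names: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    hyperparams: Hyperparams
    label_encoding: dict[str, int] = field(
        default_factory=lambda: dict(LABEL_ENCODING))
    converged: bool = True

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.feature_names):
            raise ModelError(
                f"{len(self.coefficients)} coefficients for "
                f"{len(self.feature_names)} features")

    def decision(self, x: np.ndarray) -> float:
        return float(self.intercept + self.coefficients @ np.asarray(x, dtype=float))

    def predict_proba(self, x: np.ndarray) -> float:
        """Probability of class III."""
        return float(1.0 / (1.0 + np.exp(-self.decision(x))))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "hyperparams": asdict(self.hyperparams),
            "label_encoding": self.label_encoding,
            "converged": self.converged,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            feature_names=tuple(payload["feature_names"]),
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            intercept=float(payload["intercept"]),
            hyperparams=Hyperparams(**payload["hyperparams"]),
            label_encoding={k: int(v) for k, v in payload["label_encoding"].items()},
            converged=bool(payload.get("converged", True)),
        )


def encode_labels(labels) -> np.ndarray:
    """Map class labels II/III (or already-binary values) to {0, 1}."""
    out = []
    for lab in labels:
        if lab in LABEL_ENCODING:
            out.append(LABEL_ENCODING[lab])
        elif lab in (0, 1):
            out.append(int(lab))
        else:
            raise ModelError(f"unknown class label {lab!r}")
    return np.asarray(out, dtype=int)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.dtype.kind not in "iub":
        y = encode_labels(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ModelError(f"shape mismatch: X {X.shape}, y {y.shape}")
    if not np.isfinite(X).all():
        raise ModelError("selected features contain missing values; "
                         "restrict the feature subset or the mutation list")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ModelError("training labels contain a single class")
    if counts.min() < 2:
        raise ModelError("need at least 2 rows per class")
    return X, y


def fit_logistic(
    X: np.ndarray | pd.DataFrame,
    y,
    hyperparams: Hyperparams | None = None,
    feature_names: tuple[str, ...] | None = None,
) -> TrainedModel:
    """Fit the binary logistic model; non-convergence sets a flag, not an error."""
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or tuple(X.columns)
        X = X.to_numpy(dtype=float)
    X, y = _check_xy(X, y)
    hp = hyperparams or Hyperparams()
    est = hp.estimator()
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        est.fit(X, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            logger.warning("logistic fit did not converge at max_iter=%d",
                           hp.max_iter)
    names = feature_names or tuple(f"x{i}" for i in range(X.shape[1]))
    return TrainedModel(
        feature_names=names,
        coefficients=est.coef_.ravel(),
        intercept=float(est.intercept_[0]),
        hyperparams=hp,
        converged=converged,
    )


def predict(model: TrainedModel, x: dict[str, float] | np.ndarray | pd.Series):
    """Probability of class III and the hard label (threshold 0.5)."""
    if isinstance(x, pd.Series):
        x = x.to_dict()
    if isinstance(x, dict):
        missing = [n for n in model.feature_names if n not in x]
        if missing:
            raise ModelError(f"missing feature(s) {missing}")
        x = np.asarray([x[n] for n in model.feature_names], dtype=float)
    else:
        x = np.asarray(x, dtype=float)
        if x.shape != (len(model.feature_names),):
            raise ModelError(
                f"expected {len(model.feature_names)} features, got {x.shape}")
    p = model.predict_proba(x)
    label = "III" if p >= 0.5 else "II"
    return p, label


def grid_search(
    X: np.ndarray | pd.DataFrame,
    y,
    grid: dict[str, list] | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> tuple[Hyperparams, pd.DataFrame]:
    """Exhaustive hyperparameter search ranked by mean CV accuracy.

    Ties are broken by grid order (cartesian product order of the grid
    dict).  Returns the winning :class:`Hyperparams` and the full
    results table.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X, y = _check_xy(X, y)
    grid = grid or DEFAULT_GRID
    if not all(grid.values()):
        raise ModelError("empty hyperparameter grid")
    keys = list(grid)
    rows = []
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for combo in product(*(grid[k] for k in keys)):
            hp = Hyperparams(**dict(zip(keys, combo)))
            scores = cross_val_score(hp.estimator(), X, y, cv=cv,
                                     scoring="accuracy")
            rows.append({**dict(zip(keys, combo)),
                         "mean_cv_accuracy": float(scores.mean())})
    results = pd.DataFrame(rows)
    best_idx = int(results["mean_cv_accuracy"].to_numpy().argmax())  # first max wins
    best = rows[best_idx]
    kwargs = {k: best[k] for k in keys if k in Hyperparams.__dataclass_fields__}
    if "max_iter" in kwargs:
        kwargs["max_iter"] = int(kwargs["max_iter"])
    return Hyperparams(**kwargs), results


@dataclass
class WorkflowReport:
    n_runs: int
    kept_runs: int
    mean_test_accuracy: float       # %, over all runs
    mean_cv_accuracy: float         # %, over kept runs (NaN if none kept)
    mean_kept_test_accuracy: float  # %, over kept runs (NaN if none kept)
    mean_coefficients: np.ndarray
    mean_intercept: float
    feature_names: tuple[str, ...]
    per_run: pd.DataFrame           # columns: test_accuracy, cv_accuracy, kept

    def best_model(self, hyperparams: Hyperparams) -> TrainedModel:
        """Averaged-coefficient model over the kept runs."""
        if self.kept_runs == 0:
            raise ModelError("no kept runs: averaged model undefined")
        return TrainedModel(
            feature_names=self.feature_names,
            coefficients=self.mean_coefficients,
            intercept=self.mean_intercept,
            hyperparams=hyperparams,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_runs": self.n_runs,
            "kept_runs": self.kept_runs,
            "mean_test_accuracy": self.mean_test_accuracy,
            "mean_cv_accuracy": self.mean_cv_accuracy,
            "mean_kept_test_accuracy": self.mean_kept_test_accuracy,
            "mean_coefficients": self.mean_coefficients.tolist(),
            "mean_intercept": self.mean_intercept,
            "feature_names": list(self.feature_names),
            "per_run": self.per_run.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def run_workflow(
    X: np.ndarray | pd.DataFrame,
    y,
    hyperparams: Hyperparams | None = None,
    n_runs: int = 1000,
    gate: float = 80.0,
    cv_folds: int = 10,
    test_size: float = 0.2,
    seed: int = 0,
    feature_names: tuple[str, ...] | None = None,
) -> WorkflowReport:
    """Repeated-holdout training workflow (see module docstring).

    Fully reproducible for a fixed ``seed``: every split and CV fold
    shuffle derives from one seeded generator.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or tuple(X.columns)
        X = X.to_numpy(dtype=float)
    X, y = _check_xy(X, y)
    names = feature_names or tuple(f"x{i}" for i in range(X.shape[1]))
    hp = hyperparams or Hyperparams()
    rng = np.random.default_rng(seed)

    records = []
    kept_coefs, kept_intercepts = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(n_runs):
            split_seed = int(rng.integers(0, 2**31 - 1))
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, test_size=test_size, random_state=split_seed,
                shuffle=True, stratify=None)
            if len(np.unique(y_tr)) < 2:
                records.append({"test_accuracy": np.nan,
                                "cv_accuracy": np.nan, "kept": False})
                continue
            est = hp.estimator()
            est.fit(X_tr, y_tr)
            acc = float((est.predict(X_te) == y_te).mean()) * 100.0
            kept = acc > gate
            cv_acc = np.nan
            if kept:
                cv = KFold(n_splits=cv_folds, shuffle=True,
                           random_state=int(rng.integers(0, 2**31 - 1)))
                cv_acc = float(cross_val_score(
                    hp.estimator(), X, y, cv=cv, scoring="accuracy").mean()) * 100.0
                kept_coefs.append(est.coef_.ravel())
                kept_intercepts.append(float(est.intercept_[0]))
            records.append({"test_accuracy": acc, "cv_accuracy": cv_acc,
                            "kept": kept})

    per_run = pd.DataFrame(records)
    kept_runs = int(per_run["kept"].sum())
    if kept_runs == 0:
        logger.warning("no run passed the %.0f%% accuracy gate", gate)
        mean_coefs = np.full(len(names), np.nan)
        mean_intercept = float("nan")
    else:
        mean_coefs = np.mean(kept_coefs, axis=0)
        mean_intercept = float(np.mean(kept_intercepts))
    return WorkflowReport(
        n_runs=n_runs,
        kept_runs=kept_runs,
        mean_test_accuracy=float(np.nanmean(per_run["test_accuracy"])),
        mean_cv_accuracy=(float(per_run.loc[per_run["kept"], "cv_accuracy"].mean())
                          if kept_runs else float("nan")),
        mean_kept_test_accuracy=(float(per_run.loc[per_run["kept"], "test_accuracy"].mean())
                                 if kept_runs else float("nan")),
        mean_coefficients=mean_coefs,
        mean_intercept=mean_intercept,
        feature_names=names,
        per_run=per_run,
    )
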