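"""y-randomization robustness check.

A model trained on data whose class labels have been randomly permuted
should perform at chance level; if it does not, the real model's
accuracy is an artifact of overfitting.  Each run permutes the labels
(a shuffle, so the 26/24 class balance is preserved exactly), performs
one uniform 80/20 train/test split, fits the logistic model and records
the holdout accuracy.  No accuracy gate is applied — every run's
accuracy enters the distribution, which is summarized as mean, min,
max and boxplot quartiles.  The diagnostic passes when the randomized
mean sits near the chance level implied by the label balance and no
randomized run reaches the real model's accuracy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import train_test_split

from .model import Hyperparams, _check_xy


@dataclass
class YRandReport:
    n_runs: int
    accuracies: np.ndarray  # %, one per run

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def min(self) -> float:
        return float(np.min(self.accuracies))

    @property
    def max(self) -> float:
        return float(np.max(self.accuracies))

    def boxplot_stats(self) -> dict[str, float]:
        """Quartiles and Tukey whiskers of the accuracy distribution."""
        q1, med, q3 = np.percentile(self.accuracies, [25, 50, 75])
        iqr = q3 - q1
        lo = float(self.accuracies[self.accuracies >= q1 - 1.5 * iqr].min())
        hi = float(self.accuracies[self.accuracies <= q3 + 1.5 * iqr].max())
        return {"q1": float(q1), "median": float(med), "q3": float(q3),
                "whisker_low": lo, "whisker_high": hi}

    def to_json(self, path: str | Path) -> None:
        payload = {"n_runs": self.n_runs, "mean": self.mean,
                   "min": self.min, "max": self.max,
                   "boxplot": self.boxplot_stats(),
                   "accuracies": self.accuracies.tolist()}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def y_randomize(
    X: np.ndarray | pd.DataFrame,
    y,
    hyperparams: Hyperparams | None = None,
    n_runs: int = 100,
    test_size: float = 0.2,
    seed: int = 0,
) -> YRandReport:
    """Label-permutation null distribution of holdout accuracies."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X, y = _check_xy(X, y)
    hp = hyperparams or Hyperparams()
    rng = np.random.default_rng(seed)
    accs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(n_runs):
            y_perm = rng.permutation(y)
            split_seed = int(rng.integers(0, 2**31 - 1))
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y_perm, test_size=test_size, random_state=split_seed)
            if len(np.unique(y_tr)) < 2:  # pathological tiny-split case
                accs.append(float((y_te == y_tr[0]).mean()) * 100.0)
                continue
            est = hp.estimator()
            est.fit(X_tr, y_tr)
            accs.append(float((est.predict(X_te) == y_te).mean()) * 100.0)
    return YRandReport(n_runs=n_runs, accuracies=np.asarray(accs))
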