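"""The six screening classifiers behind one uniform interface.

Methods: random forest (RF), gradient boosting (GB), Gaussian naive Bayes
(NB), RBF-kernel support vector machine (SVM), L2 logistic regression (LR,
liblinear) and a multi-layer perceptron (MLP, logistic activations, equal
hidden-layer widths).  RF/GB/MLP architectures are grid-searched by mean F1;
the MLP additionally supports a validation-based early-stopping protocol
(stop once more than 75 epochs have run and the validation log-loss improves
by less than 1e-3 between consecutive epochs, cap 200).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, log_loss
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "METHODS",
    "FULL_GRIDS",
    "DESK_GRIDS",
    "ClassifierConfig",
    "TrainedClassifier",
    "make_estimator",
    "train",
    "grid_search",
    "should_stop",
    "train_with_early_stopping",
    "save_model",
    "load_model",
]

METHODS = ("RF", "GB", "NB", "SVM", "LR", "MLP")

#: the full grids: trees 10–400 step 10 x depth 20–200 step 10 (RF);
#: depth 2–20 step 1 x trees 10–100 step 10 (GB);
#: neurons 10–200 step 10 x layers 1–6 (MLP)
FULL_GRIDS: dict[str, dict[str, list]] = {
    "RF": {"n_estimators": list(range(10, 401, 10)),
           "max_depth": list(range(20, 201, 10))},
    "GB": {"max_depth": list(range(2, 21, 1)),
           "n_estimators": list(range(10, 101, 10))},
    "MLP": {"neurons": list(range(10, 201, 10)),
            "layers": list(range(1, 7))},
}

#: thinned grids for desk-scale runs (full grids available via FULL_GRIDS)
DESK_GRIDS: dict[str, dict[str, list]] = {
    "RF": {"n_estimators": [50, 100, 200], "max_depth": [20, 50]},
    "GB": {"max_depth": [3, 6, 9], "n_estimators": [50, 100]},
    "MLP": {"neurons": [20, 60, 100], "layers": [1, 2]},
}


@dataclass(frozen=True)
class ClassifierConfig:
    """Method + hyper-parameters + seed."""

    method: str
    params: tuple[tuple[str, object], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if isinstance(self.params, dict):
            object.__setattr__(self, "params", tuple(sorted(self.params.items())))

    @property
    def param_dict(self) -> dict:
        return dict(self.params)


@dataclass
class TrainedClassifier:
    """A fitted model plus its training metadata."""

    model: object
    config: ClassifierConfig
    n_iterations: int | None = None
    early_stopped: bool = False
    train_loss_trace: list[float] = field(default_factory=list)
    validation_loss_trace: list[float] = field(default_factory=list)

    def predict(self, X):
        return self.model.predict(X)


def make_estimator(config: ClassifierConfig):
    """Instantiate the sklearn estimator for a config (unfitted)."""
    p = config.param_dict
    m = config.method
    if m == "RF":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 100),
            max_depth=p.get("max_depth", None),
            random_state=config.seed)
    if m == "GB":
        return GradientBoostingClassifier(
            n_estimators=p.get("n_estimators", 100),
            max_depth=p.get("max_depth", 3),
            random_state=config.seed)
    if m == "NB":
        return GaussianNB()
    if m == "SVM":
        return SVC(kernel="rbf", gamma="scale", random_state=config.seed)
    if m == "LR":
        return LogisticRegression(solver="liblinear", random_state=config.seed)
    if m == "MLP":
        layers = (p.get("neurons", 100),) * p.get("layers", 1)
        return MLPClassifier(
            hidden_layer_sizes=layers, activation="logistic",
            max_iter=p.get("max_iter", 200), random_state=config.seed)
    raise AssertionError(m)


def train(config: ClassifierConfig, X_train, y_train) -> TrainedClassifier:
    """Fit one classifier; deterministic for a fixed seed."""
    est = make_estimator(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X_train, y_train)
    n_iter = getattr(est, "n_iter_", None)
    if n_iter is not None:
        n_iter = int(np.max(n_iter))
    return TrainedClassifier(model=est, config=config, n_iterations=n_iter)


def _grid_points(grid: dict[str, list]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, vals)) for vals in product(*(grid[k] for k in keys))]


def grid_search(
    method: str,
    folds,
    grid: dict[str, list] | None = None,
    seed: int = 0,
    feature_fn=None,
) -> tuple[ClassifierConfig, pd.DataFrame]:
    """Exhaustive grid search maximising mean held-out F1 across folds.

    ``folds`` is a sequence of (X_train, y_train, X_test, y_test) tuples, or
    of :class:`~pulsescreen.population.MLDataset` when ``feature_fn`` maps a
    patient list to (X, y).  Ties keep the first grid point in iteration
    order.  Returns the best config and the full score table (one row per
    grid point).
    """
    if grid is None:
        grid = DESK_GRIDS.get(method, {})
    points = _grid_points(grid) if grid else [{}]
    if not points:
        raise ValueError("empty hyper-parameter grid")

    mats = []
    for f in folds:
        if feature_fn is not None:
            Xtr, ytr = feature_fn(f.train)
            Xte, yte = feature_fn(f.test)
            mats.append((Xtr, ytr, Xte, yte))
        else:
            mats.append(f)

    rows = []
    best = None
    for pt in points:
        scores = []
        for Xtr, ytr, Xte, yte in mats:
            tc = train(ClassifierConfig(method, tuple(sorted(pt.items())), seed), Xtr, ytr)
            scores.append(f1_score(yte, tc.predict(Xte), zero_division=0))
        mean_f1 = float(np.mean(scores))
        rows.append({**pt, "mean_f1": mean_f1})
        if best is None or mean_f1 > best[0]:  # strict: first point wins ties
            best = (mean_f1, pt)
    table = pd.DataFrame(rows)
    cfg = ClassifierConfig(method, tuple(sorted(best[1].items())), seed)
    return cfg, table


def save_model(trained: TrainedClassifier, path) -> None:
    """Serialise a trained classifier with a config+seed manifest sidecar."""
    import json
    from pathlib import Path

    import joblib

    path = Path(path)
    joblib.dump(trained.model, path)
    manifest = {
        "method": trained.config.method,
        "params": dict(trained.config.params),
        "seed": trained.config.seed,
        "n_iterations": trained.n_iterations,
        "early_stopped": trained.early_stopped,
    }
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))


def load_model(path) -> TrainedClassifier:
    """Load a classifier saved by :func:`save_model`."""
    import json
    from pathlib import Path

    import joblib

    path = Path(path)
    manifest = json.loads(
        path.with_suffix(path.suffix + ".manifest.json").read_text())
    cfg = ClassifierConfig(manifest["method"],
                           tuple(sorted(manifest["params"].items())),
                           seed=manifest["seed"])
    return TrainedClassifier(model=joblib.load(path), config=cfg,
                             n_iterations=manifest["n_iterations"],
                             early_stopped=manifest["early_stopped"])


def should_stop(
    val_trace,
    iteration: int,
    min_iterations: int = 75,
    improvement_threshold: float = 1e-3,
) -> bool:
    """The early-stopping rule: more than ``min_iterations`` done and the
    last consecutive validation log-loss improvement below the threshold."""
    if iteration <= min_iterations or len(val_trace) < 2:
        return False
    return (val_trace[-2] - val_trace[-1]) < improvement_threshold


def train_with_early_stopping(
    config: ClassifierConfig,
    X_train, y_train, X_val, y_val,
    min_iterations: int = 75,
    improvement_threshold: float = 1e-3,
    max_iterations: int = 200,
) -> TrainedClassifier:
    """Epoch-wise MLP training with validation-loss early stopping.

    After each epoch the validation log-loss is computed; once more than
    ``min_iterations`` epochs have run and the improvement between two
    consecutive epochs falls below ``improvement_threshold``, training stops
    (the returned model is the state at the stopping epoch).  Otherwise
    training runs to ``max_iterations``.  Train/validation loss traces are
    recorded for overfitting diagnostics.
    """
    if config.method != "MLP":
        raise ValueError("early stopping protocol applies to the MLP method")
    if X_val is None or len(X_val) == 0:
        raise ValueError("early stopping requires a validation partition")
    p = config.param_dict
    layers = (p.get("neurons", 100),) * p.get("layers", 1)
    est = MLPClassifier(hidden_layer_sizes=layers, activation="logistic",
                        max_iter=1, warm_start=True, random_state=config.seed)
    classes = np.unique(y_train)
    train_trace: list[float] = []
    val_trace: list[float] = []
    stopped = False
    it = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for it in range(1, max_iterations + 1):
            est.fit(X_train, y_train)
            train_trace.append(log_loss(y_train, est.predict_proba(X_train),
                                        labels=classes))
            val_trace.append(log_loss(y_val, est.predict_proba(X_val),
                                      labels=classes))
            if should_stop(val_trace, it, min_iterations, improvement_threshold):
                stopped = True
                break
    return TrainedClassifier(model=est, config=config, n_iterations=it,
                             early_stopped=stopped,
                             train_loss_trace=train_trace,
                             validation_loss_trace=val_trace)
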