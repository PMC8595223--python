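"""Screening metrics and result analyses.

The diseased class is the positive class throughout (screening convention):
sensitivity = TP/(TP+FN) is the fraction of diseased patients detected,
specificity = TN/(TN+FP) the fraction of healthy subjects cleared, and
F1 = 2 TP / (2 TP + FP + FN).  Metrics are computed per fold and averaged
across the five resplits.

Analyses: the exhaustive measurement-combination search (63 combinations of
the six bilateral measurements), per-count best/worst summaries, carotid-flow
(Q1) inclusion histograms, summed split-improvement feature importance per
measurement, low-severity aneurysm F1 ratios, and unilateral tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifiers import ClassifierConfig, TrainedClassifier, train
from .features import (
    MEASUREMENTS,
    MeasurementCombination,
    ZScoreScaler,
    all_combinations,
    assemble_features,
)
from .population import MLDataset, fivefold_resplits

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "metrics",
    "evaluate_fold",
    "combination_search",
    "summarise_by_count",
    "q1_partition",
    "measurement_importance",
    "severity_ratio_analysis",
    "unilateral_evaluation",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(y_true, y_pred, positive=1) -> ConfusionCounts:
    t = np.asarray(y_true) == positive
    p = np.asarray(y_pred) == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)), fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)), tn=int(np.sum(~t & ~p)))


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def metrics(counts: ConfusionCounts) -> dict:
    """Sensitivity, specificity, precision, recall and F1 from counts.

    Zero-denominator cases (e.g. no positive predictions) return 0 for the
    affected metric with ``degenerate=True``.
    """
    sens, d1 = _safe_div(counts.tp, counts.tp + counts.fn)
    spec, d2 = _safe_div(counts.tn, counts.tn + counts.fp)
    prec, d3 = _safe_div(counts.tp, counts.tp + counts.fp)
    f1, d4 = _safe_div(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "recall": sens,
        "f1": f1,
        "degenerate": d1 or d2 or d3 or d4,
    }


def evaluate_fold(
    dataset: MLDataset,
    combination: MeasurementCombination,
    config: ClassifierConfig,
    order: int = 5,
) -> tuple[dict, TrainedClassifier]:
    """Featurise, standardise (train-fitted), train and score one fold."""
    Xtr, ytr, _, _ = assemble_features(dataset.train, combination, order)
    Xte, yte, _, _ = assemble_features(dataset.test, combination, order)
    scaler = ZScoreScaler().fit(Xtr)
    tc = train(config, scaler.transform(Xtr), ytr)
    pred = tc.predict(scaler.transform(Xte))
    return metrics(confusion_counts(yte, pred)), tc


def combination_search(
    form: str,
    methods,
    healthy,
    diseased,
    rng: np.random.Generator,
    method_params: dict[str, dict] | None = None,
    measurements: tuple[str, ...] = MEASUREMENTS,
    laterality: str = "bilateral",
    n_folds: int = 5,
    order: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Exhaustive search over all non-empty measurement subsets.

    Returns one record per (method x combination x fold) with F1,
    sensitivity and specificity; failed fits are recorded with NaN metrics
    and an error note rather than dropped.
    """
    method_params = method_params or {}
    folds = fivefold_resplits(healthy, diseased, rng, n_folds=n_folds)
    combos = all_combinations(measurements, laterality)
    rows = []
    for fold_id, ds in enumerate(folds, start=1):
        for combo in combos:
            for method in methods:
                cfg = ClassifierConfig(
                    method, tuple(sorted(method_params.get(method, {}).items())),
                    seed=seed)
                try:
                    m, _ = evaluate_fold(ds, combo, cfg, order)
                    err = ""
                except Exception as exc:  # recorded, never silently dropped
                    m = {k: np.nan for k in
                         ("sensitivity", "specificity", "precision", "recall", "f1")}
                    m["degenerate"] = True
                    err = f"{type(exc).__name__}: {exc}"
                rows.append({
                    "disease": form,
                    "method": method,
                    "combination": combo.label,
                    "n_measurements": len(combo.measurements),
                    "fold": fold_id,
                    "f1": m["f1"],
                    "sensitivity": m["sensitivity"],
                    "specificity": m["specificity"],
                    "precision": m["precision"],
                    "recall": m["recall"],
                    "degenerate": m["degenerate"],
                    "error": err,
                })
    return pd.DataFrame(rows)


def _fold_means(records: pd.DataFrame) -> pd.DataFrame:
    """Mean metrics per (method, combination) across folds."""
    return (records
            .groupby(["disease", "method", "combination", "n_measurements"],
                     as_index=False)[["f1", "sensitivity", "specificity"]]
            .mean())


def summarise_by_count(records: pd.DataFrame) -> pd.DataFrame:
    """Per number-of-measurements average/max/min F1 and the best/worst
    combinations (fold-averaged), per method."""
    means = _fold_means(records)
    rows = []
    for (disease, method, k), g in means.groupby(["disease", "method", "n_measurements"]):
        if g.empty:
            raise ValueError("empty record slice")
        best = g.loc[g["f1"].idxmax()]
        worst = g.loc[g["f1"].idxmin()]
        rows.append({
            "disease": disease, "method": method, "n_measurements": int(k),
            "mean_f1": g["f1"].mean(), "max_f1": best["f1"], "min_f1": worst["f1"],
            "best_combination": best["combination"],
            "best_sensitivity": best["sensitivity"],
            "best_specificity": best["specificity"],
            "worst_combination": worst["combination"],
        })
    return pd.DataFrame(rows)


def q1_partition(
    records: pd.DataFrame,
    bins: np.ndarray | None = None,
) -> dict:
    """Split fold-averaged F1 scores by whether the combination includes the
    carotid flow-rate Q1, with histograms (32 include vs 31 exclude for the
    full six-measurement search)."""
    if bins is None:
        bins = np.arange(0.4, 1.0 + 1e-9, 0.05)
    means = _fold_means(records)
    has_q1 = means["combination"].str.contains(r"\bQ1\b", regex=True)
    inc = means[has_q1]
    exc = means[~has_q1]
    return {
        "include_q1": inc,
        "exclude_q1": exc,
        "include_hist": np.histogram(inc["f1"].dropna(), bins=bins)[0],
        "exclude_hist": np.histogram(exc["f1"].dropna(), bins=bins)[0],
        "bins": bins,
        "include_mean_f1": float(inc["f1"].mean()),
        "exclude_mean_f1": float(exc["f1"].mean()),
    }


def measurement_importance(
    trained: TrainedClassifier,
    combination: MeasurementCombination,
    order: int = 5,
) -> pd.Series:
    """Summed split-improvement importance share (%) per measurement.

    Per-feature impurity-reduction importances of a tree ensemble are summed
    over each measurement's coefficient block (22 per bilateral measurement)
    and normalised to 100%.
    """
    imp = getattr(trained.model, "feature_importances_", None)
    if imp is None:
        raise ValueError(f"{trained.config.method} model exposes no feature importances")
    cols = combination.column_names(order)
    if len(imp) != len(cols):
        raise ValueError("importance vector does not match the feature layout")
    per_meas = {}
    for m in combination.measurements:
        mask = np.array([c.startswith(f"{m}_") for c in cols])
        per_meas[m] = float(imp[mask].sum())
    s = pd.Series(per_meas)
    total = s.sum()
    if total <= 0:
        return s * 0.0
    return s / total * 100.0


def severity_ratio_analysis(
    records_high: pd.DataFrame,
    records_low: pd.DataFrame,
    method: str = "GB",
) -> pd.DataFrame:
    """Per-combination ratio of low-severity to high-severity F1 scores.

    Both tables must cover matching combinations; fold-averaged F1 is used.
    """
    hi = _fold_means(records_high[records_high["method"] == method])
    lo = _fold_means(records_low[records_low["method"] == method])
    merged = hi.merge(lo, on=["method", "combination", "n_measurements"],
                      suffixes=("_high", "_low"))
    missing = set(hi["combination"]) ^ set(lo["combination"])
    if missing:
        raise ValueError(f"unmatched combinations: {sorted(missing)}")
    merged["f1_ratio"] = merged["f1_low"] / merged["f1_high"]
    return merged[["combination", "n_measurements", "f1_high", "f1_low", "f1_ratio"]]


def unilateral_evaluation(
    healthy,
    diseased,
    rng: np.random.Generator,
    form: str = "AAA",
    measurements: tuple[str, ...] = ("Q1", "P3"),
    method: str = "GB",
    method_params: dict | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Right-only / left-only / bilateral comparison for selected sites.

    Unilateral classifiers see 11 coefficients per measurement, bilateral
    ones 22.  Returns mean sensitivity/specificity/F1 across folds.
    """
    folds = fivefold_resplits(healthy, diseased, rng, n_folds=n_folds)
    rows = []
    for meas in measurements:
        for lat in ("right", "left", "bilateral"):
            combo = MeasurementCombination((meas,), lat)
            cfg = ClassifierConfig(method, tuple(sorted((method_params or {}).items())),
                                   seed=seed)
            fold_ms = []
            for ds in folds:
                m, _ = evaluate_fold(ds, combo, cfg)
                fold_ms.append(m)
            rows.append({
                "disease": form,
                "measurement": meas,
                "side": {"right": "right", "left": "left", "bilateral": "both"}[lat],
                "feature_width": combo.width,
                "sensitivity": float(np.mean([m["sensitivity"] for m in fold_ms])),
                "specificity": float(np.mean([m["specificity"] for m in fold_ms])),
                "f1": float(np.mean([m["f1"] for m in fold_ms])),
            })
    return pd.DataFrame(rows)
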