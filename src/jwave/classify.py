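"""Random-forest J-wave detector and its statistical evaluation.

Training wraps scikit-learn's bagged decision-tree ensemble (150 trees by
default, sqrt(d) features per split).  Evaluation computes the clinical
beat-level metrics — sensitivity, specificity, accuracy, the Matthews
correlation coefficient — directly from the confusion counts, the AUC from
the rank (Mann-Whitney) statistic of the continuous scores, and Welch's
unequal-variance t-test for per-feature class separation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts", "MetricsReport", "TTestResult",
    "train_rf", "predict_scores", "evaluate", "welch_ttest",
    "metrics_from_confusion", "rank_auc", "roc_points",
    "feature_report", "save_model", "load_model",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Beat-level confusion counts (positive = J-wave-positive)."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass
class MetricsReport:
    """Se/Sp/Acc in percent, MCC in [-1, 1] (None if undefined), AUC."""

    se: float
    sp: float
    acc: float
    mcc: float | None
    auc: float | None
    confusion: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "se_pct": self.se, "sp_pct": self.sp, "acc_pct": self.acc,
            "mcc": self.mcc, "auc": self.auc,
            "confusion": {"tp": self.confusion.tp, "fn": self.confusion.fn,
                          "tn": self.confusion.tn, "fp": self.confusion.fp},
        }


@dataclass(frozen=True)
class TTestResult:
    t_value: float
    p_value: float
    df: float


def metrics_from_confusion(counts: ConfusionCounts,
                           auc: float | None = None) -> MetricsReport:
    """Sensitivity, specificity, accuracy and MCC from raw counts.

    Se = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total, all in percent;
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP)).  Any empty
    marginal makes the MCC undefined (None), never silently zero.
    """
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("empty confusion matrix")
    se = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    sp = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    acc = 100.0 * (tp + tn) / total
    denom = (tp + fp) * (tn + fn) * (tp + fn) * (tn + fp)
    if denom == 0:
        warnings.warn("MCC undefined: an empty confusion marginal")
        mcc = None
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(float(denom))
    return MetricsReport(se=se, sp=sp, acc=acc, mcc=mcc, auc=auc,
                         confusion=counts)


def train_rf(x: np.ndarray, y: np.ndarray, n_trees: int = 150,
             seed: int = 0) -> RandomForestClassifier:
    """Fit the random-forest detector (bootstrap bagging, sqrt(d) splits).

    ``y`` is a 0/1 (or boolean) beat-label vector with 1 = J-wave-positive.
    NaN feature entries (e.g. undefined sample entropies) are imputed with
    the training-column median before fitting; the imputation vector is
    stored on the model so prediction applies the same fill.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    fill = np.nan_to_num(np.nanmedian(x, axis=0))
    x = _impute(x, fill)
    model = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", bootstrap=True,
        random_state=int(seed), n_jobs=1)
    model.fit(x, y)
    model.nan_fill_ = fill
    return model


def _impute(x: np.ndarray, fill: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).copy()
    bad = ~np.isfinite(x)
    if bad.any():
        x[bad] = np.broadcast_to(fill, x.shape)[bad]
    return x


def predict_scores(model: RandomForestClassifier, x: np.ndarray) -> np.ndarray:
    """Continuous positive-class score: fraction of trees voting positive."""
    x = _impute(x, getattr(model, "nan_fill_", np.zeros(x.shape[1])))
    return model.predict_proba(x)[:, list(model.classes_).index(1)]


def rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formulation (ties counted half)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(scores: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Ordered (FPR, TPR, threshold) points of the ROC curve."""
    fpr, tpr, thr = _sk_roc_curve(np.asarray(y).astype(int), scores,
                                  drop_intermediate=False)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def evaluate(model: RandomForestClassifier, x: np.ndarray, y: np.ndarray,
             record_ids: np.ndarray | None = None,
             train_record_ids: set[str] | None = None) -> MetricsReport:
    """Beat-level metrics of a fitted model on a held-out split.

    If both record-id arguments are given, any overlap between test and
    training records is an error — the split must be by record.
    """
    if record_ids is not None and train_record_ids is not None:
        overlap = set(map(str, record_ids)) & set(map(str, train_record_ids))
        if overlap:
            raise ValueError(
                f"record-level split violated; shared records: {sorted(overlap)}")
    y = np.asarray(y).astype(int)
    scores = predict_scores(model, x)
    pred = (scores >= 0.5).astype(int)
    counts = ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()))
    return metrics_from_confusion(counts, auc=rank_auc(scores, y))


def welch_ttest(group_a: np.ndarray, group_b: np.ndarray) -> TTestResult:
    """Welch's unequal-variance two-tailed t-test.

    t = (mean_a - mean_b) / sqrt(va/na + vb/nb) with Welch-Satterthwaite
    degrees of freedom; p is two-tailed from the t distribution.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    # keep p in (0, 1]: the t survival function underflows for huge |t|
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return TTestResult(t_value=float(t), p_value=p, df=float(df))


def feature_report(model: RandomForestClassifier, x: np.ndarray,
                   y: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Importance ranking plus per-feature class statistics.

    One row per feature: RF impurity importance (sums to 1 over all
    features), Welch t/p between the classes on the given (training)
    split, a Bonferroni-adjusted p column, and per-class mean/SD.  Sorted
    by importance, descending.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int)
    imp = model.feature_importances_
    rows = []
    n_tests = len(names)
    for j, name in enumerate(names):
        col = x[:, j]
        pos = col[(y == 1) & np.isfinite(col)]
        neg = col[(y == 0) & np.isfinite(col)]
        try:
            tt = welch_ttest(pos, neg)
            t_val, p_val = tt.t_value, tt.p_value
        except ValueError:
            t_val, p_val = float("nan"), float("nan")
        rows.append({
            "feature": name, "importance": float(imp[j]),
            "t_value": t_val, "p_value": p_val,
            "p_bonferroni": min(1.0, p_val * n_tests) if np.isfinite(p_val)
            else float("nan"),
            "mean_pos": float(pos.mean()) if pos.size else float("nan"),
            "sd_pos": float(pos.std(ddof=1)) if pos.size > 1 else float("nan"),
            "mean_neg": float(neg.mean()) if neg.size else float("nan"),
            "sd_neg": float(neg.std(ddof=1)) if neg.size > 1 else float("nan"),
        })
    return (pd.DataFrame(rows)
            .sort_values("importance", ascending=False)
            .reset_index(drop=True))


def save_model(model: RandomForestClassifier, path: str | Path,
               meta: dict | None = None) -> None:
    """Persist model + JSON sidecar (parameters, seed, feature names...)."""
    path = Path(path)
    joblib.dump(model, path)
    sidecar = {
        "n_estimators": model.n_estimators,
        "random_state": model.random_state,
        "n_features": int(model.n_features_in_),
        **(meta or {}),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def load_model(path: str | Path) -> RandomForestClassifier:
    return joblib.load(path)
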