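"""Classifier evaluation: confusion-matrix metrics, ROC/AUC and
permutation wavelength importance.

The degenerated (OA or early-OA) class is the positive class throughout.
Two "accuracy" variants are reported side by side: the standard
proportion of correct predictions, and the ratio TP/(TP+FP) -- the
conventional name for which is precision -- because some of the
chemometric cartilage literature prints the latter under the accuracy
label.  Both are computed and explicitly labelled so results can be
compared either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import roc_curve

POSITIVE = 1


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(y_true, y_pred, positive=POSITIVE) -> ConfusionMatrix:
    """Counts with the OA-type class as positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted labels must have equal length")
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(cm: ConfusionMatrix) -> dict:
    """Metric dictionary; zero-denominator metrics are ``None``, never NaN.

    ``accuracy_printed_eq3`` is TP/(TP+FP) (precision); ``accuracy_standard``
    is (TP+TN)/total.
    """
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    bal = None if sens is None or spec is None else 0.5 * (sens + spec)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy_standard": _ratio(cm.tp + cm.tn, cm.total),
        "accuracy_printed_eq3": _ratio(cm.tp, cm.tp + cm.fp),
        "balanced_accuracy": bal,
    }


def roc_auc(y_true, decision_values, positive=POSITIVE
            ) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) by threshold sweep and trapezoidal AUC.

    Tied decision values cross their threshold simultaneously, which is
    what makes the trapezoidal AUC equal the pairwise (Mann-Whitney)
    statistic with half credit for ties.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(decision_values, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("decision values must be finite")
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC undefined for single-class truth")
    fpr, tpr, _ = roc_curve(y_true, scores, pos_label=positive)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def permutation_importance(model, X_test: np.ndarray, y_test: np.ndarray,
                           wavelengths, n_permutations: int = 20,
                           seed: int = 0) -> pd.DataFrame:
    """Mean % accuracy drop when one wavelength column is shuffled.

    For each column the values are permuted across the test measurements
    ``n_permutations`` times; importance is
    ``mean(baseline - permuted) / baseline * 100``.  Permutation is used
    rather than literal column removal, which would change the feature
    dimensionality of the fitted kernel machine.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    baseline = float(np.mean(model.predict(X_test) == y_test))
    if baseline == 0:
        raise ValueError("baseline accuracy is zero; importance undefined")
    rows = []
    for j, wl in enumerate(wavelengths):
        drops = np.empty(n_permutations)
        for r in range(n_permutations):
            Xp = X_test.copy()
            Xp[:, j] = Xp[rng.permutation(X_test.shape[0]), j]
            acc = float(np.mean(model.predict(Xp) == y_test))
            drops[r] = (baseline - acc) / baseline * 100.0
        rows.append({"wavelength_nm": float(wl),
                     "mean_pct_drop": float(drops.mean()),
                     "sd_pct_drop": float(drops.std(ddof=1)) if n_permutations > 1
                     else 0.0})
    df = pd.DataFrame(rows).sort_values("mean_pct_drop", ascending=False,
                                        kind="stable")
    return df.reset_index(drop=True)


def evaluation_report(y_true, y_pred, decision_values=None) -> dict:
    """Convenience bundle: confusion counts, metrics and (optionally) AUC."""
    cm = confusion(y_true, y_pred)
    rep = {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn, **metrics(cm)}
    if decision_values is not None and len(np.unique(np.asarray(y_true))) == 2:
        _, auc = roc_auc(y_true, decision_values)
        rep["auc"] = auc
    else:
        rep["auc"] = None
    return rep
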