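"""Forward sequential wavelength selection.

Greedy forward sequential feature selection (SFS): starting from the
empty set, each round adds the single remaining wavelength whose
inclusion maximizes the mean donor-grouped cross-validated accuracy of a
scoring classifier, stopping at ``k`` wavelengths (default 30).  Exact
accuracy ties -- frequent with small grouped folds, and universal once
the accuracy path plateaus -- are resolved by a deterministic hierarchy:
the candidate's own single-wavelength CV accuracy (univariate
relevance), then the mean held-out decision margin, then the lower
wavelength.  Without the hierarchy a plateaued selection would fill up
with whatever uninformative wavelength happens to sort first.

The scoring classifier defaults to a standardized RBF-kernel SVM with
inverse-frequency class weights -- the same family as the final model
but with a single hyperparameter point, since a nested grid search
inside every SFS round would be disproportionate.  Donor-grouped folds
prevent donor identity from leaking into the selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import clone
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


def default_sfs_estimator() -> object:
    return make_pipeline(StandardScaler(),
                         SVC(kernel="rbf", C=1.0, gamma="scale",
                             class_weight="balanced"))


def decimate_indices(wavelengths: np.ndarray, min_spacing_nm: float) -> np.ndarray:
    """Indices of a subgrid with at least ``min_spacing_nm`` between
    consecutive wavelengths (greedy from the low end).

    Leaves coarsely sampled regions untouched; mainly thins the dense
    visible-detector part of the grid for runtime control.
    """
    keep = [0]
    for i in range(1, len(wavelengths)):
        if wavelengths[i] - wavelengths[keep[-1]] >= min_spacing_nm:
            keep.append(i)
    return np.asarray(keep)


@dataclass
class SelectionResult:
    """Outcome of one SFS run."""

    selected_wavelengths: list[float]       # in order of inclusion
    selected_indices: list[int]             # columns of the input matrix
    cv_accuracy_path: list[float]           # score after each inclusion
    score_tables: list[dict] = field(repr=False, default_factory=list)
    scoring_config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "selected_wavelengths": self.selected_wavelengths,
            "selected_indices": self.selected_indices,
            "cv_accuracy_path": self.cv_accuracy_path,
            "score_tables": [{f"{k:.4f}": v for k, v in t.items()}
                             for t in self.score_tables],
            "scoring_config": self.scoring_config,
        }, indent=1))

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(
            d["selected_wavelengths"], d["selected_indices"],
            d["cv_accuracy_path"],
            [{float(k): v for k, v in t.items()} for t in d["score_tables"]],
            d["scoring_config"])


def _grouped_folds(y: np.ndarray, groups: np.ndarray, n_splits: int
                   ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Donor-grouped, class-stratified folds with two classes in every
    training part.

    Small cohorts can make some grouped fold degenerate (a training part
    with one class); such folds are dropped, and if fewer than two
    usable folds remain the split count is reduced before giving up.
    """
    n_groups = len(np.unique(groups))
    for ns in range(min(n_splits, n_groups), 1, -1):
        folds = [
            (tr, te) for tr, te in StratifiedGroupKFold(n_splits=ns).split(
                np.zeros((len(y), 1)), y, groups)
            if len(np.unique(y[tr])) == 2 and len(te)
        ]
        if len(folds) >= 2:
            return folds
    raise ValueError("could not build 2 grouped CV folds with both classes "
                     "in every training part")


class _Scorer:
    """Scores candidate column sets by (mean CV accuracy, mean margin).

    The margin -- the mean signed decision value of held-out samples,
    positive when on the correct side -- is a strictly finer separation
    measure than accuracy and serves as a tie-break criterion: small
    grouped folds produce many exact accuracy ties, under which accuracy
    alone cannot distinguish an informative wavelength from a noise one.
    """

    def __init__(self, estimator, X, y, folds):
        self.estimator = estimator
        self.X, self.y, self.folds = X, y, folds

    def score(self, cols) -> tuple[float, float]:
        X, y = self.X, self.y
        accs, margins = [], []
        for tr, te in self.folds:
            est = clone(self.estimator)
            est.fit(X[np.ix_(tr, cols)], y[tr])
            Xte = X[np.ix_(te, cols)]
            accs.append(accuracy_score(y[te], est.predict(Xte)))
            if hasattr(est, "decision_function"):
                dec = np.asarray(est.decision_function(Xte), dtype=float)
                classes = est.classes_ if hasattr(est, "classes_") else \
                    est[-1].classes_
                sign = np.where(y[te] == classes[1], 1.0, -1.0)
                margins.append(float(np.mean(sign * dec)))
            else:
                margins.append(0.0)
        return float(np.mean(accs)), float(np.mean(margins))


class _FastRbfScorer:
    """Default scorer with per-fold standardization precomputed once.

    Equivalent to a ``StandardScaler`` + RBF ``SVC`` pipeline: scaling
    is per column, so standardizing the full matrix on each fold's
    training rows and then slicing candidate columns gives the same fit
    as re-scaling the slice, at a fraction of the per-candidate cost.
    """

    def __init__(self, X, y, folds, *, C=1.0):
        self.prepped = []
        self.C = C
        for tr, te in folds:
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (X[tr] - mu) / sd
            Xte = (X[te] - mu) / sd
            self.prepped.append((Xtr, y[tr], Xte, y[te]))

    def score(self, cols) -> tuple[float, float]:
        accs, margins = [], []
        for Xtr, ytr, Xte, yte in self.prepped:
            svc = SVC(kernel="rbf", C=self.C, gamma="scale",
                      class_weight="balanced")
            svc.fit(Xtr[:, cols], ytr)
            dec = svc.decision_function(Xte[:, cols])
            pred = svc.classes_[(dec > 0).astype(int)]
            accs.append(float(np.mean(pred == yte)))
            sign = np.where(yte == svc.classes_[1], 1.0, -1.0)
            margins.append(float(np.mean(sign * dec)))
        return float(np.mean(accs)), float(np.mean(margins))


def sequential_forward_select(X: np.ndarray, y: np.ndarray,
                              wavelengths: np.ndarray,
                              groups: np.ndarray, k: int = 30,
                              *, estimator=None, n_splits: int = 5,
                              seed: int = 0,
                              keep_score_tables: bool = True
                              ) -> SelectionResult:
    """Greedy forward selection of ``k`` wavelengths.

    Parameters
    ----------
    X, y : spectra matrix (rows = measurements) and binary labels.
    wavelengths : column wavelengths in nm; also the tie-break key.
    groups : per-row donor identifiers for grouped CV.
    k : number of wavelengths to select.
    estimator : scoring classifier (cloned per fit); standardized RBF
        SVM by default.
    seed : recorded in the scoring config; folds and the default
        estimator are already deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[1]:
        raise ValueError("k exceeds the number of candidate wavelengths")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes for selection")
    folds = _grouped_folds(y, groups, n_splits)
    if estimator is None:
        scorer = _FastRbfScorer(X, y, folds)
        estimator_repr = "StandardScaler + SVC(rbf, C=1, gamma=scale, balanced)"
    else:
        scorer = _Scorer(estimator, X, y, folds)
        estimator_repr = repr(estimator)

    # candidate order = ascending wavelength, so with strict ">" the final
    # fallback of the ranking is the lower wavelength.
    order = np.argsort(wavelengths, kind="stable")
    remaining = list(order)
    # univariate relevance, precomputed once: the first tie-break between
    # candidate sets with equal joint CV accuracy.
    single_acc = {j: scorer.score([j])[0] for j in order}
    selected: list[int] = []
    path: list[float] = []
    tables: list[dict] = []
    for _ in range(k):
        best_key, best_j = (-np.inf, -np.inf, -np.inf), None
        table = {}
        for j in remaining:
            acc, margin = scorer.score(selected + [j])
            key = (acc, single_acc[j], margin)
            table[float(wavelengths[j])] = acc
            if key > best_key:
                best_key, best_j = key, j
        selected.append(best_j)
        remaining.remove(best_j)
        path.append(best_key[0])
        if keep_score_tables:
            tables.append(table)

    return SelectionResult(
        selected_wavelengths=[float(wavelengths[j]) for j in selected],
        selected_indices=[int(j) for j in selected],
        cv_accuracy_path=path,
        score_tables=tables,
        scoring_config={"n_splits": len(folds), "seed": seed,
                        "estimator": estimator_repr},
    )
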