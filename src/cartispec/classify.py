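"""Site-specific SVM classification of cartilage spectra.

Two binary tasks are supported: *classifier1* separates normal cartilage
(OARSI 0-1) from any osteoarthritic cartilage (OARSI 2-5);
*classifier2* separates normal (0-1) from early OA (2-3) and excludes
advanced OA (4-5) samples entirely.  The degenerated class is coded 1.

Training follows a donor-grouped design: donors are assigned whole to a
~70 % train / 30 % test split per site, hyperparameters are chosen by
donor-grouped 5-fold cross-validated grid search over four SVM kernels
with inverse-frequency class weighting, and the whole procedure (split,
selection, grid search, test evaluation) is repeated three times with
fresh splits.  No preprocessing statistic, selection or hyperparameter
decision ever sees test-donor data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, balanced_accuracy_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import evaluate
from .select import SelectionResult, decimate_indices, sequential_forward_select

TASKS = ("classifier1", "classifier2")
EXCLUDED = -1


@dataclass
class ClassifierSpec:
    """Task and hyperparameter grid of one SVM experiment."""

    task: str = "classifier2"
    kernels: tuple[str, ...] = ("rbf", "linear", "poly", "sigmoid")
    C_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_factors: tuple[float, ...] = (0.1, 1.0, 10.0)
    poly_degrees: tuple[int, ...] = (2, 3)
    class_weighting: str = "inverse_frequency"   # or "none"
    scoring: str = "auto"   # accuracy | balanced_accuracy | auto

    def validate(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.class_weighting not in ("inverse_frequency", "none"):
            raise ValueError("class_weighting must be inverse_frequency or none")
        if self.scoring not in ("auto", "accuracy", "balanced_accuracy"):
            raise ValueError("unknown scoring rule")

    def param_grid(self) -> list[dict]:
        """Deterministic enumeration of kernel/hyperparameter points."""
        grid = []
        for kernel in self.kernels:
            if kernel == "rbf":
                combos = itertools.product(self.C_grid, self.gamma_factors)
                grid += [{"kernel": "rbf", "C": c, "gamma_factor": g}
                         for c, g in combos]
            elif kernel == "linear":
                grid += [{"kernel": "linear", "C": c} for c in self.C_grid]
            elif kernel == "poly":
                combos = itertools.product(self.C_grid, self.poly_degrees)
                grid += [{"kernel": "poly", "C": c, "degree": d}
                         for c, d in combos]
            elif kernel == "sigmoid":
                grid += [{"kernel": "sigmoid", "C": c} for c in self.C_grid]
            else:
                raise ValueError(f"unknown kernel {kernel!r}")
        return grid


def make_groups(grades, task: str) -> np.ndarray:
    """Binary task labels from OARSI grades.

    Returns 0 for normal (OARSI 0-1), 1 for the degenerated class and
    ``EXCLUDED`` (-1) for grades outside the task (OARSI 4-5 under
    classifier2).
    """
    grades = np.asarray(grades)
    if np.any((grades < 0) | (grades > 5)):
        raise ValueError("OARSI grades must be in 0..5")
    y = np.where(grades <= 1, 0, 1)
    if task == "classifier2":
        y = np.where(grades >= 4, EXCLUDED, y)
    elif task != "classifier1":
        raise ValueError(f"task must be one of {TASKS}")
    return y


@dataclass
class SplitPlan:
    """Whole-donor train/test assignment for one site and repeat."""

    site: str
    train_donors: tuple[str, ...]
    test_donors: tuple[str, ...]
    fold_of_donor: dict[str, int]
    repeat_index: int = 0
    realized_fraction: float = float("nan")

    def validate(self) -> None:
        if set(self.train_donors) & set(self.test_donors):
            raise ValueError("train and test donors overlap")


def _subset_ok(donors, in_train, labels_by_donor) -> bool:
    tr_labels, te_labels = set(), set()
    for d in donors:
        (tr_labels if d in in_train else te_labels).update(labels_by_donor[d])
    return len(tr_labels) == 2 and len(te_labels) == 2


def grouped_split(meta: pd.DataFrame, y: np.ndarray, *, site: str = "",
                  fraction: float = 0.7, seed: int = 0, slack: float = 0.03,
                  n_folds: int = 5, repeat_index: int = 0,
                  max_enumeration: int = 12,
                  n_random_subsets: int = 2000) -> SplitPlan:
    """Assign donors whole to train/test, targeting ``fraction`` of spectra.

    All subsets (exhaustive up to ``max_enumeration`` donors, seeded
    random search beyond) are scored by the deviation of the realized
    train-spectrum fraction from the target; among feasible subsets --
    both classes present on both sides -- within ``slack`` of the best
    deviation, one is drawn at random, which is what makes independent
    repeats produce distinct, near-optimal plans.
    """
    donors = sorted(meta["donor_id"].unique())
    if len(donors) < 2:
        raise ValueError("need at least 2 donors to split")
    rng = np.random.default_rng(np.random.SeedSequence((seed, repeat_index)))
    counts = meta.groupby("donor_id").size()
    labels_by_donor = {d: set(y[(meta["donor_id"] == d).to_numpy()])
                       for d in donors}
    total = float(counts.sum())

    if len(donors) <= max_enumeration:
        subsets = []
        for r in range(1, len(donors)):
            subsets += [frozenset(c) for c in itertools.combinations(donors, r)]
    else:
        subsets = []
        for _ in range(n_random_subsets):
            r = int(rng.integers(1, len(donors)))
            subsets.append(frozenset(rng.choice(donors, size=r, replace=False)))
        subsets = sorted(set(subsets), key=sorted)

    feasible = []
    for sub in subsets:
        if not _subset_ok(donors, sub, labels_by_donor):
            continue
        frac = sum(counts[d] for d in sub) / total
        feasible.append((abs(frac - fraction), frac, sub))
    if not feasible:
        raise ValueError("no donor subset leaves both classes in train and test")
    best_dev = min(f[0] for f in feasible)
    candidates = sorted([f for f in feasible if f[0] <= best_dev + slack],
                        key=lambda f: (f[0], sorted(f[2])))
    dev, frac, train = candidates[int(rng.integers(len(candidates)))]

    train_donors = tuple(sorted(train))
    test_donors = tuple(sorted(set(donors) - train))
    shuffled = list(train_donors)
    rng.shuffle(shuffled)
    nf = min(n_folds, len(shuffled))
    fold_of_donor = {d: i % nf for i, d in enumerate(shuffled)}
    plan = SplitPlan(site=site, train_donors=train_donors,
                     test_donors=test_donors, fold_of_donor=fold_of_donor,
                     repeat_index=repeat_index, realized_fraction=float(frac))
    plan.validate()
    return plan


@dataclass
class TrainedClassifier:
    """A fitted SVM pipeline plus the bookkeeping to reproduce it."""

    pipeline: Pipeline
    best_params: dict
    best_cv_score: float
    cv_table: pd.DataFrame = field(repr=False)
    scoring_used: str = "accuracy"
    wavelengths: np.ndarray | None = None

    def predict(self, X):
        return self.pipeline.predict(X)

    def decision_function(self, X):
        return self.pipeline.decision_function(X)


def _build_pipeline(params: dict, class_weight, X: np.ndarray) -> Pipeline:
    kw = {k: v for k, v in params.items() if k not in ("kernel", "gamma_factor")}
    gamma = "scale"
    if "gamma_factor" in params:
        var = X.var()
        gamma = params["gamma_factor"] / (X.shape[1] * var) if var > 0 else "scale"
    svc = SVC(kernel=params["kernel"], gamma=gamma, class_weight=class_weight,
              **kw)
    return Pipeline([("scale", StandardScaler()), ("svm", svc)])


def _fold_indices(meta: pd.DataFrame, plan: SplitPlan
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
    donor = meta["donor_id"].to_numpy()
    folds = sorted(set(plan.fold_of_donor.values()))
    out = []
    for f in folds:
        te_donors = {d for d, fi in plan.fold_of_donor.items() if fi == f}
        te = np.flatnonzero(np.isin(donor, sorted(te_donors)))
        tr = np.flatnonzero(np.isin(donor, sorted(set(plan.train_donors) - te_donors)))
        out.append((tr, te))
    return out


def _resolve_scoring(spec: ClassifierSpec, y: np.ndarray) -> str:
    if spec.scoring != "auto":
        return spec.scoring
    _, counts = np.unique(y, return_counts=True)
    # balanced accuracy once the minority class drops below 40 %
    return "balanced_accuracy" if counts.min() / counts.sum() < 0.40 else "accuracy"


def train_gridsearch_cv(X: np.ndarray, y: np.ndarray, meta: pd.DataFrame,
                        plan: SplitPlan, spec: ClassifierSpec,
                        *, max_fold_retries: int = 20,
                        seed: int = 0) -> TrainedClassifier:
    """Donor-grouped cross-validated grid search over the kernel grid.

    ``X``/``y``/``meta`` are the *training* rows only.  Features are
    standardized inside each fold's pipeline on that fold's training
    rows, so no test statistic leaks into the fit.  Degenerate folds
    (a fold whose training part is single-class) trigger a reshuffled
    fold assignment before giving up.
    """
    spec.validate()
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    class_weight = "balanced" if spec.class_weighting == "inverse_frequency" else None
    scoring = _resolve_scoring(spec, y)
    scorer = balanced_accuracy_score if scoring == "balanced_accuracy" \
        else accuracy_score

    plan_try = plan
    folds = None
    last_usable: list = []
    for attempt in range(max_fold_retries):
        cand = _fold_indices(meta, plan_try)
        usable = [(tr, te) for tr, te in cand
                  if len(np.unique(y[tr])) == 2 and len(te)]
        if len(usable) == len(cand):
            folds = cand
            break
        if len(usable) > len(last_usable):
            last_usable = usable
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        shuffled = list(plan.train_donors)
        rng.shuffle(shuffled)
        nf = len(set(plan.fold_of_donor.values()))
        plan_try = SplitPlan(plan.site, plan.train_donors, plan.test_donors,
                             {d: i % nf for i, d in enumerate(shuffled)},
                             plan.repeat_index, plan.realized_fraction)
    if folds is None:
        # e.g. a single donor carries one whole class: holding it out is
        # always degenerate, so score on the usable folds only.
        if len(last_usable) >= 2:
            folds = last_usable
        else:
            raise ValueError("could not build >= 2 folds with both classes "
                             "in every training part")

    rows = []
    best_score, best_params = -np.inf, None
    for params in spec.param_grid():
        scores = []
        for tr, te in folds:
            pipe = _build_pipeline(params, class_weight, X[tr])
            pipe.fit(X[tr], y[tr])
            with warnings.catch_warnings():
                # single-class fold test parts are legitimate; sklearn warns
                warnings.simplefilter("ignore", UserWarning)
                scores.append(scorer(y[te], pipe.predict(X[te])))
        mean_score = float(np.mean(scores))
        rows.append({**params, "mean_cv_score": mean_score})
        if mean_score > best_score:
            best_score, best_params = mean_score, params

    final = _build_pipeline(best_params, class_weight, X)
    final.fit(X, y)
    return TrainedClassifier(pipeline=final, best_params=best_params,
                             best_cv_score=best_score,
                             cv_table=pd.DataFrame(rows),
                             scoring_used=scoring)


def assign_prediction_groups(pred_df: pd.DataFrame) -> pd.DataFrame:
    """Per-sample class by majority vote over replicate spectra.

    Ties go to the degenerated (positive) class.  ``pred_df`` needs
    columns ``sample_id`` and ``y_pred``.
    """
    if pred_df.empty:
        raise ValueError("no predictions to aggregate")
    agg = pred_df.groupby("sample_id")["y_pred"].agg(["mean", "size"])
    if (agg["size"] == 0).any():
        raise ValueError("sample with zero spectra")
    out = pd.DataFrame({"sample_id": agg.index,
                        "predicted_group": (agg["mean"] >= 0.5).astype(int).values})
    return out.reset_index(drop=True)


@dataclass
class RepeatResult:
    """One repeat of a site experiment."""

    repeat_index: int
    plan: SplitPlan
    selection: SelectionResult | None
    trained: TrainedClassifier
    trained_full: TrainedClassifier | None
    test_predictions: pd.DataFrame
    report: dict
    report_full: dict | None


def run_site_experiment(X: np.ndarray, wavelengths: np.ndarray,
                        meta: pd.DataFrame, spec: ClassifierSpec,
                        *, k_wavelengths: int = 30, n_repeats: int = 3,
                        seed: int = 0, min_spacing_nm: float | None = None,
                        sfs_splits: int = 5, sfs_estimator=None,
                        include_full_spectrum: bool = True,
                        reuse_selection: bool = False,
                        fraction: float = 0.7) -> list[RepeatResult]:
    """Full site protocol: split -> SFS -> grid search -> test, repeated.

    Selection and model fitting use training donors only; the
    full-wavelength variant quantifies the gain from selection.  With
    ``reuse_selection`` the first repeat's wavelengths are reused.
    """
    spec.validate()
    y_all = make_groups(meta["oarsi_grade"].to_numpy(), spec.task)
    keep = y_all != EXCLUDED
    X = np.asarray(X, dtype=float)[keep]
    y = y_all[keep]
    meta = meta.loc[keep].reset_index(drop=True)
    site = meta["site"].iloc[0] if "site" in meta and len(meta) else ""

    if min_spacing_nm:
        cols = decimate_indices(wavelengths, min_spacing_nm)
        X = X[:, cols]
        wavelengths = np.asarray(wavelengths)[cols]

    results: list[RepeatResult] = []
    selection: SelectionResult | None = None
    for r in range(n_repeats):
        plan = grouped_split(meta, y, site=site, fraction=fraction,
                             seed=seed, repeat_index=r)
        tr_mask = meta["donor_id"].isin(plan.train_donors).to_numpy()
        te_mask = ~tr_mask
        X_tr, y_tr, meta_tr = X[tr_mask], y[tr_mask], meta.loc[tr_mask].reset_index(drop=True)
        X_te, y_te, meta_te = X[te_mask], y[te_mask], meta.loc[te_mask].reset_index(drop=True)

        if selection is None or not reuse_selection:
            selection = sequential_forward_select(
                X_tr, y_tr, wavelengths, meta_tr["donor_id"].to_numpy(),
                k=min(k_wavelengths, X.shape[1]), n_splits=sfs_splits,
                estimator=sfs_estimator, seed=seed + r)
        cols = selection.selected_indices

        trained = train_gridsearch_cv(X_tr[:, cols], y_tr, meta_tr, plan, spec,
                                      seed=seed + r)
        trained.wavelengths = np.array(selection.selected_wavelengths)
        y_pred = trained.predict(X_te[:, cols])
        dec = trained.decision_function(X_te[:, cols])
        report = evaluate.evaluation_report(y_te, y_pred, dec)

        trained_full = report_full = None
        if include_full_spectrum:
            trained_full = train_gridsearch_cv(X_tr, y_tr, meta_tr, plan, spec,
                                               seed=seed + r)
            trained_full.wavelengths = np.asarray(wavelengths)
            report_full = evaluate.evaluation_report(
                y_te, trained_full.predict(X_te),
                trained_full.decision_function(X_te))

        preds = meta_te[["donor_id", "site", "sample_id", "replicate"]].copy()
        preds["y_true"] = y_te
        preds["y_pred"] = y_pred
        preds["decision_value"] = dec
        preds["repeat"] = r
        results.append(RepeatResult(r, plan, selection, trained, trained_full,
                                    preds, report, report_full))
    return results
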