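"""Grouping, donor-wise splitting, grid-search training, aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cartispec.classify import (EXCLUDED, ClassifierSpec, assign_prediction_groups,
                                grouped_split, make_groups, run_site_experiment,
                                train_gridsearch_cv)


class TestMakeGroups:
    def test_classifier1_pooling(self):
        np.testing.assert_array_equal(
            make_groups([0, 1, 2, 3, 4, 5], "classifier1"),
            [0, 0, 1, 1, 1, 1])

    def test_classifier2_excludes_advanced(self):
        np.testing.assert_array_equal(
            make_groups([0, 1, 2, 3, 4, 5], "classifier2"),
            [0, 0, 1, 1, EXCLUDED, EXCLUDED])

    def test_out_of_range_grade(self):
        with pytest.raises(ValueError):
            make_groups([0, 6], "classifier1")


def _meta(donor_sizes, labels_by_donor):
    rows = []
    for d, n in donor_sizes.items():
        for i in range(n):
            rows.append({"donor_id": d, "sample_id": f"{d}-S{i}"})
    meta = pd.DataFrame(rows)
    y = np.array([labels_by_donor[d][i % len(labels_by_donor[d])]
                  for d, n in donor_sizes.items() for i in range(n)])
    return meta, y


class TestGroupedSplit:
    def test_equal_donors_seventy_percent(self):
        sizes = {f"D{i}": 6 for i in range(10)}
        labels = {d: [0, 1] for d in sizes}
        meta, y = _meta(sizes, labels)
        plan = grouped_split(meta, y, seed=0)
        assert len(plan.train_donors) == 7
        assert not set(plan.train_donors) & set(plan.test_donors)
        assert plan.realized_fraction == pytest.approx(0.7)

    def test_unequal_donors_near_optimal_against_bruteforce(self):
        rng = np.random.default_rng(5)
        sizes = {f"D{i}": int(rng.integers(2, 12)) for i in range(9)}
        labels = {d: [0, 1] for d in sizes}
        meta, y = _meta(sizes, labels)
        plan = grouped_split(meta, y, seed=3, slack=0.03)
        total = sum(sizes.values())
        best = min(
            abs(sum(sizes[d] for d in sub) / total - 0.7)
            for r in range(1, 9)
            for sub in itertools.combinations(sizes, r))
        assert abs(plan.realized_fraction - 0.7) <= best + 0.03

    def test_repeats_are_distinct_and_disjoint(self):
        sizes = {f"D{i}": 6 for i in range(10)}
        labels = {d: [0, 1] for d in sizes}
        meta, y = _meta(sizes, labels)
        plans = [grouped_split(meta, y, seed=0, repeat_index=r)
                 for r in range(3)]
        assert len({p.train_donors for p in plans}) >= 2
        for p in plans:
            assert not set(p.train_donors) & set(p.test_donors)

    def test_class_presence_required(self):
        # one donor holds all positives; it cannot be on both sides
        sizes = {"D0": 4, "D1": 4}
        labels = {"D0": [0], "D1": [1]}
        meta, y = _meta(sizes, labels)
        with pytest.raises(ValueError):
            grouped_split(meta, y, seed=0)


def _separable(n_donors=8, n_per=8, seed=0):
    rng = np.random.default_rng(seed)
    n = n_donors * n_per
    y = np.tile([0, 1], n // 2)
    X = rng.normal(size=(n, 4))
    X[:, 0] += 8.0 * y
    meta = pd.DataFrame({
        "donor_id": np.repeat([f"D{i}" for i in range(n_donors)], n_per),
        "sample_id": [f"S{i}" for i in range(n)]})
    return X, y, meta


class TestGridSearch:
    def test_separable_data_perfect(self):
        X, y, meta = _separable()
        plan = grouped_split(meta, y, seed=1)
        tr = meta["donor_id"].isin(plan.train_donors).to_numpy()
        spec = ClassifierSpec(task="classifier1")
        trained = train_gridsearch_cv(X[tr], y[tr],
                                      meta.loc[tr].reset_index(drop=True),
                                      plan, spec)
        assert trained.best_cv_score == pytest.approx(1.0)
        assert np.mean(trained.predict(X[~tr]) == y[~tr]) == 1.0
        # full CV table logged, one row per grid point
        assert len(trained.cv_table) == len(spec.param_grid())

    def test_single_class_rejected(self):
        X, y, meta = _separable()
        plan = grouped_split(meta, y, seed=1)
        with pytest.raises(ValueError):
            train_gridsearch_cv(X, np.zeros_like(y), meta, plan,
                                ClassifierSpec())

    def test_inverse_frequency_weights_balance_class_pull(self):
        # duplicate the negative class x3; the weighted model should sit
        # closer to the balanced-data model than the unweighted one does.
        rng = np.random.default_rng(7)
        n = 120
        y_bal = np.tile([0, 1], n // 2)
        X_bal = rng.normal(size=(n, 1)) + 1.5 * y_bal[:, None]
        dup = np.concatenate([np.flatnonzero(y_bal == 0)] * 3
                             + [np.flatnonzero(y_bal == 1)])
        X_imb, y_imb = X_bal[dup], y_bal[dup]

        from sklearn.svm import SVC
        probe = np.linspace(-2, 4, 200)[:, None]
        f_bal = SVC(kernel="linear").fit(X_bal, y_bal).decision_function(probe)
        f_w = SVC(kernel="linear", class_weight="balanced").fit(
            X_imb, y_imb).decision_function(probe)
        f_uw = SVC(kernel="linear").fit(X_imb, y_imb).decision_function(probe)
        assert np.abs(f_w - f_bal).mean() < np.abs(f_uw - f_bal).mean()

    def test_fitted_class_weights_conserve_total_pull(self):
        from sklearn.svm import SVC
        rng = np.random.default_rng(8)
        y = np.array([0] * 90 + [1] * 30)
        X = rng.normal(size=(120, 2)) + 2.0 * y[:, None]
        svc = SVC(kernel="linear", class_weight="balanced").fit(X, y)
        counts = np.bincount(y)
        pulls = svc.class_weight_ * counts
        assert pulls[0] == pytest.approx(pulls[1])


class TestAggregation:
    def test_majority_vote(self):
        df = pd.DataFrame({"sample_id": ["a"] * 3, "y_pred": [0, 0, 1]})
        assert assign_prediction_groups(df)["predicted_group"].iloc[0] == 0

    def test_tie_goes_to_degenerated_class(self):
        df = pd.DataFrame({"sample_id": ["a", "a"], "y_pred": [0, 1]})
        assert assign_prediction_groups(df)["predicted_group"].iloc[0] == 1

    def test_perfect_classifier_reproduces_reference_groups(self):
        df = pd.DataFrame({
            "sample_id": np.repeat([f"s{i}" for i in range(10)], 3),
            "y_pred": np.repeat([i % 2 for i in range(10)], 3)})
        out = assign_prediction_groups(df).set_index("sample_id")
        for i in range(10):
            assert out.loc[f"s{i}", "predicted_group"] == i % 2


class TestSiteExperiment:
    def test_three_repeats_leakage_free_and_reported(self, small_cohort):
        X, wl, meta = small_cohort.spectra_matrix("PT")
        results = run_site_experiment(
            X, wl, meta, ClassifierSpec(task="classifier1"), k_wavelengths=4,
            n_repeats=3, seed=2, min_spacing_nm=40.0)
        assert len(results) == 3
        assert len({r.plan.train_donors for r in results}) >= 2
        for r in results:
            assert not set(r.plan.train_donors) & set(r.plan.test_donors)
            # per-repeat selected and full-spectrum accuracies both reported
            assert r.report["accuracy_standard"] is not None
            assert r.report_full["accuracy_standard"] is not None
            assert len(r.selection.selected_wavelengths) == 4

    def test_classifier2_never_trains_or_tests_on_advanced_oa(self, small_cohort):
        X, wl, meta = small_cohort.spectra_matrix("TR")
        results = run_site_experiment(
            X, wl, meta, ClassifierSpec(task="classifier2"), k_wavelengths=3,
            n_repeats=2, seed=4, min_spacing_nm=40.0,
            include_full_spectrum=False)
        grades = meta.drop_duplicates("sample_id").set_index(
            "sample_id")["oarsi_grade"]
        for r in results:
            seen = r.test_predictions["sample_id"].map(grades)
            assert (seen <= 3).all()
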