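"""Classifier contract, fold mechanics, leakage protection and comparisons."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from conftest import make_matrix
from sap.errors import ValidationError
from sap.featurize import FeaturizationSpec, featurize_dataset
from sap.model import (
    ClassifierSpec,
    SAPModel,
    SelectionSpec,
    _fit_fold,
    compare_configurations,
    cross_validate_matrix,
    fold_assignments,
    stratified_kfold_cv,
    train,
)
from sap.peptide_io import Peptide, PeptideDataset
from sap.synthetic import GeneratorSpec, generate

LINEAR_SVM = ClassifierSpec(family="svm", params={"kernel": "linear", "C": 1.0})


@pytest.fixture(scope="module")
def small_synth():
    return generate(GeneratorSpec(n_pos=30, n_neg=30, length_range=(15, 40), seed=3))


@pytest.fixture(scope="module")
def small_matrix(small_synth):
    return featurize_dataset(
        small_synth, FeaturizationSpec(include_400d=False, gaps=(0,))
    )


class TestTrain:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        X = np.array([[0.0, 0.0], [0.1, 0.2], [1.0, 1.0], [0.9, 1.1]])
        m = make_matrix(X, y=[0, 0, 1, 1])
        fitted = train(LINEAR_SVM, m)
        assert (fitted.predict(m).to_numpy() == m.y.to_numpy()).all()

    def test_same_seed_gives_identical_predictions(self, small_matrix):
        spec = ClassifierSpec(family="random_forest", seed=5)
        p1 = train(spec, small_matrix).predict(small_matrix)
        p2 = train(spec, small_matrix).predict(small_matrix)
        pd.testing.assert_series_equal(p1, p2)

    def test_prediction_aligns_features_by_name(self, small_matrix):
        fitted = train(LINEAR_SVM, small_matrix)
        shuffled = small_matrix.X.sample(frac=1.0, axis=1, random_state=0)
        m2 = type(small_matrix)(X=shuffled, y=small_matrix.y)
        pd.testing.assert_series_equal(fitted.predict(small_matrix), fitted.predict(m2))

    def test_missing_feature_at_predict_time_rejected(self, small_matrix):
        fitted = train(LINEAR_SVM, small_matrix)
        m2 = small_matrix.select_features(small_matrix.feature_names[:100])
        with pytest.raises(ValidationError, match="lacks"):
            fitted.predict(m2)

    def test_single_class_training_rejected(self):
        m = make_matrix(np.random.default_rng(0).random((6, 3)), y=[1] * 6)
        with pytest.raises(ValidationError):
            train(LINEAR_SVM, m)


class TestFolds:
    def test_assignment_is_pure_function_of_inputs(self, small_matrix):
        args = (small_matrix.ids, small_matrix.y.to_numpy(), 5, 11)
        assert fold_assignments(*args) == fold_assignments(*args)

    def test_every_sample_tested_exactly_once_at_max_k(self):
        # leave-one-out limit under stratification: k = the smaller class size
        ds = PeptideDataset(
            tuple(
                Peptide(f"p{i}", "ACDEFGHIK", label=i % 2) for i in range(6)
            )
        )
        m = featurize_dataset(ds, FeaturizationSpec(include_400d=False, gaps=(0,)))
        folds = fold_assignments(m.ids, m.y.to_numpy(), k=3, seed=0)
        tested = [pid for _, test_ids in folds for pid in test_ids]
        assert sorted(tested) == sorted(m.ids)
        sizes = [len(test_ids) for _, test_ids in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_class_smaller_than_k_suggests_smaller_k(self, small_matrix):
        with pytest.raises(ValidationError, match="smaller k"):
            fold_assignments(small_matrix.ids, small_matrix.y.to_numpy(), 31, 0)


class TestCrossValidation:
    def test_pooled_counts_equal_fold_sums(self, small_matrix):
        report = cross_validate_matrix(small_matrix, LINEAR_SVM, k=5, seed=2)
        total = report.fold_counts[0]
        for c in report.fold_counts[1:]:
            total = total + c
        assert total == report.pooled
        assert len(report.fold_counts) == 5

    def test_selection_runs_inside_training_folds_only(self, small_matrix):
        sel = SelectionSpec(k=25)
        folds = fold_assignments(small_matrix.ids, small_matrix.y.to_numpy(), 5, 2)
        train_ids, test_ids = folds[0]
        full = _fit_fold(small_matrix, train_ids, sel, LINEAR_SVM)
        # deleting a held-out sample must not change the fitted selector
        kept = [i for i in small_matrix.ids if i != test_ids[0]]
        reduced = _fit_fold(small_matrix.subset_rows(kept), train_ids, sel, LINEAR_SVM)
        assert full.feature_names == reduced.feature_names

    def test_global_selection_switch_runs(self, small_matrix):
        report = cross_validate_matrix(
            small_matrix,
            LINEAR_SVM,
            selection=SelectionSpec(k=25, mode="global"),
            k=5,
            seed=2,
        )
        assert report.pooled.n_pos + report.pooled.n_neg == small_matrix.n_samples

    def test_summary_mentions_the_five_metrics(self, small_matrix):
        report = cross_validate_matrix(small_matrix, LINEAR_SVM, k=5, seed=2)
        text = report.summary()
        for name in ("Sn", "Sp", "Acc", "MCC", "F_score"):
            assert name in text


class TestSAPModelSurface:
    def test_fit_returns_results_with_selected_features(self, small_synth):
        model = SAPModel(
            small_synth,
            featurization=FeaturizationSpec(include_400d=False, gaps=(0,)),
            selection=SelectionSpec(k=30),
            classifier=LINEAR_SVM,
        )
        results = model.fit()
        assert len(results.selected_features) == 30
        assert results.ranking is not None
        preds = results.predict_dataset(small_synth)
        assert set(preds.unique()) <= {0, 1}
        assert "features used: 30" in results.summary()

    def test_cross_validate_matches_functional_surface(self, small_synth):
        fspec = FeaturizationSpec(include_400d=False, gaps=(0,))
        model = SAPModel(small_synth, featurization=fspec, classifier=LINEAR_SVM)
        r1 = model.cross_validate(k=5, seed=4)
        r2 = stratified_kfold_cv(small_synth, fspec, None, LINEAR_SVM, k=5, seed=4)
        assert r1.pooled == r2.pooled

    def test_unlabeled_dataset_rejected(self):
        ds = PeptideDataset((Peptide("a", "ACDEF"), Peptide("b", "KLMNP")))
        with pytest.raises(ValidationError):
            SAPModel(ds)


class TestCompareConfigurations:
    def test_identical_configurations_give_identical_reports(self, small_synth):
        fspec = FeaturizationSpec(include_400d=False, gaps=(0,))
        cfg = ("g0", fspec, None, LINEAR_SVM)
        table = compare_configurations(small_synth, [cfg, cfg], k=5, seed=1)
        pd.testing.assert_series_equal(
            table.iloc[0].drop("configuration"),
            table.iloc[1].drop("configuration"),
            check_names=False,
        )

    def test_three_classifiers_by_two_feature_sets_gives_six_rows(self, small_synth):
        plugin = ClassifierSpec(
            family="plugin",
            plugin_factory=lambda seed: LogisticRegression(max_iter=500, random_state=seed),
        )
        feature_sets = [
            ("400D", FeaturizationSpec(include_400d=True, gaps=())),
            ("g0", FeaturizationSpec(include_400d=False, gaps=(0,))),
        ]
        configs = [
            (name, fs, None, clf)
            for clf in (LINEAR_SVM, ClassifierSpec(family="random_forest"), plugin)
            for name, fs in feature_sets
        ]
        table = compare_configurations(small_synth, configs, k=3, seed=1)
        assert len(table) == 6
        assert set(table["classifier"]) == {"svm", "random_forest", "plugin"}

    def test_adjacent_pair_signal_favors_adjacent_features(self):
        # class signal lives purely in adjacent transitions, so features of
        # adjacent pairs should classify at least as well as 4-gap features
        ds = generate(
            GeneratorSpec(n_pos=60, n_neg=60, delta=0.4, length_range=(20, 40), seed=9)
        )
        configs = [
            ("g0", FeaturizationSpec(include_400d=False, gaps=(0,)), None, LINEAR_SVM),
            ("g4", FeaturizationSpec(include_400d=False, gaps=(4,)), None, LINEAR_SVM),
        ]
        table = compare_configurations(ds, configs, k=5, seed=9).set_index("configuration")
        assert table.loc["g0", "Acc"] >= table.loc["g4", "Acc"]

    def test_fewer_than_two_configurations_rejected(self, small_synth):
        with pytest.raises(ValidationError):
            compare_configurations(
                small_synth,
                [("only", FeaturizationSpec(), None, LINEAR_SVM)],
                k=3,
                seed=0,
            )
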