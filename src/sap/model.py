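"""Classifier training and stratified cross-validated evaluation.

The high-level surface is statsmodels-flavoured: :class:`SAPModel` binds a
labeled peptide dataset to a featurization + selection + classifier
configuration; ``fit()`` returns :class:`SAPResults` (the fitted pipeline,
its feature ranking and selected features, ready to predict on new
peptides), and ``cross_validate()`` returns a :class:`CVReport` carrying
per-fold and pooled confusion counts, the five metrics and a ``summary()``
table.

Classifier internals (SVM margin optimization, random-forest split search)
are delegated to scikit-learn behind the :class:`ClassifierSpec` contract; a
``plugin`` family accepts any estimator factory, so selective-ensemble or
other third-party classifiers can occupy the third slot.  All
data-dependent fitting — min-max scaling for the SVM, MRMD ranking and
pruning — happens inside each training fold and is then applied frozen to
the held-out fold; pooled metrics come from summed counts, never averaged
percentages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .errors import ValidationError
from .featurize import FeatureMatrix, FeaturizationSpec, featurize_dataset
from .metrics import ConfusionCounts, all_metrics, as_percent
from .mrmd import FeatureRanking, rank_features, select_top_k
from .peptide_io import PeptideDataset

#: Default (C, gamma) grid searched inside training folds for the RBF SVM.
SVM_PARAM_GRID: dict[str, list] = {
    "svc__C": [1.0, 10.0, 100.0],
    "svc__gamma": ["scale", 0.01, 0.1],
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier family to train and with what hyperparameters.

    ``svm`` is an RBF-kernel SVC behind a min-max scaler, with a small
    (C, gamma) grid searched by inner stratified 3-fold CV; ``random_forest``
    is a 300-tree forest on raw features; ``plugin`` wraps any callable
    ``factory(seed) -> estimator`` obeying the scikit-learn fit/predict
    contract.  The seed is always recorded and threaded to every stochastic
    component.
    """

    family: str = "svm"
    params: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0
    plugin_factory: Optional[Callable[[int], Any]] = None

    def __post_init__(self) -> None:
        if self.family not in ("svm", "random_forest", "plugin"):
            raise ValidationError(f"unknown classifier family {self.family!r}")
        if self.family == "plugin" and self.plugin_factory is None:
            raise ValidationError("plugin family requires a plugin_factory")

    def build(self):
        """Instantiate an unfitted estimator for this spec.

        For the SVM, empty ``params`` means the default RBF kernel with the
        small inner-CV (C, gamma) grid; explicit scalar params (e.g.
        ``{"kernel": "linear", "C": 1.0}``) fix the hyperparameters and skip
        the grid search.
        """
        if self.family == "svm":
            if self.params:
                return Pipeline(
                    [("scale", MinMaxScaler()), ("svc", SVC(**dict(self.params)))]
                )
            pipe = Pipeline([("scale", MinMaxScaler()), ("svc", SVC(kernel="rbf"))])
            return GridSearchCV(
                pipe,
                param_grid=dict(SVM_PARAM_GRID),
                cv=StratifiedKFold(3, shuffle=True, random_state=self.seed),
                n_jobs=1,
            )
        if self.family == "random_forest":
            params = {"n_estimators": 300, **dict(self.params)}
            return RandomForestClassifier(random_state=self.seed, **params)
        return self.plugin_factory(self.seed)  # type: ignore[misc]

    def describe(self) -> dict[str, Any]:
        return {"family": self.family, "params": dict(self.params), "seed": self.seed}


@dataclass(frozen=True)
class SelectionSpec:
    """MRMD selection settings: how many features to keep and how to score.

    ``k=None`` disables selection.  ``mode`` controls whether ranking/pruning
    is refit inside each training fold (the leakage-safe default) or once on
    all data (a replication switch for protocols that selected globally).
    """

    k: Optional[int] = None
    orientation: str = "printed"
    minmax_scale: bool = False
    mode: str = "per_fold"

    def __post_init__(self) -> None:
        if self.mode not in ("per_fold", "global"):
            raise ValidationError("selection mode must be 'per_fold' or 'global'")
        if self.k is not None and self.k < 1:
            raise ValidationError("k must be a positive integer")


@dataclass(frozen=True)
class FittedClassifier:
    """A trained classifier bound to the feature names it was fitted on."""

    estimator: Any
    feature_names: tuple[str, ...]

    def predict(self, m: FeatureMatrix) -> pd.Series:
        """Predict 0/1 labels, aligning the matrix columns by feature name."""
        missing = [n for n in self.feature_names if n not in m.X.columns]
        if missing:
            raise ValidationError(
                f"matrix lacks {len(missing)} fitted feature(s), e.g. {missing[:3]}"
            )
        X = m.X[list(self.feature_names)].to_numpy(dtype=float)
        return pd.Series(self.estimator.predict(X).astype(int), index=m.X.index)

    def decision_values(self, m: FeatureMatrix) -> pd.Series:
        X = m.X[list(self.feature_names)].to_numpy(dtype=float)
        est = self.estimator
        if hasattr(est, "decision_function"):
            vals = est.decision_function(X)
        elif hasattr(est, "predict_proba"):
            vals = est.predict_proba(X)[:, 1]
        else:
            vals = est.predict(X).astype(float)
        return pd.Series(np.asarray(vals, dtype=float), index=m.X.index)


def train(spec: ClassifierSpec, m: FeatureMatrix) -> FittedClassifier:
    """Fit a classifier on a labeled matrix; deterministic given the seed."""
    if m.y is None:
        raise ValidationError("training requires a labeled matrix")
    y = m.y.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("training set must contain both classes")
    if m.X.isna().any().any():
        raise ValidationError("training matrix contains missing values")
    est = spec.build()
    est.fit(m.X.to_numpy(dtype=float), y)
    return FittedClassifier(estimator=est, feature_names=m.feature_names)


def fold_assignments(
    ids: Sequence[str], labels: Sequence[int], k: int, seed: int
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Stratified fold assignment as a pure function of (ids, labels, k, seed)."""
    ids = list(ids)
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValidationError(
            f"smallest class has {counts.min()} members < k={k}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(np.zeros(len(ids)), y):
        folds.append(
            (
                tuple(ids[i] for i in train_idx),
                tuple(ids[i] for i in test_idx),
            )
        )
    return folds


@dataclass(frozen=True)
class CVReport:
    """Cross-validation outcome for one pipeline configuration.

    Carries the configuration fingerprint, per-fold and pooled confusion
    counts, the five pooled metrics, and a per-fold metric table.  Pooled
    counts always equal the sum of the per-fold counts.
    """

    config: dict[str, Any]
    fold_counts: tuple[ConfusionCounts, ...]
    pooled: ConfusionCounts
    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        total = self.fold_counts[0]
        for c in self.fold_counts[1:]:
            total = total + c
        if total != self.pooled:
            raise ValidationError("pooled counts must equal the sum of fold counts")

    @property
    def metrics(self) -> dict[str, float]:
        """The five pooled metrics as fractions."""
        return all_metrics(self.pooled)

    @property
    def per_fold_table(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.fold_counts, 1):
            row = {"fold": i, "n_test": c.n_pos + c.n_neg}
            try:
                row.update(all_metrics(c))
            except Exception:
                row.update(
                    {k: np.nan for k in ("Sn", "Sp", "Acc", "MCC", "F_score")}
                )
            rows.append(row)
        return pd.DataFrame(rows).set_index("fold")

    def summary(self) -> str:
        """Human-readable report: configuration, pooled metrics, fold table."""
        frac = self.metrics
        pct = as_percent(frac)
        lines = [
            "Cross-validation report",
            "=" * 60,
            f"configuration: {json.dumps(self.config, default=str)}",
            f"folds: {len(self.fold_counts)}   "
            f"N+={self.pooled.n_pos}  N-={self.pooled.n_neg}  "
            f"F-={self.pooled.f_neg}  F+={self.pooled.f_pos}",
            "-" * 60,
            "pooled metrics (fraction / percent):",
        ]
        for name in ("Sn", "Sp", "Acc", "MCC", "F_score"):
            lines.append(f"  {name:8s} {frac[name]:.6f}   {pct[name]:6.2f}%")
        lines.append("-" * 60)
        lines.append("per-fold metrics:")
        lines.append(self.per_fold_table.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """One-row tidy frame of the pooled metrics (fractions)."""
        return pd.DataFrame([{**self.config, **self.metrics}])


def _fit_fold(
    matrix: FeatureMatrix,
    train_ids: Sequence[str],
    selection: Optional[SelectionSpec],
    clf_spec: ClassifierSpec,
) -> FittedClassifier:
    train_m = matrix.subset_rows(train_ids)
    if selection is not None and selection.k is not None and selection.mode == "per_fold":
        ranking = rank_features(
            train_m,
            orientation=selection.orientation,
            minmax_scale=selection.minmax_scale,
        )
        k = min(selection.k, train_m.n_features)
        train_m = select_top_k(train_m, ranking, k)
    return train(clf_spec, train_m)


def cross_validate_matrix(
    matrix: FeatureMatrix,
    clf_spec: ClassifierSpec,
    selection: Optional[SelectionSpec] = None,
    k: int = 10,
    seed: int = 0,
    config: Optional[dict[str, Any]] = None,
) -> CVReport:
    """Stratified k-fold CV of a classifier (+ optional MRMD pruning).

    Selection in ``per_fold`` mode is refit on each training partition; in
    ``global`` mode the ranking is computed once on the full matrix before
    splitting (leak-prone, offered only as a replication switch).
    """
    if matrix.y is None:
        raise ValidationError("cross-validation requires labels")
    if selection is not None and selection.k is not None and selection.mode == "global":
        ranking = rank_features(
            matrix,
            orientation=selection.orientation,
            minmax_scale=selection.minmax_scale,
        )
        matrix = select_top_k(matrix, ranking, min(selection.k, matrix.n_features))
        selection = replace(selection, k=None)
    folds = fold_assignments(matrix.ids, matrix.y.to_numpy(), k, seed)
    fold_counts: list[ConfusionCounts] = []
    for train_ids, test_ids in folds:
        fitted = _fit_fold(matrix, train_ids, selection, clf_spec)
        test_m = matrix.subset_rows(test_ids)
        pred = fitted.predict(test_m)
        fold_counts.append(
            ConfusionCounts.from_predictions(test_m.y.to_numpy(), pred.to_numpy())
        )
    pooled = fold_counts[0]
    for c in fold_counts[1:]:
        pooled = pooled + c
    return CVReport(
        config=config or {"classifier": clf_spec.describe(), "k": k, "seed": seed},
        fold_counts=tuple(fold_counts),
        pooled=pooled,
        folds=tuple(folds),
    )


def stratified_kfold_cv(
    d: PeptideDataset,
    featurization: FeaturizationSpec,
    selection: Optional[SelectionSpec],
    clf_spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """Featurize a dataset, then run stratified k-fold CV.

    Featurization is per-peptide (no cross-sample fitting), so it can run
    once up front; every data-dependent step (scaling, MRMD) stays inside
    the training folds.
    """
    matrix = featurize_dataset(d, featurization)
    config = {
        "featurization": {
            "include_400d": featurization.include_400d,
            "mode_400d": featurization.mode_400d,
            "gaps": list(featurization.gaps),
            "include_aac": featurization.include_aac,
        },
        "selection": None
        if selection is None
        else {
            "k": selection.k,
            "orientation": selection.orientation,
            "mode": selection.mode,
        },
        "classifier": clf_spec.describe(),
        "cv_k": k,
        "cv_seed": seed,
    }
    return cross_validate_matrix(
        matrix, clf_spec, selection=selection, k=k, seed=seed, config=config
    )


def compare_configurations(
    d: PeptideDataset,
    configurations: Sequence[tuple[str, FeaturizationSpec, Optional[SelectionSpec], ClassifierSpec]],
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Run several (name, featurization, selection, classifier) configurations
    under identical fold assignments and return a tidy comparison table.

    One row per configuration with columns configuration, classifier, the
    five pooled metrics, and the pooled counts — the paired design means
    metric differences between rows are not confounded by fold luck.
    """
    if len(configurations) < 2:
        raise ValidationError("need at least 2 configurations to compare")
    rows = []
    for name, fspec, sel, cspec in configurations:
        report = stratified_kfold_cv(d, fspec, sel, cspec, k=k, seed=seed)
        rows.append(
            {
                "configuration": name,
                "classifier": cspec.family,
                **report.metrics,
                "N+": report.pooled.n_pos,
                "N-": report.pooled.n_neg,
                "F-": report.pooled.f_neg,
                "F+": report.pooled.f_pos,
            }
        )
    return pd.DataFrame(rows)


def choose_k_by_cv(
    matrix: FeatureMatrix,
    clf_spec: ClassifierSpec,
    grid: Optional[Sequence[int]] = None,
    k_folds: int = 5,
    seed: int = 0,
    orientation: str = "printed",
) -> int:
    """Pick the retained-feature count k maximizing pooled CV accuracy.

    The grid defaults to a geometric ladder 8, 16, ... up to the feature
    count; ties go to the smaller k.
    """
    if grid is None:
        grid, g = [], 8
        while g < matrix.n_features:
            grid.append(g)
            g *= 2
        grid.append(matrix.n_features)
    best_k, best_acc = None, -1.0
    for k in grid:
        sel = SelectionSpec(k=int(k), orientation=orientation)
        report = cross_validate_matrix(
            matrix, clf_spec, selection=sel, k=k_folds, seed=seed
        )
        acc = report.metrics["Acc"]
        if acc > best_acc + 1e-12:
            best_k, best_acc = int(k), acc
    return best_k  # type: ignore[return-value]


class SAPModel:
    """Sequence-based anticancer-peptide classifier bound to a dataset.

    Parameters
    ----------
    dataset : PeptideDataset
        Labeled peptides (training mode).
    featurization : FeaturizationSpec
        Feature blocks to compute (default: 400D counts + g-gap blocks 0..4).
    selection : SelectionSpec or None
        MRMD pruning settings; None disables selection.
    classifier : ClassifierSpec
        Classifier family, hyperparameters and seed.

    ``fit()`` trains on all data and returns :class:`SAPResults`;
    ``cross_validate(k, seed)`` evaluates the configuration under stratified
    k-fold CV and returns a :class:`CVReport`.
    """

    def __init__(
        self,
        dataset: PeptideDataset,
        featurization: FeaturizationSpec = FeaturizationSpec(),
        selection: Optional[SelectionSpec] = None,
        classifier: ClassifierSpec = ClassifierSpec(),
    ) -> None:
        if not dataset.is_labeled:
            raise ValidationError("SAPModel requires a labeled dataset")
        self.dataset = dataset
        self.featurization = featurization
        self.selection = selection
        self.classifier = classifier
        self._matrix = featurize_dataset(dataset, featurization)

    @classmethod
    def from_fasta(cls, path, labels_path=None, **kwargs) -> "SAPModel":
        from .peptide_io import read_fasta

        return cls(read_fasta(path, labels_path=labels_path), **kwargs)

    @property
    def feature_matrix(self) -> FeatureMatrix:
        return self._matrix

    def fit(self) -> "SAPResults":
        """Train on the full dataset (ranking + pruning + classifier)."""
        matrix = self._matrix
        ranking: Optional[FeatureRanking] = None
        if self.selection is not None and self.selection.k is not None:
            ranking = rank_features(
                matrix,
                orientation=self.selection.orientation,
                minmax_scale=self.selection.minmax_scale,
            )
            matrix = select_top_k(
                matrix, ranking, min(self.selection.k, matrix.n_features)
            )
        fitted = train(self.classifier, matrix)
        return SAPResults(model=self, fitted=fitted, ranking=ranking)

    def cross_validate(self, k: int = 10, seed: int = 0) -> CVReport:
        return stratified_kfold_cv(
            self.dataset, self.featurization, self.selection, self.classifier,
            k=k, seed=seed,
        )


@dataclass(frozen=True)
class SAPResults:
    """Fitted-model results: the trained pipeline and its feature ranking."""

    model: SAPModel
    fitted: FittedClassifier
    ranking: Optional[FeatureRanking]

    @property
    def selected_features(self) -> tuple[str, ...]:
        return self.fitted.feature_names

    def predict_dataset(self, d: PeptideDataset) -> pd.Series:
        """Predict 0/1 labels for new peptides under the fitted featurization."""
        matrix = featurize_dataset(d, self.model.featurization)
        return self.fitted.predict(matrix)

    def predict_matrix(self, m: FeatureMatrix) -> pd.Series:
        return self.fitted.predict(m)

    def summary(self) -> str:
        lines = [
            "SAP fitted model",
            "=" * 60,
            f"classifier: {json.dumps(self.model.classifier.describe())}",
            f"features used: {len(self.selected_features)}",
        ]
        if self.ranking is not None:
            lines.append("top 10 MRMD-ranked features:")
            lines.append(
                self.ranking.table.head(10).to_string(
                    float_format=lambda v: f"{v:.4f}"
                )
            )
        return "\n".join(lines)
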