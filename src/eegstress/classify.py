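"""Multi-classifier benchmark of raw vs latent biomarker features.

Seven classifier families are benchmarked on each feature set under
stratified 5-fold cross-validation: RBF-kernel SVM, AdaBoost (depth-1 tree
base learners, 50 rounds), linear discriminant analysis, ridge classifier,
random forest (100 trees), k-nearest neighbours (k=5, Minkowski p=2) and an
optional deep-belief-style neural network adapter.

Every data-dependent transformation is fold-safe by default: per-feature
standardization and, for latent representations, the autoencoder itself are
fitted on the training folds only, so a test window never influences the
representation it is scored in.  A global (optimistic) autoencoder mode is
available for comparison.

Cross-validation is stratified over condition labels pooled across subjects
(window-level CV).  Windows of one participant can then appear in both the
training and test fold, which inflates accuracy relative to a new-subject
setting; a subject-grouped mode (``grouped=True``) is provided for the
conservative estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import RidgeClassifier
from sklearn.metrics import accuracy_score, f1_score, precision_score
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .autoencoder import AEArchitecture, TrainConfig, encode_matrix, train
from .features import WindowedFeatures

DETERMINISTIC_CLASSIFIERS = ("svm", "adaboost", "lda", "ridge", "random_forest", "knn")
ALL_CLASSIFIERS = DETERMINISTIC_CLASSIFIERS + ("dbn",)


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ALL_CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.name!r}; expected one of {ALL_CLASSIFIERS}")

    def build(self, seed: int):
        hp = dict(self.hyperparameters)
        if self.name == "svm":
            return SVC(kernel=hp.pop("kernel", "rbf"), C=hp.pop("C", 1.0),
                       gamma=hp.pop("gamma", "scale"), random_state=seed, **hp)
        if self.name == "adaboost":
            depth = hp.pop("base_max_depth", 1)
            return AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=depth, random_state=seed),
                n_estimators=hp.pop("n_estimators", 50), random_state=seed, **hp)
        if self.name == "lda":
            return LinearDiscriminantAnalysis(**hp)
        if self.name == "ridge":
            return RidgeClassifier(random_state=seed, **hp)
        if self.name == "random_forest":
            return RandomForestClassifier(n_estimators=hp.pop("n_estimators", 100),
                                          random_state=seed, **hp)
        if self.name == "knn":
            return KNeighborsClassifier(n_neighbors=hp.pop("k", 5), p=hp.pop("p", 2), **hp)
        # deep-belief-style adapter: two 64-unit layers, no greedy pretraining
        return MLPClassifier(hidden_layer_sizes=hp.pop("hidden_layer_sizes", (64, 64)),
                             max_iter=hp.pop("max_iter", 200), random_state=seed, **hp)


def default_classifiers(include_dbn: bool = False) -> list[ClassifierSpec]:
    names = ALL_CLASSIFIERS if include_dbn else DETERMINISTIC_CLASSIFIERS
    return [ClassifierSpec(name) for name in names]


@dataclass
class BenchmarkResult:
    feature_set: str
    representation: str  # "raw" or "latent"
    classifier: str
    fold_accuracies: list[float]
    per_class_precision: dict[str, float]
    per_class_f1: dict[str, float]
    n_folds: int
    seed: int
    group_filter: str = "all"
    fold_diagnostics: list[dict] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def _apply_group_filter(features: WindowedFeatures, group_filter: str) -> WindowedFeatures:
    if group_filter == "all":
        return features
    if group_filter not in ("nurse", "control"):
        raise ValueError(f"group_filter must be all/nurse/control, got {group_filter!r}")
    mask = features.groups == group_filter
    if not mask.any():
        raise ValueError(f"no rows with group {group_filter!r}")
    return features.subset(mask)


def _fold_iter(y, subject_ids, n_folds, seed, grouped):
    if grouped:
        splitter = GroupKFold(n_splits=n_folds)
        return splitter.split(np.zeros(len(y)), y, groups=subject_ids)
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return splitter.split(np.zeros(len(y)), y)


def crossvalidate(
    features: WindowedFeatures,
    spec: ClassifierSpec,
    n_folds: int = 5,
    seed: int = 0,
    group_filter: str = "all",
    encoder_factory=None,
    grouped: bool = False,
    collect_diagnostics: bool = False,
) -> BenchmarkResult:
    """Stratified k-fold cross-validation of one classifier on one feature set.

    `encoder_factory(X_train, fold_seed) -> transform` optionally injects a
    fold-safe representation learner (e.g. an autoencoder trained on the
    training rows only); the returned transform is applied to both folds.
    Standardization is always fitted on the training fold.
    """
    features = _apply_group_filter(features, group_filter)
    y = np.asarray(features.labels, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} rows; need >= {n_folds}"
        )

    fold_acc, diags = [], []
    prec_per_class = np.zeros(len(classes))
    f1_per_class = np.zeros(len(classes))
    for fold_idx, (tr, te) in enumerate(
        _fold_iter(y, features.subject_ids, n_folds, seed, grouped)
    ):
        X_tr, X_te = features.matrix[tr], features.matrix[te]
        fold_seed = seed * 1000 + fold_idx
        if encoder_factory is not None:
            transform = encoder_factory(X_tr, fold_seed)
            X_tr, X_te = transform(X_tr), transform(X_te)
        scaler = StandardScaler().fit(X_tr)
        X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        clf = spec.build(fold_seed)
        clf.fit(X_tr, y[tr])
        pred = clf.predict(X_te)
        fold_acc.append(float(accuracy_score(y[te], pred)))
        prec_per_class += precision_score(y[te], pred, labels=classes, average=None, zero_division=0)
        f1_per_class += f1_score(y[te], pred, labels=classes, average=None, zero_division=0)
        if collect_diagnostics:
            diags.append({
                "fold": fold_idx,
                "train_index": tr, "test_index": te,
                "scaler_mean": scaler.mean_.copy(),
                "transform": transform if encoder_factory is not None else None,
            })
    n_done = len(fold_acc)
    return BenchmarkResult(
        feature_set=features.feature_set,
        representation="latent" if encoder_factory is not None or
        features.feature_set.endswith("_latent") else "raw",
        classifier=spec.name,
        fold_accuracies=fold_acc,
        per_class_precision={c: float(p / n_done) for c, p in zip(classes, prec_per_class)},
        per_class_f1={c: float(f / n_done) for c, f in zip(classes, f1_per_class)},
        n_folds=n_folds, seed=seed, group_filter=group_filter,
        fold_diagnostics=diags,
    )


def make_ae_encoder_factory(
    arch: AEArchitecture | None = None, hyper: TrainConfig = TrainConfig()
):
    """Factory for fold-safe latent representations: trains a fresh
    autoencoder on the training rows of each fold.

    Trained models are memoized on (fold_seed, training-data fingerprint), so
    benchmarking several classifiers over identical folds trains each fold's
    autoencoder once.
    """
    cache: dict = {}

    def factory(X_train: np.ndarray, fold_seed: int):
        key = (fold_seed, X_train.shape, hash(X_train.tobytes()))
        if key in cache:
            return cache[key]
        a = arch or AEArchitecture(input_dim=X_train.shape[1])
        model = train(X_train, a, TrainConfig(
            lr=hyper.lr, batch_size=hyper.batch_size, max_epochs=hyper.max_epochs,
            patience=hyper.patience, seed=fold_seed,
        ))

        def transform(X: np.ndarray) -> np.ndarray:
            return encode_matrix(model, X)

        transform.model = model
        cache[key] = transform
        return transform

    return factory


def run_benchmark(
    raw_sets: dict[str, WindowedFeatures],
    classifiers: list[ClassifierSpec] | None = None,
    n_folds: int = 5,
    seed: int = 0,
    group_filters: tuple[str, ...] = ("all",),
    ae_hyper: TrainConfig = TrainConfig(),
    ae_global: bool = False,
    grouped: bool = False,
) -> list[BenchmarkResult]:
    """Full benchmark: every feature set x {raw, latent} x classifier x group.

    Latent representations are fold-safe by default (one autoencoder per
    training fold); `ae_global=True` trains a single autoencoder on all rows
    first, the optimistic variant.
    """
    if classifiers is None:
        classifiers = default_classifiers()
    results: list[BenchmarkResult] = []
    for gf in group_filters:
        for name, feats in raw_sets.items():
            for spec in classifiers:
                results.append(crossvalidate(feats, spec, n_folds, seed, gf, grouped=grouped))
            if ae_global:
                from .autoencoder import encode

                model = train(_apply_group_filter(feats, gf),
                              AEArchitecture(input_dim=feats.matrix.shape[1]),
                              TrainConfig(lr=ae_hyper.lr, batch_size=ae_hyper.batch_size,
                                          max_epochs=ae_hyper.max_epochs,
                                          patience=ae_hyper.patience, seed=seed))
                latent = encode(model, _apply_group_filter(feats, gf))
                for spec in classifiers:
                    res = crossvalidate(latent, spec, n_folds, seed, "all", grouped=grouped)
                    res.group_filter = gf
                    results.append(res)
            else:
                factory = make_ae_encoder_factory(hyper=ae_hyper)
                for spec in classifiers:
                    res = crossvalidate(feats, spec, n_folds, seed, gf,
                                        encoder_factory=factory, grouped=grouped)
                    res.feature_set = name + "_latent"
                    results.append(res)
    return results


def report(results: list[BenchmarkResult]) -> pd.DataFrame:
    """Tabulate a benchmark, sorted by (feature_set, accuracy desc), flagging
    the best classifier per feature set.  NaN metrics are a hard error."""
    if not results:
        raise ValueError("no results to report")
    rows = []
    for r in results:
        row = {
            "feature_set": r.feature_set,
            "representation": r.representation,
            "classifier": r.classifier,
            "group_filter": r.group_filter,
            "mean_accuracy": r.mean_accuracy,
        }
        for c, v in r.per_class_precision.items():
            row[f"precision_{c}"] = v
        for c, v in r.per_class_f1.items():
            row[f"f1_{c}"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    metric_cols = [c for c in df.columns if c not in
                   ("feature_set", "representation", "classifier", "group_filter")]
    if df[metric_cols].isna().any().any():
        raise ValueError("NaN metric in benchmark results")
    df = df.sort_values(["feature_set", "mean_accuracy"],
                        ascending=[True, False]).reset_index(drop=True)
    df["best_in_set"] = False
    idx = df.groupby("feature_set")["mean_accuracy"].idxmax()
    df.loc[idx, "best_in_set"] = True
    return df
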