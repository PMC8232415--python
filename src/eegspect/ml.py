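"""Classical learning pipeline on tCENTRIST features.

PCA dimension reduction, a six-classifier bank (NB, LDA, RF, kNN, LR,
linear SVM), stratified ten-fold cross-validation, and the metric suite.
PCA is always fitted inside each training fold only; the test portion is
merely transformed, so no test statistics leak into the fit.

Frozen classifier defaults (all overridable through ``params``):
Gaussian NB; LDA with SVD solver (pseudo-inverse-style handling of
singular covariance, i.e. "pseudolinear"); random forest with 100 trees;
kNN with k = 9 and Euclidean distance; L2 logistic regression; linear-kernel
SVM with C = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .metrics import ConfusionCounts, MetricsReport, compute_metrics, compute_roc_auc

CLASSIFIER_NAMES = ("nb", "lda", "rf", "knn", "lr", "svm")


@dataclass
class LabeledFeatureSet:
    """Feature matrix with binary labels (1 = ASD) and provenance ids."""

    features: np.ndarray  # (n_items, n_dims)
    labels: np.ndarray  # 0/1 per item
    subject_ids: np.ndarray  # str per item
    item_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels).astype(int)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        n = self.features.shape[0]
        if self.item_ids is None:
            self.item_ids = np.array([f"item{i:05d}" for i in range(n)], dtype=object)
        if not (len(self.labels) == len(self.subject_ids) == len(self.item_ids) == n):
            raise ValueError("features, labels, subject_ids and item_ids must align")

    def __len__(self) -> int:
        return self.features.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features)
        df.insert(0, "item_id", self.item_ids)
        df.insert(1, "subject", self.subject_ids)
        df.insert(2, "label", self.labels)
        return df

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "LabeledFeatureSet":
        meta = ("item_id", "subject", "label")
        feats = df.drop(columns=[c for c in meta if c in df.columns])
        return LabeledFeatureSet(
            features=feats.to_numpy(dtype=float),
            labels=df["label"].to_numpy(),
            subject_ids=df["subject"].to_numpy(),
            item_ids=df["item_id"].to_numpy() if "item_id" in df else None,
        )


@dataclass
class PCAModel:
    mean: np.ndarray
    components: np.ndarray  # (n_components, n_dims), orthonormal rows
    explained_variance_ratio: np.ndarray
    target_variance: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(train_features: np.ndarray, target_variance: float = 0.95,
            max_components: int | None = None, seed: int = 0) -> PCAModel:
    """Fit PCA on training data and keep the smallest component count whose
    cumulative explained-variance ratio reaches ``target_variance``.

    ``max_components`` caps the computed basis (randomized SVD is used when
    the cap is far below min(n, d)); the component count never exceeds
    n_train - 1. If the target is not reached within the cap, all computed
    components are kept.
    """
    X = np.asarray(train_features, dtype=float)
    n, d = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 training items")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate training set: all items identical")
    limit = min(n - 1, d)
    if max_components is not None:
        limit = min(limit, max_components)
    solver = "randomized" if limit < min(n, d) // 2 else "auto"
    pca = _SKPCA(n_components=limit, svd_solver=solver, random_state=seed)
    pca.fit(X)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, target_variance - 1e-12) + 1)
    k = min(k, len(ratios))
    return PCAModel(
        mean=pca.mean_,
        components=pca.components_[:k],
        explained_variance_ratio=ratios[:k],
        target_variance=target_variance,
    )


def pca_transform(model: PCAModel, features: np.ndarray) -> np.ndarray:
    return (np.asarray(features, dtype=float) - model.mean) @ model.components.T


@dataclass
class FoldPlan:
    k: int
    seed: int
    fold_index: np.ndarray  # test-fold assignment per item
    stratified: bool = True
    grouping: str = "image"  # image | subject

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def make_folds(fset: LabeledFeatureSet, k: int = 10, seed: int = 0,
               stratified: bool = True, grouping: str = "image") -> FoldPlan:
    """Assign every item to exactly one test fold, deterministically.

    grouping="subject" keeps all of a subject's items in the same fold so
    subject identity cannot leak across the split.
    """
    n = len(fset)
    if grouping not in ("image", "subject"):
        raise ValueError("grouping must be 'image' or 'subject'")
    if grouping == "subject":
        n_groups = len(np.unique(fset.subject_ids))
        if k > n_groups:
            raise ValueError(f"k={k} exceeds the {n_groups} available subjects")
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(fset.features, fset.labels, groups=fset.subject_ids)
    else:
        if k > n:
            raise ValueError(f"k={k} exceeds the {n} available items")
        if stratified:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        else:
            from sklearn.model_selection import KFold

            splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(fset.features, fset.labels)
    fold_index = np.full(n, -1, dtype=int)
    for fold, (_, test_idx) in enumerate(splits):
        fold_index[test_idx] = fold
    return FoldPlan(k=k, seed=seed, fold_index=fold_index, stratified=stratified, grouping=grouping)


def train_classifier(name: str, X: np.ndarray, y: np.ndarray,
                     params: dict | None = None, seed: int = 0):
    """Fit one of the six bank classifiers on (X, y)."""
    name = name.lower()
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    params = dict(params or {})
    if name == "nb":
        model = GaussianNB(**params)
    elif name == "lda":
        model = LinearDiscriminantAnalysis(solver="svd", **params)
    elif name == "rf":
        params.setdefault("n_estimators", 100)
        model = RandomForestClassifier(random_state=seed, **params)
    elif name == "knn":
        params.setdefault("n_neighbors", 9)
        model = KNeighborsClassifier(metric="euclidean", **params)
    elif name == "lr":
        params.setdefault("max_iter", 2000)
        model = LogisticRegression(**params)  # default L2 penalty
    elif name == "svm":
        params.setdefault("C", 1.0)
        model = SVC(kernel="linear", random_state=seed, **params)
    else:
        raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIER_NAMES}")
    model.fit(X, y)
    return model


def predict_with_scores(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels plus continuous ASD-class scores usable for ROC."""
    labels = model.predict(X)
    if hasattr(model, "decision_function"):
        scores = model.decision_function(X)
    else:
        scores = model.predict_proba(X)[:, 1]
    return np.asarray(labels).astype(int), np.asarray(scores, dtype=float)


def cross_validate(
    fset: LabeledFeatureSet,
    classifier: str,
    plan: FoldPlan | None = None,
    pca_target: float = 0.95,
    pca_max_components: int | None = 256,
    k: int = 10,
    seed: int = 0,
    params: dict | None = None,
) -> MetricsReport:
    """k-fold cross-validation of one classifier with per-fold PCA.

    Per fold: fit PCA on the training portion only, transform both
    portions, train, predict the test portion. Headline metrics pool the
    per-fold confusion counts and the pooled scores feed one ROC; per-fold
    metrics are kept in ``per_fold``. Deterministic given the seed.
    """
    if plan is None:
        plan = make_folds(fset, k=k, seed=seed)
    pooled = ConfusionCounts()
    all_scores = np.zeros(len(fset))
    per_fold: list[MetricsReport] = []
    for fold in range(plan.k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        pca = fit_pca(fset.features[tr], target_variance=pca_target,
                      max_components=pca_max_components, seed=seed)
        Xtr = pca_transform(pca, fset.features[tr])
        Xte = pca_transform(pca, fset.features[te])
        model = train_classifier(classifier, Xtr, fset.labels[tr], params=params, seed=seed)
        pred, scores = predict_with_scores(model, Xte)
        all_scores[te] = scores
        counts = ConfusionCounts.from_labels(fset.labels[te], pred)
        pooled = pooled + counts
        fold_report = compute_metrics(counts)
        if len(np.unique(fset.labels[te])) == 2:
            fold_report.auc = compute_roc_auc(scores, fset.labels[te])[0]
        per_fold.append(fold_report)
    report = compute_metrics(pooled)
    report.auc = compute_roc_auc(all_scores, fset.labels)[0]
    report.per_fold = per_fold
    return report


def cross_validate_all(fset: LabeledFeatureSet, **kwargs) -> dict[str, MetricsReport]:
    """Run the whole classifier bank; returns {classifier: report}."""
    return {name: cross_validate(fset, name, **kwargs) for name in CLASSIFIER_NAMES}
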