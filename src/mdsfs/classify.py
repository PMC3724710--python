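"""Classifiers and the cross-validated subset evaluator H(.).

The quality of an attribute subset is its average k-fold cross-validation
accuracy, written H(subset): the feature matrix of the subset is split into
k folds, a classifier is trained on each complement and scored on the held
out fold, and the k fold accuracies are averaged (unweighted).

Three classifiers are provided: a linear-discriminant projection followed by
nearest-centroid assignment (authored here), a linear-kernel SVM and
Gaussian naive Bayes (scikit-learn).  One fold partition is fixed per
selection run so that every subset is scored on identical folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import accuracy_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y, validate_data

from .attributes import AttributeTable
from .autocorrelation import LagSpec, AutocorrelationTransformer
from .errors import MDSFSError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings shared by all subset evaluations of one run.

    ``partition_id`` names one concrete fold assignment; evaluators built
    from the same config reuse the identical folds, so repeated evaluation
    of a subset is bit-identical.
    """

    k: int = 10
    seed: int = 0
    stratified: bool = True
    partition_id: str = "default"


@dataclass(frozen=True)
class ClassifierSpec:
    """Named classifier family plus hyperparameter overrides."""

    kind: str = "lda"
    hyperparameters: Mapping = field(default_factory=dict)

    _ALIASES = {
        "lda": "lda", "lda_nearest_centroid": "lda",
        "svm": "svm", "nb": "nb", "naivebayes": "nb", "custom": "custom",
    }

    def canonical_kind(self) -> str:
        try:
            return self._ALIASES[self.kind.lower()]
        except KeyError:
            raise MDSFSError(f"unknown classifier kind {self.kind!r}") from None


@dataclass(frozen=True)
class EvaluationResult:
    """H(subset): mean and per-fold k-fold CV accuracy."""

    alpha: float
    per_fold: tuple[float, ...]
    n_samples: int
    n_features: int

    def __post_init__(self) -> None:
        if not np.isclose(self.alpha, float(np.mean(self.per_fold))):
            raise MDSFSError("alpha must equal the mean of per-fold accuracies")


class LDANearestCentroid(ClassifierMixin, BaseEstimator):
    """Linear discriminant projection with nearest-centroid assignment.

    Training maximizes between-class versus within-class scatter: solve the
    generalized eigenproblem S_b w = lambda S_w w and keep the leading
    min(C-1, rank) directions.  A test point is assigned to the class whose
    projected centroid is nearest in Euclidean distance.

    The within-class scatter is ridge-regularized by ``ridge * trace(S_w)/D``
    on the diagonal so the solve never fails when features outnumber samples.

    Parameters
    ----------
    ridge : float, default 1e-6
        Relative diagonal loading of the within-class scatter.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("LDANearestCentroid requires >= 2 classes")
        n, d = X.shape
        mean = X.mean(axis=0)
        Sw = np.zeros((d, d))
        Sb = np.zeros((d, d))
        means = np.empty((n_classes, d))
        for c in range(n_classes):
            Xc = X[y_idx == c]
            means[c] = Xc.mean(axis=0)
            dev = Xc - means[c]
            Sw += dev.T @ dev
            diff = (means[c] - mean)[:, None]
            Sb += len(Xc) * (diff @ diff.T)
        tr = np.trace(Sw)
        eps = self.ridge * (tr / d if tr > 0 else 1.0)
        Sw[np.diag_indices_from(Sw)] += eps
        n_comp = min(n_classes - 1, d)
        evals, evecs = scipy.linalg.eigh(
            Sb, Sw, subset_by_index=(d - n_comp, d - 1)
        )
        order = np.argsort(evals)[::-1]
        self.scalings_ = evecs[:, order]
        self.eigenvalues_ = evals[order]
        self.centroids_ = means @ self.scalings_
        self.n_features_in_ = d
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "scalings_")
        X = validate_data(self, X, reset=False)
        return X @ self.scalings_

    def predict(self, X):
        Z = self.transform(X)
        d2 = ((Z[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]


def make_classifier(spec: ClassifierSpec | str = "lda") -> BaseEstimator:
    """Instantiate the classifier a :class:`ClassifierSpec` describes."""
    if isinstance(spec, str):
        spec = ClassifierSpec(kind=spec)
    kind = spec.canonical_kind()
    hp = dict(spec.hyperparameters)
    if kind == "lda":
        return LDANearestCentroid(**hp)
    if kind == "svm":
        # linear kernel, C = 1, one-vs-one multiclass (SVC default)
        hp = {"kernel": "linear", "C": 1.0, **hp}
        return SVC(**hp)
    if kind == "nb":
        return GaussianNB(**hp)
    if kind == "custom":
        est = hp.pop("estimator", None)
        if est is None:
            raise MDSFSError("custom classifier spec needs an 'estimator' entry")
        return clone(est).set_params(**hp)
    raise MDSFSError(f"unknown classifier kind {spec.kind!r}")


def make_partition(labels: Sequence, cv: CVConfig) -> np.ndarray:
    """Assign each sample to one of ``cv.k`` folds.

    Deterministic under ``(cv.seed, labels)``.  Stratified when requested;
    if some class has fewer samples than ``k`` the split falls back to an
    unstratified one with a warning.

    Returns
    -------
    ndarray of int, shape (n_samples,)
        Fold index in ``0..k-1`` per sample.
    """
    y = np.asarray(labels)
    n = len(y)
    if n == 0:
        raise MDSFSError("labels are empty")
    if not 2 <= cv.k <= n:
        raise MDSFSError(f"fold count k={cv.k} must satisfy 2 <= k <= {n} samples")
    stratified = cv.stratified
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < cv.k:
            warnings.warn(
                "a class has fewer samples than folds; "
                "falling back to unstratified folds",
                stacklevel=2,
            )
            stratified = False
    if stratified:
        splitter = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    else:
        splitter = KFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    assignment = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), y)):
        assignment[test_idx] = fold
    return assignment


def kfold_accuracy(
    X: np.ndarray,
    y: Sequence,
    spec: ClassifierSpec | str | BaseEstimator,
    partition: np.ndarray,
    standardize: bool = False,
) -> EvaluationResult:
    """H(.): average k-fold cross-validation accuracy of a classifier.

    Parameters
    ----------
    X, y : feature matrix rows and aligned labels.
    spec : classifier family (see :func:`make_classifier`) or an estimator
        instance to clone per fold.
    partition : fold index per row, as built by :func:`make_partition`.
    standardize : bool, default False
        Per-column z-scoring fit on the training folds only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    partition = np.asarray(partition)
    if partition.shape[0] != X.shape[0]:
        raise MDSFSError("partition does not cover all feature matrix rows")
    if len(np.unique(y)) < 2:
        raise MDSFSError("need >= 2 classes to evaluate")
    base = spec if isinstance(spec, BaseEstimator) else make_classifier(spec)
    folds = np.unique(partition)
    accs = []
    for fold in folds:
        test = partition == fold
        train = ~test
        if len(np.unique(y[train])) < len(np.unique(y)):
            missing = set(np.unique(y)) - set(np.unique(y[train]))
            warnings.warn(
                f"fold {fold}: training split is missing class(es) {missing}; "
                "those classes are unlearnable in this fold",
                stacklevel=2,
            )
        Xtr, Xte = X[train], X[test]
        if standardize:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        clf = clone(base).fit(Xtr, y[train])
        accs.append(accuracy_score(y[test], clf.predict(Xte)))
    accs = tuple(float(a) for a in accs)
    return EvaluationResult(
        alpha=float(np.mean(accs)), per_fold=accs,
        n_samples=X.shape[0], n_features=X.shape[1],
    )


class SubsetEvaluator:
    """Callable H(.) over attribute subsets of one labeled sequence dataset.

    Per-attribute descriptor blocks are computed once and concatenated per
    subset, and results are cached by frozen subset, so greedy searches with
    tie beams never re-score a subset.  All evaluations share one fixed fold
    partition.
    """

    def __init__(
        self,
        sequences: Sequence[str],
        labels: Sequence,
        table: AttributeTable,
        classifier: ClassifierSpec | str = "lda",
        cv: CVConfig = CVConfig(),
        lag: LagSpec | int = LagSpec(),
        standardize: bool = False,
    ):
        self.table = table
        self.labels = np.asarray(labels)
        self.classifier = classifier
        self.cv = cv
        self.d = lag.d if isinstance(lag, LagSpec) else LagSpec(lag).d
        self.standardize = standardize
        self.partition = make_partition(self.labels, cv)
        self._blocks: dict[str, np.ndarray] = {}
        self._sequences = list(sequences)
        self._cache: dict[frozenset, EvaluationResult] = {}
        self.n_evaluations = 0  # cache misses, i.e. distinct H(.) computations

    def _block(self, symbol: str) -> np.ndarray:
        if symbol not in self._blocks:
            tr = AutocorrelationTransformer(
                subset=[symbol], d=self.d, table=self.table
            ).fit(self._sequences)
            self._blocks[symbol] = tr.transform(self._sequences)
        return self._blocks[symbol]

    def features(self, subset: Sequence) -> np.ndarray:
        symbols = [a if isinstance(a, str) else a.symbol for a in subset]
        return np.hstack([self._block(s) for s in symbols])

    def evaluate(self, subset: Sequence) -> EvaluationResult:
        symbols = tuple(a if isinstance(a, str) else a.symbol for a in subset)
        key = frozenset(symbols)
        if key not in self._cache:
            result = kfold_accuracy(
                self.features(symbols), self.labels, self.classifier,
                self.partition, standardize=self.standardize,
            )
            self._cache[key] = result
            self.n_evaluations += 1
            logger.debug(
                "H(%s) = %.4f (folds: %s)",
                "".join(symbols), result.alpha,
                ", ".join(f"{a:.3f}" for a in result.per_fold),
            )
        return self._cache[key]

    def __call__(self, subset: Sequence) -> float:
        return self.evaluate(subset).alpha


def evaluator_from_weights(weights: Mapping[str, float]) -> Callable:
    """Modular mock evaluator H(S) = mean of per-attribute weights.

    Useful for closed-form checks of the greedy searches: under a modular
    score both schemes rank attributes in exact weight order.
    """

    def h(subset: Sequence) -> float:
        symbols = [a if isinstance(a, str) else a.symbol for a in subset]
        if not symbols:
            raise MDSFSError("empty subset")
        return float(np.mean([weights[s] for s in symbols]))

    return h
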