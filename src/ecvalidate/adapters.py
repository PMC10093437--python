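"""Classifier adapters: the fit/predict contract the engine consumes.

The engine is agnostic about what does the learning; it only needs an
object with ``fit(X, y, ids)`` and ``predict(X, ids) -> labels``.  Sample
ids travel alongside feature rows because error sets are defined over
sample *identity*, not feature values: the deterministic mock classifiers
below key their behaviour on ids, which makes error-consistency outcomes
exactly predictable and the whole pipeline testable without any real
learning.  Real estimators simply ignore the ids.
"""

from __future__ import annotations

import copy
from typing import Any, Iterable, Mapping

import numpy as np
from sklearn.base import clone as _sk_clone

from .datasets import Dataset
from .exceptions import ClassifierContractError, InvalidInputError


class ClassifierAdapter:
    """Base adapter.  Subclasses implement fit/predict; ``descriptor`` names
    the classifier in reports."""

    descriptor: str = "classifier"

    def fit(self, features: np.ndarray, labels: np.ndarray,
            ids: np.ndarray) -> "ClassifierAdapter":
        raise NotImplementedError

    def predict(self, features: np.ndarray, ids: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def fresh(self) -> "ClassifierAdapter":
        """An unfitted copy used for each fold-fit, so repetitions never
        share trained state.  Stateless mocks may return ``self``."""
        return copy.deepcopy(self)


class SklearnAdapter(ClassifierAdapter):
    """Wraps any scikit-learn style estimator exposing fit and predict.

    The estimator is cloned before every fit, so successive fold-fits are
    independent; predictions before the first fit violate the contract.
    """

    def __init__(self, estimator: Any, descriptor: str | None = None):
        for method in ("fit", "predict"):
            if not callable(getattr(estimator, method, None)):
                raise ClassifierContractError(
                    f"estimator {estimator!r} has no callable {method!r} method")
        self._template = estimator
        self._model: Any = None
        self.descriptor = descriptor or type(estimator).__name__

    def fit(self, features, labels, ids):
        try:
            self._model = _sk_clone(self._template)
        except TypeError:
            # not a scikit-learn estimator proper; a deep copy still gives
            # an independent unfitted instance
            self._model = copy.deepcopy(self._template)
        try:
            self._model.fit(features, labels)
        except Exception as exc:  # surface with adapter context
            raise ClassifierContractError(
                f"{self.descriptor}: fit failed: {exc}") from exc
        return self

    def predict(self, features, ids):
        if self._model is None:
            raise ClassifierContractError(
                f"{self.descriptor}: predict called before fit")
        pred = np.asarray(self._model.predict(features))
        if len(pred) != len(features):
            raise ClassifierContractError(
                f"{self.descriptor}: predict returned {len(pred)} labels "
                f"for {len(features)} rows")
        return pred

    def fresh(self):
        return SklearnAdapter(self._template, self.descriptor)


def wrap_estimator(estimator: Any, descriptor: str | None = None) -> SklearnAdapter:
    """Adapt a fit/predict estimator to the engine's classifier contract."""
    return SklearnAdapter(estimator, descriptor)


class PlantedErrorClassifier(ClassifierAdapter):
    """Mock whose errors are a fixed, training-independent set of ids.

    Given truth access (the id → label mapping of the dataset), it predicts
    the true label everywhere except on ``error_ids``, where it predicts a
    fixed wrong label.  On any held-out set H its error set is therefore
    exactly ``error_ids ∩ H``, which makes EC outcomes exact: identical
    planted sets give AEC = 1, an empty planted set gives a perfect
    classifier and all-undefined EC.
    """

    def __init__(self, error_ids: Iterable[int], truth: Mapping[int, Any] | Dataset):
        if isinstance(truth, Dataset):
            truth = truth.label_of()
        self.error_ids = frozenset(int(i) for i in error_ids)
        unknown = self.error_ids - set(truth)
        if unknown:
            raise InvalidInputError(
                f"error ids outside the dataset: {sorted(unknown)[:5]}")
        self._truth = dict(truth)
        self._classes = sorted(set(self._truth.values()), key=repr)
        self.descriptor = f"planted-error({len(self.error_ids)})"

    def _wrong_label(self, true_label):
        for c in self._classes:
            if c != true_label:
                return c
        return true_label  # single-class corner: no wrong label exists

    def fit(self, features, labels, ids):
        return self  # behaviour is independent of training data

    def predict(self, features, ids):
        out = []
        for sid in np.asarray(ids, dtype=int):
            true = self._truth[int(sid)]
            out.append(self._wrong_label(true) if int(sid) in self.error_ids else true)
        return np.asarray(out)

    def fresh(self):
        return self


def planted_error_classifier(error_ids: Iterable[int],
                             truth: Mapping[int, Any] | Dataset) -> PlantedErrorClassifier:
    return PlantedErrorClassifier(error_ids, truth)


class RandomErrorClassifier(ClassifierAdapter):
    """Mock that errs on a fresh independent random subset at every fit.

    Each call to :meth:`fit` draws ``round(error_rate · N)`` ids from the
    bound dataset's id universe (without replacement, from a private seeded
    stream) and errs exactly there at predict time.  This is the
    independence baseline: with rate p = k/N, two independently drawn error
    sets overlap like random k-subsets, so the expected pairwise EC is
    close to k / (2N − k).

    The seed stream is deliberately shared across :meth:`fresh` copies —
    a fresh *draw* per fit is the mock's contract.
    """

    def __init__(self, error_rate: float, truth: Mapping[int, Any] | Dataset,
                 seed: int = 0):
        if not 0.0 <= error_rate <= 1.0:
            raise InvalidInputError("error_rate must lie in [0, 1]")
        if isinstance(truth, Dataset):
            truth = truth.label_of()
        self.error_rate = float(error_rate)
        self._truth = dict(truth)
        self._universe = np.array(sorted(self._truth), dtype=int)
        self._classes = sorted(set(self._truth.values()), key=repr)
        self._rng = np.random.default_rng(seed)
        self._current: frozenset[int] = frozenset()
        self.descriptor = f"random-error({error_rate:g})"

    def fit(self, features, labels, ids):
        k = int(round(self.error_rate * len(self._universe)))
        drawn = self._rng.choice(self._universe, size=k, replace=False)
        self._current = frozenset(int(i) for i in drawn)
        return self

    def predict(self, features, ids):
        out = []
        for sid in np.asarray(ids, dtype=int):
            true = self._truth[int(sid)]
            if int(sid) in self._current:
                wrong = next((c for c in self._classes if c != true), true)
                out.append(wrong)
            else:
                out.append(true)
        return np.asarray(out)

    def fresh(self):
        return self  # shared stream: every fit anywhere advances it


def random_error_classifier(error_rate: float,
                            truth: Mapping[int, Any] | Dataset,
                            seed: int = 0) -> RandomErrorClassifier:
    return RandomErrorClassifier(error_rate, truth, seed)


def _preset_estimators(random_state: int | None):
    from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    return {
        "svm-rbf": lambda: SVC(kernel="rbf"),
        "rf-100": lambda: RandomForestClassifier(
            n_estimators=100, random_state=random_state),
        "logreg": lambda: LogisticRegression(max_iter=1000),
        "adaboost-dt": lambda: AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            random_state=random_state),
    }


#: names of the built-in reference learners addressable from the CLI
PRESET_NAMES = ("svm-rbf", "rf-100", "logreg", "adaboost-dt")


def get_preset(name: str, random_state: int | None = 0) -> SklearnAdapter:
    """Reference learners: RBF-kernel SVM, 100-tree random forest,
    logistic regression, AdaBoost on decision stumps.  Hyperparameter
    tuning is the caller's job; these are the library defaults."""
    presets = _preset_estimators(random_state)
    if name not in presets:
        raise InvalidInputError(
            f"unknown classifier preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    return SklearnAdapter(presets[name](), descriptor=name)
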