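"""EC-enhanced repeated K-Fold validation.

Two procedures produce the error sets the consistency statistic is
computed over:

* the **internal** approach — plain repeated K-Fold on one dataset; for
  each of the m repetitions the K disjoint fold-wise error sets are united
  into a single *master error set* over all N samples, giving n = m error
  sets.  Overall accuracy per repetition is pooled over all N held-out
  predictions, so OA ≡ 1 − |master set| / N exactly.

* the **external** approach — the user supplies (or splits off) an
  independent validation set; each of the m·K fold-trained models predicts
  the whole validation set, giving n = m·K error sets.  Two accuracy
  families are reported and named separately: the pooled fold-test OA per
  repetition, and each model's accuracy on the validation set.

Defaults follow the reference protocol: K = 5 folds, m = 500 repetitions,
with m set high for statistical reliability of the validation summary.
Folds are stratified by default (a flag restores plain K-Fold); every
repetition is reshuffled with a seed derived from the master seed, so runs
are reproducible end-to-end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from ._seeds import derive_seed
from .adapters import ClassifierAdapter
from .datasets import Dataset
from .ec_core import (DEFAULT_PAIRWISE_CAP, ECSummary, ErrorSet, PairwiseEC,
                      pairwise_ec, summarize_error_sets)
from .exceptions import ClassifierContractError, InvalidInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationConfig:
    """Protocol constants for one validation run.

    K and m default to the reference protocol (5-fold, 500 repetitions);
    ``validation_fraction`` is used by the external approach only when no
    explicit validation set is supplied.  ``pairwise_cap`` bounds how many
    error sets the full pairwise matrix is materialised for.
    """

    k: int = 5
    m: int = 500
    approach: Literal["internal", "external"] = "internal"
    stratified: bool = True
    master_seed: int = 0
    validation_fraction: float = 0.2
    pairwise_cap: int = DEFAULT_PAIRWISE_CAP

    def __post_init__(self) -> None:
        if self.k < 2:
            raise InvalidInputError("K must be at least 2")
        if self.m < 1:
            raise InvalidInputError("m must be at least 1")
        if self.approach not in ("internal", "external"):
            raise InvalidInputError("approach must be 'internal' or 'external'")
        if not 0.0 < self.validation_fraction < 1.0:
            raise InvalidInputError("validation_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "k": self.k, "m": self.m, "approach": self.approach,
            "stratified": self.stratified, "master_seed": self.master_seed,
            "validation_fraction": self.validation_fraction,
            "pairwise_cap": self.pairwise_cap,
        }


@dataclass
class RunResult:
    """Everything one validation run produced.

    ``oa_per_repetition`` is the pooled fold-test overall accuracy of each
    repetition; for the external approach ``val_accuracy_per_model`` holds
    each fold-trained model's accuracy on the validation set (length m·K),
    labelled separately because the two families measure different things.
    """

    config: ValidationConfig
    classifier: str
    n_samples: int
    oa_per_repetition: np.ndarray
    error_sets: list[ErrorSet]
    ec_summary: ECSummary
    repetition_seeds: list[int]
    val_accuracy_per_model: np.ndarray | None = None
    n_validation: int | None = None

    @property
    def mean_oa(self) -> float:
        return float(np.mean(self.oa_per_repetition))

    @property
    def sd_oa(self) -> float:
        if len(self.oa_per_repetition) < 2:
            return float("nan")
        return float(np.std(self.oa_per_repetition, ddof=1))

    @property
    def n_error_sets(self) -> int:
        return len(self.error_sets)

    def pairwise(self) -> PairwiseEC:
        """Materialise the full upper-triangular EC matrix on request."""
        return pairwise_ec(self.error_sets)

    def error_sets_frame(self):
        """Long-format membership table: repetition, model_index, sample_id."""
        import pandas as pd

        rows = [(e.repetition, e.model_index, sid)
                for e in self.error_sets for sid in sorted(e.members)]
        return pd.DataFrame(rows, columns=["repetition", "model_index", "sample_id"])

    def oa_frame(self):
        import pandas as pd

        frame = pd.DataFrame({
            "repetition": np.arange(len(self.oa_per_repetition)),
            "oa": self.oa_per_repetition,
        })
        return frame

    def to_json_dict(self) -> dict:
        from .io import _round_trip_float as _f  # deterministic formatting

        out = {
            "config": self.config.to_dict(),
            "classifier": self.classifier,
            "n_samples": self.n_samples,
            "mean_oa": _f(self.mean_oa),
            "sd_oa": _f(self.sd_oa),
            "aec": _f(self.ec_summary.aec),
            "aec_sd": _f(self.ec_summary.sd),
            "n_error_sets": self.n_error_sets,
            "n_pairs_defined": self.ec_summary.n_pairs_defined,
            "n_pairs_undefined": self.ec_summary.n_pairs_undefined,
            "repetition_seeds": self.repetition_seeds,
        }
        if self.val_accuracy_per_model is not None:
            out["mean_val_accuracy"] = _f(float(np.mean(self.val_accuracy_per_model)))
            out["n_validation"] = self.n_validation
        return out

    def summary(self) -> str:
        from .io import render_report

        return render_report(self).text()


def plan_folds(ds: Dataset, k: int, repetition_seed: int,
               stratified: bool = True) -> np.ndarray:
    """Assign each sample to one of K folds; returns fold indices (length N).

    Stratified assignment keeps per-class fold sizes within one sample of
    each other and requires every class to have at least K members.
    """
    if ds.n_samples < k:
        raise InvalidInputError(f"cannot split {ds.n_samples} samples into {k} folds")
    if stratified:
        classes, counts = np.unique(ds.labels, return_counts=True)
        small = classes[counts < k]
        if len(small):
            raise InvalidInputError(
                f"class {small[0]!r} has fewer than K={k} members; "
                "disable stratification or lower K")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=repetition_seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=repetition_seed)
    assignment = np.empty(ds.n_samples, dtype=int)
    for fold_idx, (_, test_idx) in enumerate(splitter.split(ds.features, ds.labels)):
        assignment[test_idx] = fold_idx
    return assignment


def split_validation(ds: Dataset, fraction: float, seed: int,
                     stratified: bool = True) -> tuple[Dataset, Dataset]:
    """Partition one dataset into (train, validation) parts.

    Deterministic given the seed; with stratification, class proportions
    are preserved within one sample per class.
    """
    if not 0.0 < fraction < 1.0:
        raise InvalidInputError("validation fraction must lie strictly in (0, 1)")
    n_val = int(round(fraction * ds.n_samples))
    if n_val < 1 or n_val >= ds.n_samples:
        raise InvalidInputError("validation split leaves an empty part")
    strat = ds.labels if stratified else None
    try:
        idx_train, idx_val = train_test_split(
            np.arange(ds.n_samples), test_size=n_val,
            random_state=seed, stratify=strat)
    except ValueError as exc:
        raise InvalidInputError(f"degenerate validation split: {exc}") from exc
    train, val = ds.subset(np.sort(idx_train)), ds.subset(np.sort(idx_val))
    if stratified and (len(train.classes) < 2 or len(val.classes) < 2):
        raise InvalidInputError("each split part needs at least 2 classes")
    return train, val


def _fit_predict_fold(clf: ClassifierAdapter, ds: Dataset,
                      train_idx: np.ndarray, rep: int, fold: int):
    model = clf.fresh()
    try:
        model.fit(ds.features[train_idx], ds.labels[train_idx], ds.ids[train_idx])
    except Exception as exc:
        raise ClassifierContractError(
            f"classifier failed to fit (repetition {rep}, fold {fold}): {exc}"
        ) from exc
    return model


def _check_dataset(ds: Dataset, cfg: ValidationConfig) -> None:
    if ds.n_samples < 2 * cfg.k:
        raise InvalidInputError(
            f"dataset of {ds.n_samples} samples is too small for K={cfg.k} "
            "(need at least 2K)")
    if len(ds.classes) < 2:
        raise InvalidInputError("dataset must contain at least 2 classes")


def run_internal(ds: Dataset, clf: ClassifierAdapter,
                 cfg: ValidationConfig | None = None) -> RunResult:
    """Internal approach: m repetitions of K-Fold, one master error set each.

    Every sample is held out exactly once per repetition, so the fold-wise
    error sets are disjoint and their union is the repetition's master
    error set with support = all N ids; OA is pooled over all N held-out
    predictions and equals 1 − |master| / N exactly.
    """
    cfg = cfg or ValidationConfig()
    if cfg.approach != "internal":
        raise InvalidInputError("run_internal requires approach='internal'")
    _check_dataset(ds, cfg)
    n = ds.n_samples
    error_sets: list[ErrorSet] = []
    oas = np.empty(cfg.m)
    rep_seeds = [derive_seed(cfg.master_seed, r) for r in range(cfg.m)]
    support = frozenset(ds.ids.tolist())
    for r in range(cfg.m):
        assignment = plan_folds(ds, cfg.k, rep_seeds[r], cfg.stratified)
        members: set[int] = set()
        for fold in range(cfg.k):
            test_mask = assignment == fold
            train_idx = np.flatnonzero(~test_mask)
            test_idx = np.flatnonzero(test_mask)
            model = _fit_predict_fold(clf, ds, train_idx, r, fold)
            pred = model.predict(ds.features[test_idx], ds.ids[test_idx])
            wrong = test_idx[np.asarray(pred) != ds.labels[test_idx]]
            fold_errors = set(ds.ids[wrong].tolist())
            assert not (members & fold_errors)  # folds partition the ids
            members |= fold_errors
        error_sets.append(ErrorSet(frozenset(members), repetition=r,
                                   model_index=0, support=support))
        oas[r] = 1.0 - len(members) / n
    summary = (summarize_error_sets(error_sets, cfg.pairwise_cap)
               if cfg.m >= 2 else ECSummary(float("nan"), float("nan"), 0, 0))
    return RunResult(config=cfg, classifier=clf.descriptor, n_samples=n,
                     oa_per_repetition=oas, error_sets=error_sets,
                     ec_summary=summary, repetition_seeds=rep_seeds)


def run_external(train: Dataset, val: Dataset, clf: ClassifierAdapter,
                 cfg: ValidationConfig | None = None) -> RunResult:
    """External approach: every fold-trained model predicts one hold-out
    validation set, yielding m·K error sets with support = the validation
    ids.

    ``oa_per_repetition`` holds the pooled fold-test OA of each repetition
    (computed on the training data's held-out folds);
    ``val_accuracy_per_model`` holds each model's validation-set accuracy.
    """
    cfg = cfg or ValidationConfig(approach="external")
    if cfg.approach != "external":
        raise InvalidInputError("run_external requires approach='external'")
    _check_dataset(train, cfg)
    if val.n_samples == 0:
        raise InvalidInputError("validation set is empty")
    if train.n_features != val.n_features:
        raise InvalidInputError("train and validation feature schemas differ")
    overlap = set(train.ids.tolist()) & set(val.ids.tolist())
    if overlap:
        raise InvalidInputError(
            f"train and validation ids overlap: {sorted(overlap)[:5]}")
    n_train = train.n_samples
    val_support = frozenset(val.ids.tolist())
    rep_seeds = [derive_seed(cfg.master_seed, r) for r in range(cfg.m)]
    error_sets: list[ErrorSet] = []
    oas = np.empty(cfg.m)
    val_acc = np.empty(cfg.m * cfg.k)
    for r in range(cfg.m):
        assignment = plan_folds(train, cfg.k, rep_seeds[r], cfg.stratified)
        n_fold_errors = 0
        for fold in range(cfg.k):
            test_mask = assignment == fold
            train_idx = np.flatnonzero(~test_mask)
            test_idx = np.flatnonzero(test_mask)
            model = _fit_predict_fold(clf, train, train_idx, r, fold)
            fold_pred = model.predict(train.features[test_idx], train.ids[test_idx])
            n_fold_errors += int(np.sum(np.asarray(fold_pred) != train.labels[test_idx]))
            val_pred = model.predict(val.features, val.ids)
            wrong = np.asarray(val_pred) != val.labels
            eset = ErrorSet(frozenset(val.ids[wrong].tolist()),
                            repetition=r, model_index=fold, support=val_support)
            error_sets.append(eset)
            val_acc[r * cfg.k + fold] = eset.accuracy()
        oas[r] = 1.0 - n_fold_errors / n_train
    summary = summarize_error_sets(error_sets, cfg.pairwise_cap)
    return RunResult(config=cfg, classifier=clf.descriptor, n_samples=n_train,
                     oa_per_repetition=oas, error_sets=error_sets,
                     ec_summary=summary, repetition_seeds=rep_seeds,
                     val_accuracy_per_model=val_acc, n_validation=val.n_samples)


def run(ds: Dataset, clf: ClassifierAdapter, cfg: ValidationConfig,
        val: Dataset | None = None) -> RunResult:
    """Dispatch on the configured approach, splitting off a validation set
    when the external approach is requested without one."""
    if cfg.approach == "internal":
        return run_internal(ds, clf, cfg)
    if val is None:
        split_seed = derive_seed(cfg.master_seed, 2**20)
        ds, val = split_validation(ds, cfg.validation_fraction, split_seed,
                                   cfg.stratified)
    return run_external(ds, val, clf, cfg)
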