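"""Model/Results facade over the validation engine.

``ErrorConsistencyValidation`` is constructed from a dataset and a
classifier, and ``fit()`` executes the configured validation procedure,
returning an ``ErrorConsistencyResults`` that carries the estimates (mean
OA, AEC), their spread (SDs over repetitions / model pairs), diagnostics
(undefined-pair counts, per-repetition accuracies, the raw error sets)
and a ``summary()`` table.  The down-sampling experiment and plotting
hang off these two objects.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Any, Sequence

import pandas as pd

from .adapters import ClassifierAdapter, SklearnAdapter, get_preset, wrap_estimator
from .datasets import Dataset
from .engine import RunResult, ValidationConfig, run
from .exceptions import InvalidInputError
from .sample_size import (DEFAULT_DRAWS, DEFAULT_POINT_M, DEFAULT_PROPORTIONS,
                          DownsamplingPoint, downsample_experiment, fit_trend)


class ErrorConsistencyValidation:
    """EC-enhanced repeated K-Fold validation of one classifier.

    Parameters
    ----------
    data
        The classification dataset (features, labels, ids).
    classifier
        A :class:`ClassifierAdapter`, a scikit-learn style estimator
        (wrapped automatically), or the name of a built-in preset
        (``svm-rbf``, ``rf-100``, ``logreg``, ``adaboost-dt``).
    k, m, approach, stratified, master_seed, validation_fraction
        Protocol constants; defaults are 5-fold, 500 repetitions,
        internal approach, stratified folds.
    validation_data
        Optional explicit hold-out set for the external approach.

    Examples
    --------
    >>> from ecvalidate import ErrorConsistencyValidation, SyntheticSpec
    >>> from ecvalidate.synthetic import generate_boundary_dataset
    >>> ds = generate_boundary_dataset(SyntheticSpec(seed=7))
    >>> res = ErrorConsistencyValidation(ds, "logreg", m=20, master_seed=7).fit()
    >>> print(res.summary().text())  # doctest: +SKIP
    """

    def __init__(self, data: Dataset, classifier: ClassifierAdapter | str | Any,
                 k: int = 5, m: int = 500,
                 approach: str = "internal", stratified: bool = True,
                 master_seed: int = 0, validation_fraction: float = 0.2,
                 validation_data: Dataset | None = None):
        self.data = data
        self.classifier = self._coerce(classifier)
        self.config = ValidationConfig(
            k=k, m=m, approach=approach, stratified=stratified,
            master_seed=master_seed, validation_fraction=validation_fraction)
        self.validation_data = validation_data
        if validation_data is not None and approach != "external":
            raise InvalidInputError(
                "validation_data is only meaningful with approach='external'")

    @staticmethod
    def _coerce(classifier) -> ClassifierAdapter:
        if isinstance(classifier, ClassifierAdapter):
            return classifier
        if isinstance(classifier, str):
            return get_preset(classifier)
        return wrap_estimator(classifier)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_column: str,
                       classifier, id_column: str | None = None,
                       **kwargs) -> "ErrorConsistencyValidation":
        ds = Dataset.from_dataframe(frame, label_column, id_column)
        return cls(ds, classifier, **kwargs)

    def fit(self) -> "ErrorConsistencyResults":
        """Execute the validation procedure."""
        result = run(self.data, self.classifier, self.config,
                     val=self.validation_data)
        return ErrorConsistencyResults(self, result)

    def downsampling_curve(self,
                           proportions: Sequence[float] = DEFAULT_PROPORTIONS,
                           draws_per_proportion: int = DEFAULT_DRAWS,
                           m: int = DEFAULT_POINT_M,
                           span: float = 0.6):
        """Effect-of-sample-size experiment on this model's dataset.

        Returns ``(points, trend)`` — the raw down-sampling points and
        their LOWESS trends.
        """
        cfg = replace(self.config, m=m)
        points = downsample_experiment(self.data, self.classifier, cfg,
                                       proportions, draws_per_proportion)
        trend = fit_trend(points, span=span) if len(points) >= 5 else None
        return points, trend


class ErrorConsistencyResults:
    """Results of one EC-enhanced validation run."""

    def __init__(self, model: ErrorConsistencyValidation, result: RunResult):
        self.model = model
        self._result = result

    # -- estimates ---------------------------------------------------------
    @property
    def mean_oa(self) -> float:
        """Mean overall accuracy across repetitions (fraction)."""
        return self._result.mean_oa

    @property
    def sd_oa(self) -> float:
        return self._result.sd_oa

    @property
    def aec(self) -> float:
        """Average error consistency over defined model pairs (fraction)."""
        return self._result.ec_summary.aec

    @property
    def aec_sd(self) -> float:
        return self._result.ec_summary.sd

    @property
    def ec_summary(self):
        return self._result.ec_summary

    @property
    def run_result(self) -> RunResult:
        """The underlying engine result (error sets, seeds, config echo)."""
        return self._result

    # -- diagnostics -------------------------------------------------------
    def pairwise(self):
        return self._result.pairwise()

    def oa_frame(self) -> pd.DataFrame:
        return self._result.oa_frame()

    def error_sets_frame(self) -> pd.DataFrame:
        return self._result.error_sets_frame()

    def summary(self):
        """Formatted report (percent cells in the ``OA (SD)/AEC (SD)`` style)."""
        from .io import render_report

        return render_report(self._result)

    def save(self, out_dir) -> dict:
        from .io import write_run_artifacts

        return write_run_artifacts(self._result, out_dir)

    def plot_ec_matrix(self, ax=None):
        from .plotting import plot_ec_matrix

        return plot_ec_matrix(self.pairwise(), ax=ax)

    def __repr__(self) -> str:
        from .io import format_oa_aec_cell

        cell = format_oa_aec_cell(self.mean_oa, self.sd_oa, self.aec, self.aec_sd)
        return (f"<ErrorConsistencyResults {self._result.classifier} "
                f"{self._result.config.approach} n={self._result.n_samples} "
                f"OA/AEC={cell}>")
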