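"""Synthetic classification data with controllable error geometry.

Two generators cover the two consistency regimes a developer meets in
practice:

* :func:`generate_boundary_dataset` — two isotropic unit-variance Gaussian
  classes whose centroids sit ``class_separation`` apart along the first
  feature axis.  Errors of a reasonable classifier concentrate on the same
  ambiguous samples near the midplane, so error consistency is high.  The
  isotropic-Gaussian choice gives an analytic anchor: for balanced classes
  the Bayes-optimal accuracy is Φ(separation / 2).

* :func:`generate_label_noise_dataset` — well-separated classes with a
  fraction of labels flipped uniformly at random.  Which samples a model
  gets wrong then depends on where the flipped labels landed relative to
  its fitted boundary, and the flipped ids are recorded as ground-truth
  metadata so tests can reason about where errors should occur.  The
  flipped ids are never visible to classifiers.

Defaults (400 samples, 5 features, separation 2.0, balanced classes) are
the reference conditions used throughout the test-bench: moderate overlap
where linear margin learners and randomised ensembles reach comparable
accuracy but measurably different error consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .datasets import Dataset
from .exceptions import InvalidInputError


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a generated dataset with known error geometry.

    class_balance is the fraction of samples in class 1; class_separation
    is the distance between the class centroids in feature units
    (features have unit variance, so it is also a z-distance);
    label_noise_rate is the fraction of labels flipped after generation.
    """

    n_samples: int = 400
    n_features: int = 5
    class_balance: float = 0.5
    class_separation: float = 2.0
    label_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 20:
            raise InvalidInputError("n_samples must be at least 20")
        if self.n_features < 1:
            raise InvalidInputError("n_features must be at least 1")
        if not 0.0 < self.class_balance < 1.0:
            raise InvalidInputError("class_balance must lie in (0, 1)")
        if self.class_separation < 0:
            raise InvalidInputError("class_separation must be non-negative")
        if not 0.0 <= self.label_noise_rate <= 1.0:
            raise InvalidInputError("label_noise_rate must lie in [0, 1]")


def bayes_accuracy(class_separation: float) -> float:
    """Bayes-optimal accuracy for balanced unit-variance Gaussian classes.

    The optimal rule thresholds the first feature at the midplane; each
    class errs with probability Φ(−separation/2), so accuracy is
    Φ(separation/2).
    """
    return float(norm.cdf(class_separation / 2.0))


def _gaussian_classes(spec: SyntheticSpec) -> Dataset:
    rng = np.random.default_rng(spec.seed)
    n1 = int(round(spec.n_samples * spec.class_balance))
    n0 = spec.n_samples - n1
    if n0 == 0 or n1 == 0:
        raise InvalidInputError("class_balance leaves one class empty")
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    features = rng.standard_normal((spec.n_samples, spec.n_features))
    features[:, 0] += np.where(labels == 1,
                               spec.class_separation / 2.0,
                               -spec.class_separation / 2.0)
    # shuffle so class blocks do not align with row order
    order = rng.permutation(spec.n_samples)
    features, labels = features[order], labels[order]
    ids = np.arange(spec.n_samples)
    return Dataset(features, labels, ids, meta={
        "spec": spec,
        "bayes_accuracy": bayes_accuracy(spec.class_separation),
    })


def generate_boundary_dataset(spec: SyntheticSpec) -> Dataset:
    """Two overlapping Gaussian classes; errors concentrate at the boundary."""
    if spec.label_noise_rate != 0.0:
        raise InvalidInputError(
            "boundary datasets are noise-free; use generate_label_noise_dataset")
    return _gaussian_classes(spec)


def generate_label_noise_dataset(spec: SyntheticSpec) -> Dataset:
    """Separable classes with a recorded fraction of labels flipped.

    The returned dataset's ``meta['flipped_ids']`` holds the ids whose
    labels were inverted; ``meta['clean_labels']`` the pre-flip labels.
    """
    if spec.label_noise_rate <= 0.0:
        raise InvalidInputError("label_noise_rate must be positive")
    ds = _gaussian_classes(spec)
    rng = np.random.default_rng(spec.seed + 1)
    n_flip = int(round(spec.label_noise_rate * spec.n_samples))
    flip_pos = rng.choice(spec.n_samples, size=n_flip, replace=False)
    clean = ds.labels.copy()
    noisy = clean.copy()
    noisy[flip_pos] = 1 - noisy[flip_pos]
    ds.labels = noisy
    ds.meta["clean_labels"] = clean
    ds.meta["flipped_ids"] = frozenset(ds.ids[flip_pos].tolist())
    return ds
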