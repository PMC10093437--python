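"""Fold planning, splitting, and the two validation approaches."""

import numpy as np
import pytest

from ecvalidate import (Dataset, InvalidInputError, SyntheticSpec,
                        ValidationConfig, generate_boundary_dataset,
                        is_undefined, plan_folds, planted_error_classifier,
                        run, run_external, run_internal, split_validation,
                        wrap_estimator)


def small_ds(n, n_classes=2, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % n_classes
    return Dataset(rng.standard_normal((n, 2)), labels, np.arange(n))


class TestPlanFolds:
    def test_equal_partition(self):
        ds = small_ds(10)
        assignment = plan_folds(ds, 5, repetition_seed=0)
        sizes = np.bincount(assignment, minlength=5)
        assert sizes.tolist() == [2, 2, 2, 2, 2]

    def test_balanced_remainder(self):
        # 11 samples over 5 folds: four folds of 2, one of 3
        ds = small_ds(11)
        sizes = sorted(np.bincount(plan_folds(ds, 5, 1), minlength=5))
        assert sizes == [2, 2, 2, 2, 3]

    def test_deterministic_given_seed(self, boundary_ds):
        a = plan_folds(boundary_ds, 5, 42)
        b = plan_folds(boundary_ds, 5, 42)
        assert np.array_equal(a, b)
        c = plan_folds(boundary_ds, 5, 43)
        assert not np.array_equal(a, c)

    def test_stratified_per_class_balance(self, boundary_ds):
        assignment = plan_folds(boundary_ds, 5, 7, stratified=True)
        for cls in boundary_ds.classes:
            sizes = np.bincount(assignment[boundary_ds.labels == cls], minlength=5)
            assert sizes.max() - sizes.min() <= 1

    def test_small_class_rejected_with_name(self):
        rng = np.random.default_rng(0)
        labels = np.array(["rare"] * 3 + ["common"] * 17)
        ds = Dataset(rng.standard_normal((20, 2)), labels, np.arange(20))
        with pytest.raises(InvalidInputError, match="rare"):
            plan_folds(ds, 5, 0, stratified=True)
        # unstratified planning tolerates the small class
        assert len(plan_folds(ds, 5, 0, stratified=False)) == 20


class TestSplitValidation:
    def test_sizes_and_determinism(self, boundary_ds):
        train, val = split_validation(boundary_ds, 0.2, seed=5)
        assert val.n_samples == 20 and train.n_samples == 80
        train2, val2 = split_validation(boundary_ds, 0.2, seed=5)
        assert np.array_equal(val.ids, val2.ids)
        assert not (set(train.ids) & set(val.ids))

    def test_class_proportions_preserved(self, boundary_ds):
        train, val = split_validation(boundary_ds, 0.3, seed=1, stratified=True)
        for part in (train, val):
            frac = np.mean(part.labels == boundary_ds.classes[0])
            base = np.mean(boundary_ds.labels == boundary_ds.classes[0])
            assert abs(frac - base) <= 1.5 / part.n_samples + 1e-9

    @pytest.mark.parametrize("fraction", [0.0, 1.0, 1.5])
    def test_degenerate_fraction_rejected(self, boundary_ds, fraction):
        with pytest.raises(InvalidInputError):
            split_validation(boundary_ds, fraction, seed=0)


class TestRunInternal:
    def test_planted_error_exactness(self, boundary_ds):
        """A training-independent planted error set forces AEC=1, SD=0 and
        OA = 1 − |S|/N in every repetition."""
        S = frozenset(range(10))
        clf = planted_error_classifier(S, boundary_ds)
        res = run_internal(boundary_ds, clf, ValidationConfig(m=20, master_seed=9))
        assert all(e.members == S for e in res.error_sets)
        assert res.ec_summary.aec == 1.0
        assert res.ec_summary.sd == 0.0
        assert np.all(res.oa_per_repetition == 0.9)

    def test_oa_identity_bitwise(self, boundary_ds):
        from sklearn.linear_model import LogisticRegression

        clf = wrap_estimator(LogisticRegression(max_iter=500))
        res = run_internal(boundary_ds, clf, ValidationConfig(m=5, master_seed=2))
        n = boundary_ds.n_samples
        for r, e in enumerate(res.error_sets):
            assert res.oa_per_repetition[r] == 1.0 - len(e.members) / n

    def test_master_set_support_and_counts(self, boundary_ds):
        clf = planted_error_classifier(frozenset({3, 50, 99}), boundary_ds)
        res = run_internal(boundary_ds, clf, ValidationConfig(m=3, master_seed=0))
        assert len(res.error_sets) == 3  # n = m for the internal approach
        for e in res.error_sets:
            assert e.support == frozenset(boundary_ds.ids.tolist())
            assert e.model_index == 0

    def test_perfect_classifier_undefined_everywhere(self, boundary_ds):
        clf = planted_error_classifier(frozenset(), boundary_ds)
        res = run_internal(boundary_ds, clf, ValidationConfig(m=5, master_seed=1))
        assert is_undefined(res.ec_summary.aec)
        assert res.ec_summary.n_pairs_defined == 0
        assert res.ec_summary.n_pairs_undefined == 10
        assert np.all(res.oa_per_repetition == 1.0)
        assert "NA" in res.summary()  # report renders cleanly

    def test_reproducible_end_to_end(self, boundary_ds):
        from sklearn.linear_model import LogisticRegression

        cfg = ValidationConfig(m=4, master_seed=123)
        make = lambda: wrap_estimator(LogisticRegression(max_iter=500))
        r1 = run_internal(boundary_ds, make(), cfg)
        r2 = run_internal(boundary_ds, make(), cfg)
        assert np.array_equal(r1.oa_per_repetition, r2.oa_per_repetition)
        assert [e.members for e in r1.error_sets] == [e.members for e in r2.error_sets]
        assert r1.repetition_seeds == r2.repetition_seeds
        assert r1.ec_summary == r2.ec_summary

    def test_training_insensitive_rule_gives_aec_one(self, boundary_ds):
        """A majority-class rule ignores training variation, so every
        repetition errs on the whole minority class: AEC = 1."""
        from sklearn.dummy import DummyClassifier

        clf = wrap_estimator(DummyClassifier(strategy="most_frequent"))
        res = run_internal(boundary_ds, clf, ValidationConfig(m=6, master_seed=3))
        assert res.ec_summary.aec == 1.0
        assert res.ec_summary.sd == 0.0

    def test_wrong_approach_rejected(self, boundary_ds):
        clf = planted_error_classifier(frozenset(), boundary_ds)
        with pytest.raises(InvalidInputError):
            run_internal(boundary_ds, clf,
                         ValidationConfig(approach="external", m=2))


class TestRunExternal:
    @pytest.fixture()
    def split(self, boundary_ds):
        return split_validation(boundary_ds, 0.2, seed=11)

    def test_set_counts_m_times_k(self, split):
        train, val = split
        clf = planted_error_classifier(frozenset({0}), {**train.label_of(),
                                                        **val.label_of()})
        cfg = ValidationConfig(approach="external", m=2, k=5, master_seed=1)
        res = run_external(train, val, clf, cfg)
        assert len(res.error_sets) == 10           # m·K error sets
        assert res.pairwise().n_pairs == 45        # n(n−1)/2
        assert res.val_accuracy_per_model.shape == (10,)
        assert len(res.oa_per_repetition) == 2     # fold-test OA per repetition

    def test_planted_validation_errors(self, split):
        train, val = split
        planted = frozenset(val.ids[:4].tolist())
        truth = {**train.label_of(), **val.label_of()}
        clf = planted_error_classifier(planted, truth)
        cfg = ValidationConfig(approach="external", m=3, master_seed=5)
        res = run_external(train, val, clf, cfg)
        assert all(e.members == planted for e in res.error_sets)
        assert res.ec_summary.aec == 1.0 and res.ec_summary.sd == 0.0
        # per-model validation accuracy = 1 − |members| / |support|
        assert np.all(res.val_accuracy_per_model
                      == 1.0 - len(planted) / val.n_samples)

    def test_support_is_validation_ids(self, split):
        train, val = split
        truth = {**train.label_of(), **val.label_of()}
        clf = planted_error_classifier(frozenset(), truth)
        res = run_external(train, val, clf,
                           ValidationConfig(approach="external", m=2))
        assert all(e.support == frozenset(val.ids.tolist())
                   for e in res.error_sets)

    def test_overlapping_ids_rejected(self, boundary_ds):
        clf = planted_error_classifier(frozenset(), boundary_ds)
        with pytest.raises(InvalidInputError, match="overlap"):
            run_external(boundary_ds, boundary_ds.subset([0, 1, 2]), clf,
                         ValidationConfig(approach="external", m=1))

    def test_empty_validation_rejected(self, split):
        train, val = split
        clf = planted_error_classifier(frozenset(), train)
        with pytest.raises(InvalidInputError):
            run_external(train, val.subset([]), clf,
                         ValidationConfig(approach="external", m=1))


def test_run_dispatch_splits_for_external(boundary_ds):
    from sklearn.linear_model import LogisticRegression

    cfg = ValidationConfig(approach="external", m=2, master_seed=8,
                           validation_fraction=0.25)
    res = run(boundary_ds, wrap_estimator(LogisticRegression(max_iter=500)), cfg)
    assert res.n_validation == 25
    assert len(res.error_sets) == 10


def test_config_validation():
    with pytest.raises(InvalidInputError):
        ValidationConfig(k=1)
    with pytest.raises(InvalidInputError):
        ValidationConfig(m=0)
    with pytest.raises(InvalidInputError):
        ValidationConfig(approach="sideways")
    cfg = ValidationConfig()
    assert (cfg.k, cfg.m, cfg.approach, cfg.stratified) == (5, 500, "internal", True)
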