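"""Brand-held-out schemes and split-half cross-validation."""

import numpy as np
import pytest

from spikedspec import (
    CVResult,
    PreprocessingPipeline,
    brand_holdout_splits,
    encode_classes,
    fit_pls,
    lda_threshold,
    select_model,
    split_half_cv,
)


def test_scheme_order_and_held_out_brands(small_dataset):
    schemes = brand_holdout_splits(small_dataset)
    assert [s.held_out for s in schemes] == ["G3", "G2", "G1", "T3", "T2", "T1"]
    assert schemes[0].test_combos == (("G3", "T1"), ("G3", "T2"), ("G3", "T3"))
    assert schemes[0].test_label == "G3T1G3T2G3T3"
    assert schemes[3].test_combos == (("G1", "T3"), ("G2", "T3"), ("G3", "T3"))


def test_full_design_split_sizes(full_dataset):
    for scheme in brand_holdout_splits(full_dataset):
        assert full_dataset.subset_by_combination(scheme.train_combos).n_samples == 342
        assert full_dataset.subset_by_combination(scheme.test_combos).n_samples == 171


def test_gin_wise_test_sets_partition_all_samples(small_dataset):
    schemes = brand_holdout_splits(small_dataset)[:3]
    ids = [set(small_dataset.subset_by_combination(s.test_combos).sample_ids)
           for s in schemes]
    assert ids[0] | ids[1] | ids[2] == set(small_dataset.sample_ids)
    assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])


def test_cv_groups_are_the_two_training_brands(small_dataset):
    scheme = brand_holdout_splits(small_dataset)[0]  # G3 held out
    assert scheme.cv_groups[0] == (("G1", "T1"), ("G1", "T2"), ("G1", "T3"))
    assert scheme.cv_groups[1] == (("G2", "T1"), ("G2", "T2"), ("G2", "T3"))


def test_every_training_sample_in_exactly_one_fold(small_dataset):
    scheme = brand_holdout_splits(small_dataset)[0]
    train = small_dataset.subset_by_combination(scheme.train_combos)
    a = set(train.subset_by_combination(scheme.cv_groups[0]).sample_ids)
    b = set(train.subset_by_combination(scheme.cv_groups[1]).sample_ids)
    assert a | b == set(train.sample_ids) and not a & b


def test_cv_grid_cell_matches_hand_rolled_two_fold_loop(small_dataset):
    scheme = brand_holdout_splits(small_dataset)[0]
    train = small_dataset.subset_by_combination(scheme.train_combos)
    cv = split_half_cv(train, scheme, candidates=("MC",), F_max=3, task="reg")

    folds = [train.subset_by_combination(g) for g in scheme.cv_groups]
    sse, n = 0.0, 0
    for fit_s, ev in ((folds[0], folds[1]), (folds[1], folds[0])):
        pipe = PreprocessingPipeline("MC").fit(fit_s.absorbance, fit_s.wavenumbers)
        m = fit_pls(pipe.transform(fit_s.absorbance, fit_s.wavenumbers),
                    fit_s.concentration, 2)
        pred = m.predict(pipe.transform(ev.absorbance, ev.wavenumbers))
        sse += np.sum((pred - ev.concentration) ** 2)
        n += ev.n_samples
    assert cv.errors[("MC", 2)] == pytest.approx(np.sqrt(sse / n), rel=1e-10)


def test_cv_da_grid_cell_matches_hand_rolled_loop(small_dataset):
    scheme = brand_holdout_splits(small_dataset)[0]
    train = small_dataset.subset_by_combination(scheme.train_combos)
    cv = split_half_cv(train, scheme, candidates=("MC",), F_max=2, task="da")

    folds = [train.subset_by_combination(g) for g in scheme.cv_groups]
    wrong, n = 0, 0
    for fit_s, ev in ((folds[0], folds[1]), (folds[1], folds[0])):
        pipe = PreprocessingPipeline("MC").fit(fit_s.absorbance, fit_s.wavenumbers)
        y_fit = encode_classes(fit_s.class_label)
        m = fit_pls(pipe.transform(fit_s.absorbance, fit_s.wavenumbers), y_fit, 2)
        thr = lda_threshold(m.predict(pipe.transform(fit_s.absorbance,
                                                     fit_s.wavenumbers)), y_fit)
        pred = m.predict(pipe.transform(ev.absorbance, ev.wavenumbers))
        wrong += np.sum((pred > thr.threshold)
                        != (encode_classes(ev.class_label) == 1.0))
        n += ev.n_samples
    assert cv.errors[("MC", 2)] == pytest.approx(wrong / n)


def test_f_max_clipped_with_warning(small_dataset):
    scheme = brand_holdout_splits(small_dataset)[0]
    train = small_dataset.subset_by_combination(scheme.train_combos)
    # each fold holds 30 samples -> at most 29 components
    with pytest.warns(UserWarning, match="clipped"):
        cv = split_half_cv(train, scheme, candidates=("MC",), F_max=40, task="reg")
    assert max(cv.F_grid) <= 29


def test_select_model_tie_breaking():
    cv = CVResult(task="da", candidates=("MC", "SNV+MC"), F_grid=(1, 2),
                  errors={("MC", 1): 0.2, ("MC", 2): 0.1,
                          ("SNV+MC", 1): 0.1, ("SNV+MC", 2): 0.1})
    # three cells tie at 0.1: smaller F wins, then candidate order
    assert select_model(cv) == ("SNV+MC", 1)
    cv.errors[("MC", 1)] = 0.1
    assert select_model(cv) == ("MC", 1)


def test_single_cell_grid(small_dataset):
    scheme = brand_holdout_splits(small_dataset)[0]
    train = small_dataset.subset_by_combination(scheme.train_combos)
    cv = split_half_cv(train, scheme, candidates=("MC",), F_max=1, task="reg")
    assert select_model(cv) == ("MC", 1)


def test_no_information_leak_from_other_fold(small_dataset):
    """A fold-B-only artifact must not change anything fitted on fold A."""
    scheme = brand_holdout_splits(small_dataset)[0]
    train = small_dataset.subset_by_combination(scheme.train_combos)
    fold_a = train.subset_by_combination(scheme.cv_groups[0])
    fold_b = train.subset_by_combination(scheme.cv_groups[1])

    pipe = PreprocessingPipeline("MC").fit(fold_a.absorbance, fold_a.wavenumbers)
    out_before = pipe.transform(fold_a.absorbance, fold_a.wavenumbers)

    fold_b.absorbance += 100.0  # gross artifact confined to fold B
    pipe2 = PreprocessingPipeline("MC").fit(fold_a.absorbance, fold_a.wavenumbers)
    out_after = pipe2.transform(fold_a.absorbance, fold_a.wavenumbers)
    np.testing.assert_array_equal(out_before, out_after)

    m_a = fit_pls(out_before, fold_a.concentration, 2)
    m_a2 = fit_pls(out_after, fold_a.concentration, 2)
    np.testing.assert_array_equal(m_a.b, m_a2.b)
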