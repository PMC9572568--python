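"""PLS-DA: dummy coding, LDA threshold, classification figures of merit."""

import numpy as np
import pytest

from spikedspec import (
    classification_fom,
    classify,
    decode_classes,
    encode_classes,
    fit_plsda,
    lda_threshold,
)
from spikedspec.errors import DegenerateInputError
from spikedspec.plsda import PLSDAModel, round_half_away


def test_encoding_convention():
    np.testing.assert_array_equal(encode_classes(["spiked", "pure"]), [1.0, 0.0])
    np.testing.assert_array_equal(encode_classes(["pure", "pure"]), [0.0, 0.0])


def test_encode_decode_round_trip():
    labels = np.array(["pure", "spiked", "spiked", "pure"], dtype=object)
    np.testing.assert_array_equal(decode_classes(encode_classes(labels)), labels)


def test_unknown_label_rejected():
    with pytest.raises(ValueError):
        encode_classes(["pure", "mystery"])


def test_threshold_is_midpoint_of_class_means():
    thr = lda_threshold([0.0, 1.0], [0.0, 1.0])
    assert thr.threshold == pytest.approx(0.5)
    thr = lda_threshold([0.1, 0.2, 0.8, 0.9], [0.0, 0.0, 1.0, 1.0])
    assert thr.threshold == pytest.approx(0.5)
    assert thr.mean_pure == pytest.approx(0.15)
    assert thr.mean_spiked == pytest.approx(0.85)


def test_threshold_matches_brute_force_scan_on_separable_data(rng):
    y_hat = np.concatenate([rng.normal(0.1, 0.05, 40), rng.normal(0.9, 0.05, 40)])
    dummy = np.concatenate([np.zeros(40), np.ones(40)])
    thr = lda_threshold(y_hat, dummy).threshold
    # exhaustive scan over candidate thresholds (midpoints of sorted values)
    cands = (np.sort(y_hat)[1:] + np.sort(y_hat)[:-1]) / 2
    errs = [np.sum((y_hat > c) != (dummy == 1)) for c in cands]
    best = cands[int(np.argmin(errs))]
    assert np.sum((y_hat > thr) != (dummy == 1)) == min(errs)
    assert np.sum((y_hat > best) != (dummy == 1)) == min(errs)


def test_single_class_threshold_degenerate():
    with pytest.raises(DegenerateInputError):
        lda_threshold([0.1, 0.2], [1.0, 1.0])


def test_proportional_priors_shift_toward_minority():
    y_hat = np.array([0.0] * 10 + [1.0] * 30)
    dummy = np.array([0.0] * 10 + [1.0] * 30)
    y_hat = y_hat + np.linspace(-0.05, 0.05, 40)  # some within-class spread
    eq = lda_threshold(y_hat, dummy, priors="equal").threshold
    prop = lda_threshold(y_hat, dummy, priors="proportional").threshold
    assert prop < eq  # more spiked samples -> lower threshold


def _separable_model(rng):
    n = 30
    X = rng.normal(size=(n, 8))
    labels = np.array(["pure"] * (n // 2) + ["spiked"] * (n // 2), dtype=object)
    X[labels == "spiked", 0] += 6.0
    return X, labels


def test_separable_training_data_classified_perfectly(rng):
    X, labels = _separable_model(rng)
    m = fit_plsda(X, labels, F=2)
    np.testing.assert_array_equal(classify(m, X), labels)


def test_tie_on_threshold_goes_to_pure():
    # hand-built univariate model: decision value equals the input exactly
    from spikedspec.pls import PLSModel
    from spikedspec.plsda import LDAThreshold

    one = np.ones((1, 1))
    pls = PLSModel(F=1, W=one, P=one, R=one, q=np.ones(1), b=np.ones(1),
                   T=one, x_mean=np.zeros(1), y_mean=0.0)
    m = PLSDAModel(pls=pls, threshold=LDAThreshold(0.5, 0.0, 1.0))
    labels = classify(m, np.array([[0.5], [0.5000001], [0.4999999]]))
    assert labels.tolist() == ["pure", "spiked", "pure"]


def test_classification_is_deterministic(rng):
    X, labels = _separable_model(rng)
    m = fit_plsda(X, labels, F=2)
    np.testing.assert_array_equal(classify(m, X), classify(m, X))


def test_label_flip_symmetry():
    # swapping the class coding mirrors the decision axis but yields the
    # same partition of samples
    y_hat = np.array([0.1, 0.4, 0.6, 0.9])
    dummy = np.array([0.0, 0.0, 1.0, 1.0])
    thr = lda_threshold(y_hat, dummy).threshold
    thr_flip = lda_threshold(-y_hat, 1.0 - dummy).threshold
    assert (y_hat > thr).tolist() == (-y_hat <= thr_flip).tolist()


def test_fom_all_correct():
    labels = np.array(["pure", "spiked"], dtype=object)
    fom = classification_fom(labels, labels)
    assert all(v == 100.0 for v in fom.values())


def test_fom_weighted_accuracy_and_average_ccr():
    # 111 spiked / 60 pure with known per-class hit counts
    true = np.array(["spiked"] * 111 + ["pure"] * 60, dtype=object)
    pred = true.copy()
    pred[:4] = "pure"     # 4 spiked missed -> sensitivity 96.40
    pred[111:115] = "spiked"  # 4 pure missed -> sensitivity 93.33
    fom = classification_fom(pred, true)
    assert round_half_away(fom["sensitivity_spiked"]) == 96.40
    assert round_half_away(fom["sensitivity_pure"]) == 93.33
    assert round_half_away(fom["accuracy"]) == 95.32
    assert fom["average_ccr"] == pytest.approx(
        (fom["sensitivity_spiked"] + fom["sensitivity_pure"]) / 2)


def test_fom_empty_rejected():
    with pytest.raises(ValueError):
        classification_fom(np.array([]), np.array([]))


def test_round_half_away():
    assert round_half_away(0.125) == 0.13
    assert round_half_away(-0.125) == -0.13
    assert round_half_away(95.321) == 95.32
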