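import numpy as np
import pytest

from emotiwin.models import (
    ClassifierSpec,
    feature_layer_fusion,
    fit_classifier,
    fit_reduction,
)
from emotiwin.nn import numerical_gradient_check


def test_contribution_threshold_is_strict():
    """Two standardized features with sample correlation 0.98 give PCA
    contribution rates exactly (0.99, 0.01); 0.01 is not > 0.01."""
    a = np.array([1.0, 1.0, -1.0, -1.0])
    e = np.array([1.0, -1.0, 1.0, -1.0])
    rho = 0.98
    b = rho * a + np.sqrt(1 - rho ** 2) * e
    X = np.column_stack([a, b])
    red = fit_reduction(X)
    np.testing.assert_allclose(sorted(red.contribution_rates, reverse=True),
                               [0.99, 0.01], atol=1e-12)
    assert red.n_components == 1


def test_isotropic_gaussian_keeps_all_components(rng):
    X = rng.normal(size=(100000, 3))
    red = fit_reduction(X)
    assert red.n_components == 3
    np.testing.assert_allclose(red.contribution_rates, [1 / 3] * 3, atol=0.02)
    assert red.contribution_rates.sum() == pytest.approx(1.0, abs=1e-9)


def test_zero_variance_feature_dropped(rng):
    X = rng.normal(size=(50, 3))
    X[:, 1] = 4.2
    with pytest.warns(UserWarning, match="zero-variance"):
        red = fit_reduction(X)
    assert list(red.kept_feature_idx) == [0, 2]
    assert red.transform(X).shape[0] == 50


def test_transform_inverse_identity_on_retained_subspace(rng):
    X = rng.normal(size=(200, 4)) @ rng.normal(size=(4, 4))
    red = fit_reduction(X, contribution_threshold=0.0)  # retain everything
    Z = red.transform(X)
    back = red.inverse_transform(Z)
    scaled = red.scaler.transform(X[:, red.kept_feature_idx])
    np.testing.assert_allclose(back, scaled, atol=1e-9)


def test_no_test_set_leakage(rng):
    Xtr = rng.normal(size=(100, 5))
    Xte = rng.normal(size=(20, 5))
    red = fit_reduction(Xtr)
    z1 = red.transform(Xte)
    _ = red.transform(Xte * 1e6 + 37.0)  # wild perturbation of 'test' data
    z2 = red.transform(Xte)
    np.testing.assert_array_equal(z1, z2)
    mu_before = red.scaler.mean_.copy()
    np.testing.assert_array_equal(red.scaler.mean_, mu_before)


def test_curves_reduction_shape(rng):
    X3 = rng.normal(size=(30, 12, 8))
    red = fit_reduction(X3)
    out = red.transform_curves(X3)
    assert out.shape == (30, red.n_components, 8)


def test_single_class_training_predicts_that_class(rng):
    X = rng.normal(size=(10, 4))
    model = fit_classifier(ClassifierSpec("knn"), X, ["bored"] * 10)
    assert set(model.predict(rng.normal(size=(5, 4)))) == {"bored"}


def test_knn_perfect_on_separated_blobs(rng):
    mu = {"interest": (0, 0), "happy": (20, 0), "confused": (0, 20), "bored": (20, 20)}
    Xtr, ytr, Xte, yte = [], [], [], []
    for lab, m in mu.items():
        Xtr += list(rng.normal(m, 0.5, (20, 2)))
        ytr += [lab] * 20
        Xte += list(rng.normal(m, 0.5, (10, 2)))
        yte += [lab] * 10
    model = fit_classifier(ClassifierSpec("knn"), np.array(Xtr), ytr)
    assert np.mean(model.predict(np.array(Xte)) == np.array(yte)) == 1.0
    scores = model.predict_scores(np.array(Xte))
    assert scores.shape == (40, 4)
    np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)


@pytest.mark.parametrize("family", ["random_forest", "tcn"])
def test_seeded_families_are_reproducible(family, rng):
    if family == "tcn":
        X = rng.normal(size=(40, 5, 8))
        spec = ClassifierSpec(family, seed=3, input_shape="curves",
                              params={"train": {"epochs": 5}})
    else:
        X = rng.normal(size=(40, 5))
        spec = ClassifierSpec(family, seed=3)
    y = list(np.tile(["interest", "happy", "confused", "bored"], 10))
    p1 = fit_classifier(spec, X, y).predict(X)
    p2 = fit_classifier(spec, X, y).predict(X)
    np.testing.assert_array_equal(p1, p2)


def test_shape_contract_enforced(rng):
    with pytest.raises(ValueError, match="curves"):
        ClassifierSpec("tcn", input_shape="flat")
    with pytest.raises(ValueError, match="flat"):
        ClassifierSpec("knn", input_shape="curves")
    spec = ClassifierSpec("tcn", input_shape="curves")
    with pytest.raises(ValueError, match="batch, channels, time"):
        fit_classifier(spec, rng.normal(size=(10, 4)),
                       ["interest", "happy"] * 5)


def test_cnn1d_accepts_flat_vectors(rng):
    X = rng.normal(size=(40, 6))
    y = list(np.tile(["interest", "happy", "confused", "bored"], 10))
    model = fit_classifier(ClassifierSpec("cnn1d", input_shape="flat",
                                          params={"train": {"epochs": 3}}), X, y)
    assert model.predict(X).shape == (40,)


def test_fusion_dimensions_and_oracle(rng):
    blocks = [rng.normal(size=(10, 16)), rng.normal(size=(10, 8)), rng.normal(size=(10, 3))]
    fused = feature_layer_fusion(blocks)
    assert fused.shape == (10, 27)
    np.testing.assert_array_equal(fused[:, :16], blocks[0])
    np.testing.assert_array_equal(fused[:, 16:24], blocks[1])
    np.testing.assert_array_equal(fused[:, 24:], blocks[2])
    one = feature_layer_fusion([blocks[0]])
    np.testing.assert_array_equal(one, blocks[0])
    c3 = feature_layer_fusion([rng.normal(size=(4, 5, 8)), rng.normal(size=(4, 2, 8))])
    assert c3.shape == (4, 7, 8)
    with pytest.raises(ValueError):
        feature_layer_fusion([rng.normal(size=(4, 5)), rng.normal(size=(5, 5))])


@pytest.mark.parametrize("family", ["cnn1d", "tcn", "lstm", "tcn_cnn", "lstm_cnn"])
def test_backprop_matches_finite_differences(family):
    assert numerical_gradient_check(family, seed=0) < 1e-4
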