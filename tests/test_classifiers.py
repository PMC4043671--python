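"""Linear SVM, EP-based GP classification and probability fusion."""

import json

import numpy as np
import pytest
from scipy.stats import norm

from thermocanopy.classifiers import (EPNotConvergedWarning, STRESSED,
                                      SVMModel, Standardizer, WELL_WATERED,
                                      fuse, gpc_predict, load_gpc, load_svm,
                                      save_gpc, save_svm, svm_predict,
                                      train_gpc_ep, train_linear_svm)


def quadrature_posterior_predictive(x_train, y_train, queries, sf2=1.0):
    """Exact oracle for 1-D inputs under the linear kernel: the latent GP
    is f(x) = w*x with scalar weight w ~ N(0, sf2), so the posterior
    predictive is a one-dimensional integral evaluated on a dense grid.
    Independent of the EP implementation."""
    w = np.linspace(-12, 12, 20001)
    log_post = norm.logpdf(w, 0.0, np.sqrt(sf2))
    for xi, yi in zip(x_train, y_train):
        log_post += norm.logcdf(yi * w * xi)
    post = np.exp(log_post - log_post.max())
    post /= np.trapezoid(post, w)
    return np.array([np.trapezoid(norm.cdf(w * q) * post, w)
                     for q in queries])


# --------------------------------------------------------------------------
# SVM
# --------------------------------------------------------------------------

def test_svm_symmetric_pair_boundary_at_origin():
    X = np.array([[-1.0], [1.0]])
    y = np.array([-1, 1])
    model = train_linear_svm(X, y)
    assert svm_predict(model, X).tolist() == [-1, 1]
    # decision value at the midpoint is zero -> tie resolves to +1
    assert svm_predict(model, np.array([[0.0]]))[0] == STRESSED


def test_svm_separable_set_has_zero_training_error(rng):
    X = np.vstack([rng.normal([-2, -2], 0.4, (20, 2)),
                   rng.normal([2, 2], 0.4, (20, 2))])
    y = np.repeat([-1, 1], 20)
    model = train_linear_svm(X, y)
    assert (svm_predict(model, X) == y).all()
    # margin check on the training points: all on the correct side
    scores = model.standardizer.transform(X) @ model.w + model.b
    assert (np.sign(scores) == y).all()


def test_svm_cannot_separate_xor():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
    y = np.array([-1, -1, 1, 1])
    model = train_linear_svm(X, y)
    assert (svm_predict(model, X) != y).any()


def test_svm_input_validation():
    with pytest.raises(ValueError, match="both classes"):
        train_linear_svm(np.array([[1.0], [2.0]]), np.array([1, 1]))
    with pytest.raises(ValueError, match="\\+1"):
        train_linear_svm(np.array([[1.0], [2.0]]), np.array([0, 1]))
    model = train_linear_svm(np.array([[-1.0], [1.0]]), np.array([-1, 1]))
    with pytest.raises(ValueError, match="features"):
        svm_predict(model, np.array([[1.0, 2.0]]))


# --------------------------------------------------------------------------
# GPC with EP
# --------------------------------------------------------------------------

def test_gpc_symmetric_pair_query_at_origin_is_exactly_half():
    model = train_gpc_ep(np.array([[-1.0], [1.0]]), np.array([-1, 1]),
                         standardize=False)
    p = gpc_predict(model, np.array([[0.0]]))
    assert p[0] == pytest.approx(0.5, abs=1e-12)


def test_gpc_matches_quadrature_oracle_within_002(rng):
    x = rng.normal(0, 1, 20)
    y = np.where(x + 0.3 * rng.normal(0, 1, 20) > 0, 1.0, -1.0)
    queries = np.linspace(-2.5, 2.5, 11)
    expected = quadrature_posterior_predictive(x, y, queries)
    model = train_gpc_ep(x[:, None], y, standardize=False)
    assert model.converged
    got = gpc_predict(model, queries[:, None])
    assert np.all(np.abs(got - expected) < 0.02)


def test_gpc_identical_inputs_approximates_class_fraction():
    """All training inputs at the same point with 7:3 labels; the
    predictive there must match the exact single-latent-site posterior."""
    X = np.ones((10, 1))
    y = np.array([1.0] * 7 + [-1.0] * 3)
    expected = quadrature_posterior_predictive(X.ravel(), y, [1.0])[0]
    model = train_gpc_ep(X, y, standardize=False)
    got = gpc_predict(model, np.array([[1.0]]))[0]
    assert got == pytest.approx(expected, abs=0.02)


def test_gpc_monotone_along_discriminant_ray(rng):
    X = np.vstack([rng.normal(-2, 0.5, (15, 1)), rng.normal(2, 0.5, (15, 1))])
    y = np.repeat([-1.0, 1.0], 15)
    model = train_gpc_ep(X, y, standardize=False)
    ray = np.linspace(-4, 4, 21)[:, None]
    p = gpc_predict(model, ray)
    assert np.all(np.diff(p) > 0)
    assert p[0] < 0.5 < p[-1]
    assert np.all((p > 0) & (p < 1))


def test_gpc_nonconvergence_is_flagged_not_silent(rng):
    X = np.array([[-1.0], [1.0]])
    with pytest.warns(EPNotConvergedWarning):
        model = train_gpc_ep(X, np.array([-1, 1]), max_sweeps=0,
                             standardize=False)
    assert not model.converged


def test_standardization_absorbs_feature_shift_and_scale(rng):
    X = rng.normal(0, 1, (30, 3))
    y = np.where(X[:, 0] + 0.2 * rng.normal(0, 1, 30) > 0, 1.0, -1.0)
    shift = np.array([100.0, -5.0, 3000.0])
    scale = np.array([0.01, 7.0, 250.0])
    Xq = rng.normal(0, 1, (8, 3))
    svm_a = train_linear_svm(X, y)
    svm_b = train_linear_svm(X * scale + shift, y)
    assert (svm_predict(svm_a, Xq)
            == svm_predict(svm_b, Xq * scale + shift)).all()
    gpc_a = train_gpc_ep(X, y)
    gpc_b = train_gpc_ep(X * scale + shift, y)
    assert np.allclose(gpc_predict(gpc_a, Xq),
                       gpc_predict(gpc_b, Xq * scale + shift), atol=1e-6)


# --------------------------------------------------------------------------
# Fusion
# --------------------------------------------------------------------------

def test_fuse_paper_examples():
    assert fuse(WELL_WATERED, 0.85) == STRESSED
    assert fuse(STRESSED, 0.10) == WELL_WATERED
    assert fuse(WELL_WATERED, 0.50) == WELL_WATERED
    assert fuse(STRESSED, 0.80) == STRESSED
    assert fuse(WELL_WATERED, 0.80) == WELL_WATERED  # strict inequality
    assert fuse(STRESSED, 0.20) == STRESSED          # strict inequality


def test_fuse_total_and_idempotent_on_probability_grid():
    grid = np.round(np.linspace(0, 1, 101), 10)
    for label in (WELL_WATERED, STRESSED):
        out = np.array([fuse(label, p) for p in grid])
        assert set(out) <= {WELL_WATERED, STRESSED}
        # overrides only in the open override regions
        for p, o in zip(grid, out):
            if label == WELL_WATERED:
                assert o == (STRESSED if p > 0.8 else WELL_WATERED)
            else:
                assert o == (WELL_WATERED if p < 0.2 else STRESSED)


def test_fuse_limits_reduce_to_single_classifiers(rng):
    labels = rng.choice([WELL_WATERED, STRESSED], 200)
    p = rng.uniform(0, 1, 200)
    # hi=1, lo=0: no override ever -> pure SVM
    assert (fuse(labels, p, hi=1.0, lo=0.0) == labels).all()
    # hi=lo=0.5: GPC thresholding (away from exact ties at 0.5)
    fused = fuse(labels, p, hi=0.5, lo=0.5)
    expected = np.where(p > 0.5, STRESSED, WELL_WATERED)
    off_tie = p != 0.5
    assert (fused[off_tie] == expected[off_tie]).all()


def test_fuse_validates_inputs():
    with pytest.raises(ValueError):
        fuse(STRESSED, 0.5, hi=0.2, lo=0.8)
    with pytest.raises(ValueError):
        fuse(STRESSED, 1.5)


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------

def test_model_json_round_trip(tmp_path, rng):
    X = np.vstack([rng.normal(-1, 0.5, (10, 2)), rng.normal(1, 0.5, (10, 2))])
    y = np.repeat([-1.0, 1.0], 10)
    Xq = rng.normal(0, 1, (6, 2))

    svm = train_linear_svm(X, y)
    save_svm(svm, tmp_path / "svm.json")
    svm2 = load_svm(tmp_path / "svm.json")
    assert (svm_predict(svm, Xq) == svm_predict(svm2, Xq)).all()

    gpc = train_gpc_ep(X, y)
    save_gpc(gpc, tmp_path / "gpc.json")
    gpc2 = load_gpc(tmp_path / "gpc.json")
    assert np.allclose(gpc_predict(gpc, Xq), gpc_predict(gpc2, Xq))
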