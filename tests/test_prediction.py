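"""Cross-dataset prediction, explained variance, significance."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import rkcca
from rkcca import (explained_variance, fit_cca, predict_heldout,
                   prediction_significance, regularized_pinv)


# ------------------------------------------------------ regularized_pinv

def test_pinv_invertible_diagonal():
    np.testing.assert_allclose(regularized_pinv(np.diag([2.0, 1.0])),
                               np.diag([0.5, 1.0]), atol=1e-12)


def test_pinv_rank_deficient_moore_penrose():
    w = np.array([[1.0, 0.0], [0.0, 0.0]])
    np.testing.assert_allclose(regularized_pinv(w), w, atol=1e-12)


def test_pinv_spectral_cutoff_truncates_small_singular_values():
    got = regularized_pinv(np.diag([10.0, 0.5]), cutoff=0.1)
    np.testing.assert_allclose(got, np.diag([0.1, 0.0]), atol=1e-12)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(0, 2 ** 31 - 1), st.integers(1, 6), st.integers(1, 6))
def test_pinv_matches_numpy_pinv_at_zero_cutoff(seed, n, p):
    w = np.random.default_rng(seed).normal(size=(n, p))
    np.testing.assert_allclose(regularized_pinv(w), np.linalg.pinv(w),
                               atol=1e-10)


def test_pinv_matches_svd_reconstruction_oracle(rng):
    w = rng.normal(size=(5, 3))
    cutoff = 0.4
    u, s, vt = np.linalg.svd(w, full_matrices=False)
    s_inv = np.array([1 / x if x >= cutoff * s[0] else 0.0 for x in s])
    oracle = vt.T @ np.diag(s_inv) @ u.T
    np.testing.assert_allclose(regularized_pinv(w, cutoff), oracle,
                               atol=1e-10)


def test_pinv_zero_matrix_and_bad_cutoff():
    with pytest.warns(UserWarning, match="all-zero"):
        out = regularized_pinv(np.zeros((3, 2)))
    np.testing.assert_array_equal(out, np.zeros((2, 3)))
    with pytest.raises(ValueError):
        regularized_pinv(np.eye(2), cutoff=1.0)
    with pytest.raises(ValueError):
        regularized_pinv(np.eye(2), cutoff=-0.1)


# ------------------------------------------------------- predict_heldout

def test_self_prediction_is_nearly_perfect(rng):
    x = rng.normal(size=(100, 3))
    y = x @ rng.normal(size=(3, 3)) + 0.01 * rng.normal(size=(100, 3))
    model = fit_cca([x, y], reg=0.0, n_components=3, kernel=None)
    res = predict_heldout(model, [x, y], cutoff=0.0)
    for c in res.corrs:
        assert np.all(c > 0.99)


def test_example_heldout_prediction_accuracy(fitted_model, example_halves):
    _, test, _ = example_halves
    res = fitted_model.predict([t.raw() for t in test])
    allc = np.concatenate(res.corrs)
    assert allc.shape == (9,)
    assert np.all(allc > 0.85) and np.all(allc < 0.97)


def test_permuted_rows_destroy_prediction(fitted_model, example_halves, rng):
    _, test, _ = example_halves
    shuffled = test[0].raw()[rng.permutation(test[0].n_samples)]
    res = fitted_model.predict([shuffled, test[1].raw()])
    assert np.mean(np.abs(res.corrs[0])) < 0.1


def test_prediction_corrs_shift_invariant(fitted_model, example_halves):
    _, test, _ = example_halves
    base = fitted_model.predict([t.raw() for t in test])
    shifted = [t.raw() + 100.0 * (i + 1) for i, t in enumerate(test)]
    moved = fitted_model.predict(shifted)
    for a, b in zip(base.corrs, moved.corrs):
        np.testing.assert_allclose(a, b, atol=1e-8)


def test_training_data_projection_reproduced_exactly(fitted_model,
                                                     example_halves):
    """With cutoff 0 and full-rank weights, the predicted matrix projects
    back onto the exact component-space coordinates."""
    train, _, _ = example_halves
    res = fitted_model.predict([t.raw() for t in train], cutoff=0.0)
    for i, (pred, w) in enumerate(zip(res.preds, fitted_model.weights_)):
        others = [train[j].values @ fitted_model.weights_[j]
                  for j in range(len(train)) if j != i]
        ubar = np.mean(others, axis=0)
        np.testing.assert_allclose(pred @ w, ubar, atol=1e-8)


def test_prediction_input_validation(fitted_model, example_halves, rng):
    _, test, _ = example_halves
    with pytest.raises(ValueError, match=">= 2"):
        predict_heldout(fitted_model, [test[0]])
    with pytest.raises(ValueError, match="features"):
        predict_heldout(fitted_model, [rng.normal(size=(10, 3)),
                                       rng.normal(size=(10, 5))])


# ----------------------------------------------------- explained_variance

def test_feature_equal_to_component_has_unit_ev(rng):
    x = rng.normal(size=(200, 2))
    y = np.hstack([x[:, :1], rng.normal(size=(200, 2))])
    model = fit_cca([x, y], reg=0.0, n_components=1, kernel=None)
    # make a feature identical to the model's own held-out component
    u = (y - y.mean(axis=0)) @ model.weights_[1]
    y2 = np.hstack([u[:, :1], y[:, 1:]])
    ev = explained_variance(model, [x, y2]).ev
    assert ev[1][0, 0] == pytest.approx(1.0, abs=1e-10)


def test_independent_feature_has_near_zero_ev(rng):
    # the shared signal lives only in column 0; column 1 is pure noise, so
    # on fresh data the component should explain ~none of its variance
    def draw():
        shared = rng.normal(size=(10_000, 1))
        return ([np.hstack([shared + 0.1 * rng.normal(size=(10_000, 1)),
                            rng.normal(size=(10_000, 1))]) for _ in range(2)])
    model = fit_cca(draw(), reg=0.0, n_components=1, kernel=None)
    ev = explained_variance(model, draw()).ev
    assert max(e[0, 1] for e in ev) < 0.01


def test_ev_equals_rank_one_residual_variance_oracle(fitted_model,
                                                     example_halves):
    _, test, _ = example_halves
    ev = explained_variance(fitted_model, test).ev
    # brute-force: R^2 of the best least-squares single-regressor fit
    for d, (block, w, e) in enumerate(zip(test, fitted_model.weights_, ev)):
        xc = block.raw() - fitted_model.means_[d]
        u = xc @ w
        for k in range(u.shape[1]):
            for f in range(xc.shape[1]):
                reg = np.column_stack([u[:, k], np.ones(len(u))])
                resid = xc[:, f] - reg @ np.linalg.lstsq(reg, xc[:, f],
                                                         rcond=None)[0]
                r2 = 1 - resid.var() / xc[:, f].var()
                assert e[k, f] == pytest.approx(r2, abs=1e-10)
    for e in ev:
        assert np.all(e >= 0) and np.all(e <= 1)


# ------------------------------------------------------------ significance

def test_zero_correlation_not_significant():
    res = prediction_significance([0.0, 0.0], n_test=50, alpha=0.05)
    np.testing.assert_allclose(res.p_values, 1.0)
    assert not res.significant_mask.any()
    assert res.q_threshold == 0.0


def test_fisher_z_closed_form_p_value():
    res = prediction_significance([0.5], n_test=100, alpha=0.05)
    z = np.arctanh(0.5) * np.sqrt(97)
    assert z == pytest.approx(5.41, abs=0.01)
    assert res.p_values[0] == pytest.approx(2 * norm.sf(z), rel=1e-12)
    assert res.p_values[0] == pytest.approx(6.3e-8, rel=0.05)


def test_bh_step_up_hand_worked_example():
    # p-values (0.01, 0.02, 0.04) vs thresholds (0.0167, 0.0333, 0.05):
    # the largest k with p_(k) <= k*alpha/m is 3, so all pass
    r = np.tanh(norm.isf(np.array([0.01, 0.02, 0.04]) / 2) / np.sqrt(97))
    res = prediction_significance(r, n_test=100, alpha=0.05)
    np.testing.assert_allclose(res.p_values, [0.01, 0.02, 0.04], atol=1e-12)
    assert res.significant_mask.all()
    assert res.q_threshold == pytest.approx(0.04)


def _bh_by_hand(p, alpha):
    m = len(p)
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = np.flatnonzero(p[order] <= thresh)
    mask = np.zeros(m, dtype=bool)
    if passed.size:
        mask[order[:passed[-1] + 1]] = True
    return mask


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1), st.integers(1, 40))
def test_bh_mask_equals_step_up_by_hand(seed, m):
    rng = np.random.default_rng(seed)
    r = np.clip(rng.normal(0, 0.3, size=m), -0.99, 0.99)
    res = prediction_significance(r, n_test=30, alpha=0.05)
    np.testing.assert_array_equal(res.significant_mask,
                                  _bh_by_hand(res.p_values, 0.05))
    if res.significant_mask.any():
        assert res.significant_mask.sum() == np.sum(
            res.p_values <= res.q_threshold)
    else:
        assert res.q_threshold == 0.0


def test_bh_mask_monotone_in_alpha(rng):
    r = rng.normal(0, 0.4, size=30).clip(-0.99, 0.99)
    lo = prediction_significance(r, n_test=40, alpha=0.01)
    hi = prediction_significance(r, n_test=40, alpha=0.10)
    assert np.all(hi.significant_mask[lo.significant_mask])


def test_perfect_correlation_clamped_and_validation():
    res = prediction_significance([1.0, -1.0], n_test=10)
    assert np.all(np.isfinite(res.p_values))
    assert res.significant_mask.all()
    with pytest.raises(ValueError):
        prediction_significance([0.5], n_test=3)
    with pytest.raises(ValueError):
        prediction_significance([0.5], n_test=10, alpha=0.0)
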