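"""Constrained weight estimation, ensembles, and the weighted index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wqsmix import (
    ValidationError,
    WQSFitConfig,
    WeightSet,
    auto_subset_size,
    bootstrap_ensemble,
    compute_wqs_index,
    fit_wqs_single,
    quantile_score_dataset,
    random_subset_ensemble,
)
from wqsmix.ensemble import EnsembleError

from conftest import make_dataset


def grid_oracle_two_components(Q, y, step=1e-4):
    """Brute-force 1-simplex grid search for c = 2 (independent oracle)."""
    best = (np.inf, None, None)
    for w1 in np.arange(0.0, 1.0 + step / 2, step):
        idx = w1 * Q[:, 0] + (1 - w1) * Q[:, 1]
        X = np.column_stack([np.ones(len(y)), idx])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        if coef[1] < 0:
            coef = np.array([y.mean(), 0.0])
        rss = float(((y - X @ coef) ** 2).sum())
        if rss < best[0]:
            best = (rss, w1, coef[1])
    return best


def test_noiseless_weight_recovery():
    """y = 2*(0.5 q1 + 0.3 q2 + 0.2 q3) recovered to 1e-3."""
    rng = np.random.default_rng(0)
    Q = rng.integers(0, 10, size=(200, 3)).astype(float)
    y = 2.0 * (Q @ np.array([0.5, 0.3, 0.2]))
    fit = fit_wqs_single(Q, y)
    assert fit.converged
    np.testing.assert_allclose(fit.weights[0], [0.5, 0.3, 0.2], atol=1e-3)
    assert abs(fit.b1 - 2.0) < 1e-3


def test_single_component_weight_is_one():
    rng = np.random.default_rng(1)
    Q = rng.integers(0, 10, size=(50, 1)).astype(float)
    y = 1.5 * Q[:, 0] + rng.normal(0, 0.1, 50)
    fit = fit_wqs_single(Q, y)
    assert fit.weights[0, 0] == pytest.approx(1.0)
    slope = np.polyfit(Q[:, 0], y, 1)[0]
    assert fit.b1 == pytest.approx(slope, abs=1e-4)


def test_pure_noise_slope_constrained_near_zero():
    rng = np.random.default_rng(2)
    Q = rng.integers(0, 10, size=(2000, 3)).astype(float)
    y = rng.normal(size=2000)
    fit = fit_wqs_single(Q, y, direction="positive")
    assert fit.b1 >= 0
    assert fit.b1 < 0.05


def test_negative_direction_constraint():
    rng = np.random.default_rng(3)
    Q = rng.integers(0, 10, size=(150, 3)).astype(float)
    y = -1.0 * (Q @ np.array([0.6, 0.3, 0.1])) + rng.normal(0, 0.2, 150)
    fit = fit_wqs_single(Q, y, direction="negative")
    assert fit.b1 <= 0
    assert fit.b1 == pytest.approx(-1.0, abs=0.1)
    np.testing.assert_allclose(fit.weights[0], [0.6, 0.3, 0.1], atol=0.05)


def test_stratified_fit_recovers_per_stratum_truth():
    rng = np.random.default_rng(4)
    n = 300
    Q = rng.integers(0, 10, size=(n, 3)).astype(float)
    strat = rng.integers(0, 2, size=n)
    w0, w1 = np.array([0.7, 0.2, 0.1]), np.array([0.1, 0.2, 0.7])
    idx = np.where(strat == 0, Q @ w0, Q @ w1)
    y = 1.0 + 0.5 * idx + 0.3 * idx * (strat == 1) + 0.4 * (strat == 1)
    fit = fit_wqs_single(Q, y, stratum=strat)
    np.testing.assert_allclose(fit.weights[0], w0, atol=1e-3)
    np.testing.assert_allclose(fit.weights[1], w1, atol=1e-3)
    assert fit.b1 == pytest.approx(0.5, abs=1e-3)
    assert fit.b12 == pytest.approx(0.3, abs=1e-3)


def test_constant_outcome_rejected():
    Q = np.tile(np.arange(10.0), (2, 1)).T
    with pytest.raises(ValidationError, match="constant"):
        fit_wqs_single(Q, np.ones(10))


def test_grid_oracle_equivalence():
    """Constrained fit matches the 1-simplex grid oracle for c = 2."""
    rng = np.random.default_rng(5)
    Q = rng.integers(0, 10, size=(120, 2)).astype(float)
    y = 1.2 * (0.35 * Q[:, 0] + 0.65 * Q[:, 1])
    _, w1_star, b_star = grid_oracle_two_components(Q, y)
    fit = fit_wqs_single(Q, y)
    assert fit.weights[0, 0] == pytest.approx(w1_star, abs=1e-3)
    assert fit.b1 == pytest.approx(b_star, abs=1e-3)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------


def _signal_dataset(n_subjects=60, c=4, seed=0):
    ds = make_dataset(n_subjects=n_subjects, n_occasions=1, n_components=c, seed=seed)
    qm = quantile_score_dataset(ds, 4)
    rng = np.random.default_rng(seed + 100)
    w = np.zeros(c)
    w[:2] = [0.7, 0.3]
    ds.data["y"] = qm.scores @ w + rng.normal(0, 0.3, ds.n_rows)
    return ds, quantile_score_dataset(ds, 4)


def test_bootstrap_ensemble_counts_and_simplex():
    ds, qm = _signal_dataset()
    cfg = WQSFitConfig(b=25, ensemble_kind="bootstrap", seed=0)
    ws = bootstrap_ensemble(ds, qm, cfg)
    assert np.all(ws.selection_counts == len(ws.per_fit_weights))
    assert np.all(ws.weights >= 0)
    np.testing.assert_allclose(ws.weights.sum(axis=1), 1.0, atol=1e-8)
    # signal components dominate
    assert set(np.argsort(ws.weights[0])[-2:]) == {0, 1}


def test_bootstrap_b1_close_to_single_fit():
    ds, qm = _signal_dataset()
    cfg = WQSFitConfig(b=1, ensemble_kind="bootstrap", seed=3)
    ws = bootstrap_ensemble(ds, qm, cfg)
    assert len(ws.per_fit_weights) == 1
    np.testing.assert_allclose(ws.weights.sum(axis=1), 1.0, atol=1e-8)


def test_mean_on_simplex():
    """Averaging one-hot weight vectors lands at the centroid."""
    from wqsmix.ensemble import _average_weights

    per = [np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])]
    mean, counts = _average_weights(per, 1, 2)
    np.testing.assert_allclose(mean, [[0.5, 0.5]])
    np.testing.assert_array_equal(counts, [[2, 2]])


@pytest.mark.parametrize("c,n_strata,expected", [(30, 2, 10), (30, 1, 5), (9, 1, 3), (16, 2, 8)])
def test_auto_subset_size(c, n_strata, expected):
    assert auto_subset_size(c, n_strata) == expected


def test_random_subset_covers_all_components():
    ds, qm = _signal_dataset(c=6)
    cfg = WQSFitConfig(b=40, ensemble_kind="random_subset", subset_size=3, seed=1)
    ws = random_subset_ensemble(ds, qm, cfg)
    assert np.all(ws.selection_counts >= 1)
    np.testing.assert_allclose(ws.weights.sum(axis=1), 1.0, atol=1e-8)


def test_random_subset_insufficient_coverage_errors():
    ds, qm = _signal_dataset(c=6)
    cfg = WQSFitConfig(b=1, ensemble_kind="random_subset", subset_size=2, seed=1)
    with pytest.raises(EnsembleError, match="never sampled"):
        random_subset_ensemble(ds, qm, cfg)


def test_random_subset_size_must_be_less_than_c():
    ds, qm = _signal_dataset(c=4)
    cfg = WQSFitConfig(b=5, ensemble_kind="random_subset", subset_size=4, seed=1)
    with pytest.raises(ValidationError, match="subset_size"):
        random_subset_ensemble(ds, qm, cfg)


def test_singleton_subsets_give_interior_weights():
    """With subsets of size 1 each fit puts weight 1 on its component;
    averaging + renormalization yields the enumeration oracle's answer."""
    rng = np.random.default_rng(8)
    ds = make_dataset(n_subjects=80, n_occasions=1, n_components=2, seed=8)
    qm = quantile_score_dataset(ds, 4)
    ds.data["y"] = qm.scores @ np.array([0.8, 0.2]) + rng.normal(0, 0.1, 80)
    qm = quantile_score_dataset(ds, 4)
    cfg = WQSFitConfig(b=60, ensemble_kind="random_subset", subset_size=1, seed=2)
    ws = random_subset_ensemble(ds, qm, cfg)
    for fw in ws.per_fit_weights:
        sampled = ~np.isnan(fw[0])
        assert fw[0][sampled] == pytest.approx(1.0)
    # enumeration oracle: every singleton fit returns weight 1, so the
    # average over inclusions is 1 for each component and renormalization
    # yields exactly (0.5, 0.5)
    np.testing.assert_allclose(ws.weights[0], [0.5, 0.5], atol=1e-8)


def test_random_subset_agrees_with_bootstrap_on_easy_data():
    """subset_size = c-1 with many replicates lands near bootstrap weights."""
    ds, qm = _signal_dataset(n_subjects=100, c=4, seed=5)
    ws_b = bootstrap_ensemble(ds, qm, WQSFitConfig(b=40, ensemble_kind="bootstrap", seed=3))
    ws_r = random_subset_ensemble(
        ds, qm, WQSFitConfig(b=80, ensemble_kind="random_subset", subset_size=3, seed=3)
    )
    assert np.abs(ws_b.weights - ws_r.weights).max() < 0.15


# ---------------------------------------------------------------------------
# the index
# ---------------------------------------------------------------------------


def _weightset(W, names):
    W = np.atleast_2d(W)
    return WeightSet(
        weights=W,
        direction="positive",
        component_names=names,
        selection_counts=np.ones_like(W, dtype=int),
    )


def test_index_uniform_weights_constant_scores():
    from wqsmix.quantiles import QuantiledMixture

    qm = QuantiledMixture(
        scores=np.full((5, 4), 3), nq=10, component_names=list("abcd"),
        cut_points=np.tile(np.arange(9.0), (4, 1)),
    )
    ws = _weightset(np.full(4, 0.25), list("abcd"))
    np.testing.assert_allclose(compute_wqs_index(qm, ws), 3.0)


def test_index_hand_dot_product():
    from wqsmix.quantiles import QuantiledMixture

    qm = QuantiledMixture(
        scores=np.array([[1, 2, 3]]), nq=10, component_names=list("abc"),
        cut_points=np.tile(np.arange(9.0), (3, 1)),
    )
    ws = _weightset([0.5, 0.3, 0.2], list("abc"))
    assert compute_wqs_index(qm, ws)[0] == pytest.approx(1.7)


def test_index_one_hot_selects_column():
    from wqsmix.quantiles import QuantiledMixture

    rng = np.random.default_rng(0)
    scores = rng.integers(0, 10, size=(20, 3))
    qm = QuantiledMixture(
        scores=scores, nq=10, component_names=list("abc"),
        cut_points=np.tile(np.arange(9.0), (3, 1)),
    )
    ws = _weightset([0.0, 1.0, 0.0], list("abc"))
    np.testing.assert_allclose(compute_wqs_index(qm, ws), scores[:, 1])


def test_index_stratified_and_errors():
    from wqsmix.quantiles import QuantiledMixture

    qm = QuantiledMixture(
        scores=np.array([[2, 4], [2, 4]]), nq=10, component_names=list("ab"),
        cut_points=np.tile(np.arange(9.0), (2, 1)),
    )
    ws = _weightset(np.array([[1.0, 0.0], [0.0, 1.0]]), list("ab"))
    idx = compute_wqs_index(qm, ws, stratum=np.array([0, 1]))
    np.testing.assert_allclose(idx, [2.0, 4.0])
    with pytest.raises(ValidationError, match="stratum"):
        compute_wqs_index(qm, ws, stratum=np.array([0, 2]))
    with pytest.raises(ValidationError, match="stratum"):
        compute_wqs_index(qm, ws)


@settings(max_examples=25, deadline=None)
@given(
    c=st.integers(min_value=2, max_value=5),
    seed=st.integers(min_value=0, max_value=2**16),
    stratified=st.booleans(),
)
def test_simplex_invariant_property(c, seed, stratified):
    """Every fit returns nonnegative per-stratum weights summing to 1."""
    rng = np.random.default_rng(seed)
    n = 60
    Q = rng.integers(0, 4, size=(n, c)).astype(float)
    y = rng.normal(size=n) + Q @ rng.dirichlet(np.ones(c))
    strat = rng.integers(0, 2, size=n) if stratified else None
    if strat is not None and (strat.sum() < 3 or (1 - strat).sum() < 3):
        strat = None
    fit = fit_wqs_single(Q, y, stratum=strat)
    assert np.all(fit.weights >= 0)
    np.testing.assert_allclose(fit.weights.sum(axis=1), 1.0, atol=1e-8)
    if strat is not None:
        assert fit.slopes.min() >= 0  # positive direction
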