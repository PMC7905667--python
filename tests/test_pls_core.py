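import numpy as np
import pytest

from pleiopls import (
    FitConfig,
    PenaltyParams,
    cross_products,
    deflate,
    fit,
    pool_studies,
    predict,
    selected_features,
    solve_joint_component,
    solve_single_component,
    standardize_within_study,
)
from pleiopls.errors import DegenerateSolutionError, IdentifierError, ParameterError
from .conftest import make_dataset, make_groups


def test_cross_products_values(toy_dataset):
    std = standardize_within_study(toy_dataset)
    Zs = cross_products(std)
    assert Zs.M == 2 and Zs.standardized_input
    for Z, (_, rows) in zip(Zs.matrices, std.obs_sets.blocks()):
        np.testing.assert_allclose(Z, std.X[rows].T @ std.Y[rows], atol=1e-12)


def test_unpenalized_component_is_normalized_cross_product():
    rng = np.random.default_rng(0)
    groups = make_groups([3, 3])
    Zs = [rng.normal(size=(6, 1)), rng.normal(size=(6, 1))]
    U, V = solve_joint_component(Zs, PenaltyParams(lam=0.0), groups)
    for m, Z in enumerate(Zs):
        np.testing.assert_allclose(U[:, m], Z[:, 0] / np.linalg.norm(Z), atol=1e-12)
        assert np.linalg.norm(U[:, m]) == pytest.approx(1.0)
    np.testing.assert_allclose(V, 1.0)


def test_group_count_surrogate_controls_selection():
    rng = np.random.default_rng(1)
    groups = make_groups([4, 4, 4, 4])
    Zs = [rng.normal(size=(16, 1)) for _ in range(2)]
    for g in (1, 2, 3):
        U, _ = solve_joint_component(
            Zs, PenaltyParams(alpha=0.5, n_groups_kept=g), groups
        )
        alive = {int(groups.index[i]) for i in np.flatnonzero(np.any(U != 0, axis=1))}
        assert len(alive) == g


def test_degenerate_penalty_raises():
    rng = np.random.default_rng(2)
    groups = make_groups([3, 3])
    Zs = [rng.normal(size=(6, 1))]
    with pytest.raises(DegenerateSolutionError):
        solve_joint_component(Zs, PenaltyParams(alpha=0.5, n_groups_kept=0), groups)


def test_single_component_spls_ignores_groups():
    rng = np.random.default_rng(3)
    groups = make_groups([2, 4])
    Z = rng.normal(size=(6, 1))
    u_a, _ = solve_single_component(Z, PenaltyParams(lam=0.8, alpha=0.2), groups, method="spls")
    u_b, _ = solve_single_component(Z, PenaltyParams(lam=0.8, alpha=1.0), groups, method="sgpls")
    np.testing.assert_allclose(u_a, u_b, atol=1e-12)


def test_multivariate_alternation_converges():
    rng = np.random.default_rng(4)
    groups = make_groups([3, 3, 2])
    Zs = [rng.normal(size=(8, 3)) for _ in range(2)]
    cfg = FitConfig(params=PenaltyParams(lam=0.3, alpha=0.5), max_alternations=500)
    U, V, info = solve_joint_component(
        Zs, PenaltyParams(lam=0.3, alpha=0.5), groups, config=cfg, return_info=True
    )
    obj = info["objective"]
    assert len(obj) >= 1 and np.isfinite(obj).all()
    assert info["alternations"] < cfg.max_alternations  # stopped by the tolerance
    # near a fixed point the objective has settled
    assert abs(obj[-1] - obj[-2]) <= 1e-6 * max(1.0, abs(obj[-2]))
    np.testing.assert_allclose(np.linalg.norm(U, axis=0), 1.0, atol=1e-9)
    np.testing.assert_allclose(np.linalg.norm(V, axis=0), 1.0, atol=1e-9)


def test_deflate_orthogonalizes_scores():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(20, 6))
    Y = rng.normal(size=(20, 1))
    u = rng.normal(size=6)
    t = X @ u
    X2, Y2 = deflate(X, Y, u)
    assert abs(t @ (X2 @ u)) < 1e-9
    assert abs(t @ Y2[:, 0]) < 1e-9
    # zero loading is an identity deflation
    X3, Y3 = deflate(X, Y, np.zeros(6))
    np.testing.assert_allclose(X3, X)
    np.testing.assert_allclose(Y3, Y)


def test_fit_requires_pooling_for_single_study_methods(toy_dataset):
    with pytest.raises(ParameterError):
        fit(toy_dataset, FitConfig(method="sgpls"))
    fit(pool_studies(toy_dataset), FitConfig(method="sgpls"))


def test_fit_is_deterministic(toy_dataset):
    cfg = FitConfig(params=PenaltyParams(alpha=0.5, n_groups_kept=2), n_components=2)
    m1 = fit(toy_dataset, cfg)
    m2 = fit(toy_dataset, cfg)
    for (U1, V1), (U2, V2) in zip(m1.loadings.components, m2.loadings.components):
        np.testing.assert_array_equal(U1, U2)
        np.testing.assert_array_equal(V1, V2)


def test_successive_scores_orthogonal_within_study():
    d = make_dataset(n_per_study=(30, 25), group_sizes=(3, 3, 3), seed=6, signal_vars=(0, 4))
    model = fit(d, FitConfig(n_components=3))
    std = standardize_within_study(d)
    for label, rows in std.obs_sets.blocks():
        m = model.study_labels.index(label)
        Xc = std.X[rows].copy()
        scores = []
        for (U, _), reg in zip(model.loadings.components, model.regression):
            t = Xc @ U[:, m]
            scores.append(t)
            Xc = Xc - np.outer(t, reg[label]["x_loading"])
        for a in range(len(scores)):
            for b in range(a + 1, len(scores)):
                assert abs(scores[a] @ scores[b]) < 1e-8


def test_fit_predict_recovers_linear_signal():
    d = make_dataset(
        n_per_study=(60, 60), group_sizes=(4, 4, 4), seed=7, signal_vars=(0, 1)
    )
    train = d.subset_rows(np.arange(0, d.n, 2))
    test = d.subset_rows(np.arange(1, d.n, 2))
    model = fit(train, FitConfig(n_components=3))
    for label, rows in test.obs_sets.blocks():
        y_pred, labels = predict(model, test.X[rows], label)
        assert labels is None
        resid = test.Y[rows, 0] - y_pred[:, 0]
        r2 = 1 - resid.var() / test.Y[rows, 0].var()
        assert r2 > 0.9


def test_predict_binary_labels(binary_dataset):
    model = fit(binary_dataset, FitConfig())
    assert model.y_is_binary
    rows = binary_dataset.study_rows("s1")
    y_pred, labels = predict(model, binary_dataset.X[rows], "s1")
    assert set(np.unique(labels)).issubset({0, 1})
    # in-sample fit with a strong effect beats the prior
    err = np.mean(labels != binary_dataset.Y[rows, 0])
    prior = min(np.mean(binary_dataset.Y[rows, 0]), 1 - np.mean(binary_dataset.Y[rows, 0]))
    assert err <= prior


def test_predict_input_validation(toy_dataset):
    model = fit(toy_dataset, FitConfig())
    with pytest.raises(IdentifierError):
        predict(model, np.zeros((3, toy_dataset.p)), "unknown")
    with pytest.raises(IdentifierError):
        predict(model, np.zeros((3, toy_dataset.p + 1)), "s1")


def test_selected_features_union_over_components():
    d = make_dataset(n_per_study=(40, 40), group_sizes=(3, 3, 3), seed=8, signal_vars=(0, 3))
    cfg = FitConfig(params=PenaltyParams(alpha=0.5, n_groups_kept=1), n_components=2)
    model = fit(d, cfg)
    sel = selected_features(model)
    expected = set()
    for U, _ in model.loadings.components:
        expected |= {d.variable_ids[j] for j in np.flatnonzero(np.any(U != 0, axis=1))}
    assert set(sel.variables) == expected
    member_groups = {d.var_groups.labels[d.var_groups.index[d.variable_ids.index(v)]] for v in sel.variables}
    assert set(sel.groups) == member_groups
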