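import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleiopls import (
    GroupNormProfile,
    PenaltyParams,
    group_norms,
    lambda_for_group_count,
    resolve_lambda,
    soft_threshold_groups,
    soft_threshold_rows,
    sparse_group_prox,
)
from pleiopls.errors import ParameterError, TieError
from pleiopls.penalties import group_critical_lambdas
from .conftest import make_groups


def _surviving_groups(U, groups):
    return int((group_norms(U, groups).norms > 0).sum())


def test_soft_threshold_rows_formula():
    U0 = np.array([[3.0, 4.0], [0.3, 0.4], [0.0, 0.0]])
    out = soft_threshold_rows(U0, 1.0)
    np.testing.assert_allclose(out[0], U0[0] * (1 - 1 / 5.0))
    np.testing.assert_allclose(out[1], 0.0)  # norm 0.5 <= 1
    np.testing.assert_allclose(out[2], 0.0)
    with pytest.raises(ParameterError):
        soft_threshold_rows(U0, -0.5)


def test_soft_threshold_groups_weighted():
    groups = make_groups([2, 1])
    U1 = np.array([[3.0], [4.0], [2.0]])
    out = soft_threshold_groups(U1, groups, 1.0)
    np.testing.assert_allclose(out[:2, 0], U1[:2, 0] * (1 - 1 / 5.0))
    np.testing.assert_allclose(out[2, 0], 1.0)
    outw = soft_threshold_groups(U1, groups, 1.0, size_weighted=True)
    np.testing.assert_allclose(outw[:2, 0], U1[:2, 0] * (1 - np.sqrt(2) / 5.0))


def test_prox_zeroes_rows_jointly():
    rng = np.random.default_rng(3)
    groups = make_groups([3, 4, 3])
    U0 = rng.normal(size=(10, 2))
    out = sparse_group_prox(U0, PenaltyParams(lam=1.5, alpha=0.7), groups)
    row_norms = np.linalg.norm(out, axis=1)
    for i in range(10):
        # a row is zero in every study or nonzero as a whole
        assert (out[i] == 0).all() or row_norms[i] > 0


def test_lambda_for_group_count_midpoint_rule():
    profile = GroupNormProfile(np.array([5.0, 4.0, 3.0, 2.0, 1.0]), np.ones(5))
    lam = lambda_for_group_count(profile, 2, alpha=0.5)
    assert lam == pytest.approx(2 * 3.5 / 0.5)
    # applying the group threshold keeps exactly 2 groups
    t = lam * (1 - 0.5) / 2
    assert int((profile.norms > t).sum()) == 2
    # boundary counts
    lam0 = lambda_for_group_count(profile, 0, alpha=0.5)
    assert int((profile.norms > lam0 * 0.25) .sum()) == 0
    lam5 = lambda_for_group_count(profile, 5, alpha=0.5)
    assert int((profile.norms > lam5 * 0.25).sum()) == 5


def test_lambda_for_group_count_ties_and_bounds():
    profile = GroupNormProfile(np.array([4.0, 3.0, 3.0, 1.0]), np.ones(4))
    with pytest.raises(TieError) as err:
        lambda_for_group_count(profile, 2, alpha=0.5)
    assert list(err.value.tied_groups) == [1, 2]
    with pytest.raises(ParameterError):
        lambda_for_group_count(profile, 7, alpha=0.5)
    with pytest.raises(ParameterError):
        lambda_for_group_count(profile, 2, alpha=1.0)


def test_group_critical_lambdas_are_exact_boundaries():
    rng = np.random.default_rng(11)
    groups = make_groups([3, 2, 4, 1])
    U0 = rng.normal(size=(10, 2))
    for alpha in (0.0, 0.3, 0.8):
        crit = group_critical_lambdas(U0, groups, alpha)
        for k, lam_k in enumerate(crit):
            below = sparse_group_prox(U0, PenaltyParams(lam=lam_k * (1 - 1e-9), alpha=alpha), groups)
            above = sparse_group_prox(U0, PenaltyParams(lam=lam_k * (1 + 1e-9), alpha=alpha), groups)
            members = groups.members(k)
            assert np.any(below[members] != 0)
            assert not np.any(above[members] != 0)


@settings(max_examples=40, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    alpha=st.floats(0.0, 0.95),
    sizes=st.lists(st.integers(1, 4), min_size=2, max_size=5),
    M=st.integers(1, 3),
)
def test_resolve_lambda_hits_requested_count(seed, alpha, sizes, M):
    rng = np.random.default_rng(seed)
    groups = make_groups(sizes)
    U0 = rng.normal(size=(int(groups.sizes.sum()), M))
    for g in range(groups.K + 1):
        lam = resolve_lambda(U0, groups, g, alpha)
        out = sparse_group_prox(U0, PenaltyParams(lam=lam, alpha=alpha), groups)
        assert _surviving_groups(out, groups) == g


@settings(max_examples=40, deadline=None)
@given(seed=st.integers(0, 10_000), alpha=st.floats(0.0, 1.0))
def test_support_shrinks_monotonically_in_lambda(seed, alpha):
    rng = np.random.default_rng(seed)
    groups = make_groups([3, 2, 4])
    U0 = rng.normal(size=(9, 2))
    prev_support = None
    for lam in np.linspace(0.0, 6.0, 12):
        out = sparse_group_prox(U0, PenaltyParams(lam=lam, alpha=alpha), groups)
        support = np.any(out != 0, axis=1)
        if prev_support is not None:
            # larger lambda never resurrects a variable (nested supports)
            assert not np.any(support & ~prev_support)
        prev_support = support


def test_prox_lam_zero_is_identity():
    rng = np.random.default_rng(5)
    groups = make_groups([2, 3])
    U0 = rng.normal(size=(5, 2))
    out = sparse_group_prox(U0, PenaltyParams(lam=0.0, alpha=0.4), groups)
    np.testing.assert_allclose(out, U0, atol=1e-15)
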