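"""Shared synthetic fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pleiopls import ObservationSets, StructuredDataset, VariableGroups


def make_groups(sizes) -> VariableGroups:
    sizes = list(sizes)
    labels = tuple(f"g{k + 1}" for k in range(len(sizes)))
    index = np.repeat(np.arange(len(sizes)), sizes)
    return VariableGroups(labels, index)


def make_dataset(
    n_per_study=(14, 12),
    group_sizes=(2, 3, 2),
    q=1,
    binary=False,
    seed=0,
    signal_vars=(),
    signal_strength=2.0,
):
    """Random multi-study dataset; ``signal_vars`` columns drive the outcome."""
    rng = np.random.default_rng(seed)
    var_groups = make_groups(group_sizes)
    p = int(var_groups.sizes.sum())
    M = len(n_per_study)
    n = int(sum(n_per_study))
    X = rng.normal(size=(n, p))
    eta = np.zeros(n)
    for j in signal_vars:
        eta += signal_strength * X[:, j]
    if binary:
        prob = 1.0 / (1.0 + np.exp(-eta))
        Y = (rng.random(n) < prob).astype(float)[:, None]
        if q != 1:
            raise ValueError("binary fixture is univariate")
    else:
        Y = eta[:, None] + 0.1 * rng.normal(size=(n, 1))
        if q > 1:
            Y = np.column_stack([Y[:, 0]] + [
                0.5 * eta + 0.1 * rng.normal(size=n) for _ in range(q - 1)
            ])
    study_index = np.repeat(np.arange(M), n_per_study)
    obs_sets = ObservationSets(tuple(f"s{m + 1}" for m in range(M)), study_index)
    return StructuredDataset(
        X=X,
        Y=Y,
        obs_sets=obs_sets,
        var_groups=var_groups,
        sample_ids=tuple(f"id{i + 1}" for i in range(n)),
        variable_ids=tuple(f"v{j + 1}" for j in range(p)),
        outcome_ids=tuple(f"y{c + 1}" for c in range(Y.shape[1])),
    )


@pytest.fixture
def toy_dataset():
    return make_dataset(seed=1)


@pytest.fixture
def binary_dataset():
    return make_dataset(n_per_study=(30, 26), binary=True, seed=2, signal_vars=(0,))
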