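"""Per-study standardization and application-style cleaning filters.

Centering and scaling each column *within each study* is what makes the
per-study cross-products proportional to empirical correlations and is the
device used to absorb batch effects before any pooled or joint analysis.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .data_model import ObservationSets, StructuredDataset, VariableGroups
from .errors import ImputationError, ParameterError, PartitionError


def _standardize_block(block: np.ndarray, scale: bool):
    mean = block.mean(axis=0)
    centered = block - mean
    if scale:
        sd = block.std(axis=0, ddof=1)
        flags = sd == 0
        safe = np.where(flags, 1.0, sd)
        centered = centered / safe
        return centered, mean, safe, flags
    flags = centered.std(axis=0, ddof=1) == 0
    return centered, mean, np.ones_like(mean), flags


def standardize_within_study(dataset: StructuredDataset, scale: bool = True) -> StructuredDataset:
    """Center (and optionally scale to unit sample SD, ddof=1) X and Y within each study.

    Constant-within-study columns become all-zero in that study and are
    flagged; they can never be selected downstream because their loadings
    threshold to zero.  The per-study means/scales are stored on the result
    so fitted models can standardize new data identically.
    """
    X = dataset.X.copy()
    Y = dataset.Y.copy()
    stats: dict = {}
    flags: dict = {}
    for label, rows in dataset.obs_sets.blocks():
        if len(rows) < 2:
            raise PartitionError(f"study '{label}' has fewer than 2 samples")
        Xb, x_mean, x_scale, x_flags = _standardize_block(X[rows], scale)
        Yb, y_mean, y_scale, _ = _standardize_block(Y[rows], scale)
        X[rows] = Xb
        Y[rows] = Yb
        stats[label] = {
            "x_mean": x_mean,
            "x_scale": x_scale,
            "y_mean": y_mean,
            "y_scale": y_scale,
        }
        flags[label] = x_flags
    out = replace(dataset, X=X, Y=Y)
    out.standardized = True
    out.study_stats = stats
    out.zero_variance_flags = flags
    return out


def impute_median(dataset: StructuredDataset, stratify_by_outcome: bool = True) -> StructuredDataset:
    """Replace missing X entries by the stratum median (study x outcome class).

    With ``stratify_by_outcome`` the outcome must be binary; each missing
    value becomes the median of observed values of that column among samples
    of the same study and outcome class.
    """
    X = dataset.X.copy()
    y = dataset.Y[:, 0]
    if stratify_by_outcome:
        classes = np.unique(y[~np.isnan(y)])
        if len(classes) > 2:
            raise ParameterError("outcome-stratified imputation requires a binary outcome")
    for label, rows in dataset.obs_sets.blocks():
        if stratify_by_outcome:
            strata = [rows[y[rows] == c] for c in np.unique(y[rows])]
        else:
            strata = [rows]
        for stratum in strata:
            block = X[stratum]
            missing_cols = np.flatnonzero(np.isnan(block).any(axis=0))
            for j in missing_cols:
                observed = block[~np.isnan(block[:, j]), j]
                if observed.size == 0:
                    raise ImputationError(
                        f"column '{dataset.variable_ids[j]}' entirely missing in a stratum of study '{label}'"
                    )
                block[np.isnan(block[:, j]), j] = np.median(observed)
            X[stratum] = block
    return replace(dataset, X=X)


def prune_correlated(
    X: np.ndarray,
    var_groups: VariableGroups,
    r2_exact: float = 1.0,
    r2_within_group: float = 0.98,
) -> np.ndarray:
    """Greedy correlation pruning; returns indices of kept variables.

    Any retained pair has squared Pearson correlation < ``r2_exact``;
    retained pairs *within the same group* additionally have squared
    correlation <= ``r2_within_group``.  When a pair violates a rule the
    variable later in canonical order is dropped.  Zero-variance columns
    count as uncorrelated with everything and are never dropped here.
    """
    if not (0 < r2_exact <= 1) or not (0 < r2_within_group <= 1):
        raise ParameterError("correlation thresholds must lie in (0, 1]")
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    sd = X.std(axis=0)
    Z = np.where(sd > 0, (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    n = X.shape[0]
    corr = Z.T @ Z / n
    np.fill_diagonal(corr, 1.0)
    r2 = corr**2
    kept: list[int] = []
    for j in range(p):
        drop = False
        for i in kept:
            if r2[i, j] >= r2_exact:
                drop = True
                break
            if var_groups.index[i] == var_groups.index[j] and r2[i, j] > r2_within_group:
                drop = True
                break
        if not drop:
            kept.append(j)
    return np.asarray(kept, dtype=int)


def pool_studies(dataset: StructuredDataset, label: str = "pooled") -> StructuredDataset:
    """Standardize within each study, then relabel all samples as one study.

    This is the "both data" single-study mode: per-study standardization
    aggregates observations from different sources on a common scale, after
    which a single-study (non-joint) model can be fit on the concatenation.
    The outcome is left on its original scale so class coding survives.
    """
    std = standardize_within_study(dataset, scale=True)
    return StructuredDataset(
        X=std.X,
        Y=dataset.Y.copy(),
        obs_sets=ObservationSets((label,), np.zeros(dataset.n, dtype=int)),
        var_groups=dataset.var_groups,
        sample_ids=dataset.sample_ids,
        variable_ids=dataset.variable_ids,
        outcome_ids=dataset.outcome_ids,
        user_variable_order=dataset.user_variable_order,
    )
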