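"""K-fold cross-validation over the (group count, alpha) grid and
bootstrap stability selection.

CV error is the misclassification rate for a binary outcome, the root mean
squared error for a quantitative one, and its mean over outcome columns
for a multivariate outcome.  Because prediction-based calibration is weak
when effects are small, the bootstrap procedure offers an alternative:
refit on B within-study (and, for a binary outcome, within-class)
resamples and keep an originally selected feature only when its selection
rate strictly exceeds the best rate among features the original model did
not select.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import ObservationSets, PenaltyParams, SelectionResult, StructuredDataset
from .errors import (
    DegenerateSolutionError,
    ParameterError,
    RankDegeneracyError,
    StratificationError,
)
from .pls_core import FitConfig, FittedModel, fit, predict, selected_features
from .preprocessing import standardize_within_study

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 5
    group_counts: Sequence[int] = ()
    alphas: Sequence[float] = (0.1, 0.5, 0.9)
    stratify: bool = True
    seed: int = 0

    def resolved_group_counts(self, K: int) -> tuple[int, ...]:
        return tuple(self.group_counts) if self.group_counts else tuple(range(1, K + 1))


@dataclass(frozen=True)
class BootstrapConfig:
    B: int = 100
    seed: int = 0
    params: PenaltyParams = field(default_factory=PenaltyParams)

    def __post_init__(self):
        if self.B < 1:
            raise ParameterError("B must be >= 1")


def make_folds(
    y: np.ndarray,
    obs_sets: ObservationSets,
    L: int,
    stratify: bool = True,
    seed: int = 0,
) -> list[np.ndarray]:
    """Split samples into L disjoint folds, round-robin within study x class.

    With stratification each fold's class proportion within each study is
    within one sample of the overall proportion.
    """
    y = np.asarray(y).ravel()
    n = len(y)
    if not 2 <= L <= n:
        raise StratificationError(f"need 2 <= L <= n, got L={L}, n={n}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    start = 0
    for m in range(obs_sets.M):
        rows = obs_sets.rows(m)
        strata = (
            [rows[y[rows] == c] for c in np.unique(y[rows])] if stratify else [rows]
        )
        for stratum in strata:
            perm = rng.permutation(stratum)
            for pos, idx in enumerate(perm):
                fold_of[idx] = (start + pos) % L
            start += len(perm)
    folds = [np.flatnonzero(fold_of == l) for l in range(L)]
    if any(len(f) == 0 for f in folds):
        raise StratificationError(f"cannot fill {L} folds with n={n}")
    return folds


def _prediction_error(y_true: np.ndarray, y_pred: np.ndarray, labels, y_is_binary: bool) -> float:
    if y_is_binary:
        return float(np.mean(labels != y_true[:, 0].astype(int)))
    per_col = np.sqrt(np.mean((y_pred - y_true) ** 2, axis=0))
    return float(per_col.mean())


def _fold_error(model: FittedModel, test: StructuredDataset) -> float:
    errs = []
    weights = []
    for label, rows in test.obs_sets.blocks():
        if len(rows) == 0:
            continue
        y_pred, labels = predict(model, test.X[rows], label)
        errs.append(_prediction_error(test.Y[rows], y_pred, labels, model.y_is_binary))
        weights.append(len(rows))
    return float(np.average(errs, weights=weights))


def _prior_error(y: np.ndarray) -> float:
    vals, counts = np.unique(y.astype(int), return_counts=True)
    return float(1.0 - counts.max() / counts.sum())


def cross_validate(
    dataset: StructuredDataset,
    cv_config: CVConfig,
    fit_config_template: FitConfig,
) -> tuple[pd.DataFrame, PenaltyParams]:
    """Grid CV; returns the CV surface table and the error-minimizing params.

    The dataset must be on its original scale: each training split is
    standardized within study before fitting and test blocks are
    standardized with the training statistics at prediction time.  Ties are
    broken toward the smaller group count, then the smaller alpha.
    """
    group_counts = cv_config.resolved_group_counts(dataset.K)
    grid = [(g, a) for g in group_counts for a in cv_config.alphas]
    y = dataset.Y[:, 0]
    y_is_binary = dataset.q == 1 and set(np.unique(y)).issubset({0.0, 1.0})
    folds = make_folds(
        y, dataset.obs_sets, cv_config.n_folds,
        stratify=cv_config.stratify and y_is_binary, seed=cv_config.seed,
    )
    errors = np.full((len(grid), len(folds)), np.nan)
    for l, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(dataset.n), test_idx)
        train = standardize_within_study(dataset.subset_rows(train_idx), scale=True)
        test = dataset.subset_rows(test_idx)
        worst = _prior_error(y[train_idx]) if y_is_binary else float(np.std(y[train_idx]))
        for j, (g, a) in enumerate(grid):
            cfg = replace(
                fit_config_template,
                params=PenaltyParams(alpha=a, n_groups_kept=g),
            )
            try:
                model = fit(train, cfg)
                errors[j, l] = _fold_error(model, test)
            except (DegenerateSolutionError, RankDegeneracyError) as exc:
                logger.warning("fold %d grid (%d, %.2f): %s", l, g, a, exc)
                errors[j, l] = worst
    table = pd.DataFrame(
        {
            "group_count": [g for g, _ in grid],
            "alpha": [a for _, a in grid],
            "mean_error": errors.mean(axis=1),
            "var_error": errors.var(axis=1, ddof=1),
        }
    )
    order = np.lexsort(
        (table["alpha"].to_numpy(), table["group_count"].to_numpy(), table["mean_error"].to_numpy())
    )
    best_row = table.iloc[order[0]]
    best = PenaltyParams(alpha=float(best_row["alpha"]), n_groups_kept=int(best_row["group_count"]))
    return table, best


def _resample_within(dataset: StructuredDataset, rng: np.random.Generator, y_is_binary: bool):
    """Bootstrap rows with replacement within study (x class for binary y)."""
    idx = []
    y = dataset.Y[:, 0]
    for _, rows in dataset.obs_sets.blocks():
        strata = [rows[y[rows] == c] for c in np.unique(y[rows])] if y_is_binary else [rows]
        for stratum in strata:
            idx.append(rng.choice(stratum, size=len(stratum), replace=True))
    return np.sort(np.concatenate(idx))


def bootstrap_stability(
    dataset: StructuredDataset,
    params: PenaltyParams,
    B: int = 100,
    seed: int = 0,
    fit_config_template: Optional[FitConfig] = None,
) -> tuple[pd.DataFrame, SelectionResult]:
    """Bootstrap stability selection at fixed penalty parameters.

    Fits on the original data (the "preselection"), then on B within-study
    resamples; a preselected variable (or group) is kept iff its selection
    rate strictly exceeds the maximum rate among non-preselected features
    of the same level.  Returns the rate table and the final selection.
    """
    template = fit_config_template or FitConfig()
    cfg = replace(template, params=params)
    base_model = fit(dataset, cfg)
    pre = selected_features(base_model)

    y = dataset.Y[:, 0]
    y_is_binary = dataset.q == 1 and set(np.unique(y)).issubset({0.0, 1.0})
    rng = np.random.default_rng(seed)
    var_hits = np.zeros(dataset.p)
    grp_hits = np.zeros(dataset.K)
    done = 0
    while done < B:
        for attempt in range(100):
            idx = _resample_within(dataset, rng, y_is_binary)
            boot = dataset.subset_rows(idx)
            ok = all(
                len(np.unique(boot.Y[rows, 0])) > 1
                for _, rows in boot.obs_sets.blocks()
            ) if y_is_binary else True
            if ok:
                break
        else:
            raise StratificationError("could not draw a bootstrap replicate with both classes")
        try:
            sel = selected_features(fit(boot, cfg))
            var_hits += sel.variable_mask
            grp_hits += sel.group_mask
        except (DegenerateSolutionError, RankDegeneracyError) as exc:
            logger.warning("bootstrap replicate %d degenerate: %s", done, exc)
        done += 1
    var_rate = var_hits / B
    grp_rate = grp_hits / B

    def _keep(rates: np.ndarray, pre_mask: np.ndarray) -> np.ndarray:
        non_pre = rates[~pre_mask]
        cutoff = non_pre.max() if non_pre.size else -np.inf
        return pre_mask & (rates > cutoff)

    keep_var = _keep(var_rate, pre.variable_mask)
    keep_grp = _keep(grp_rate, pre.group_mask)

    rows = []
    for j, vid in enumerate(dataset.variable_ids):
        rows.append(("variable", vid, var_rate[j], bool(pre.variable_mask[j]), bool(keep_var[j])))
    for k, gid in enumerate(dataset.var_groups.labels):
        rows.append(("group", gid, grp_rate[k], bool(pre.group_mask[k]), bool(keep_grp[k])))
    table = pd.DataFrame(rows, columns=["level", "feature_id", "rate", "preselected", "kept"])
    final = SelectionResult(
        variables=tuple(v for v, s in zip(dataset.variable_ids, keep_var) if s),
        groups=tuple(g for g, s in zip(dataset.var_groups.labels, keep_grp) if s),
        variable_mask=keep_var,
        group_mask=keep_grp,
    )
    return table, final
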