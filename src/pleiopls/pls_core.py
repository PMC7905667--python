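"""Fitting sPLS / sgPLS / joint-sgPLS components, deflation and prediction.

Each component solves, over stacked loadings U (p x M) and V (q x M) with
unit-norm columns,

    min  sum_m || Z^(m) - U_{.,m} V_{.,m}^T ||_F^2  +  sparse-group penalty(U)

where Z^(m) = X_m^T Y_m is the per-study cross-product of the (within-study
standardized, possibly deflated) blocks.  For a univariate outcome the
solution is closed-form: U^(0)_{.,m} = Z^(m), then the composed prox, then
column renormalization.  For q > 1 the pair (U, V) is obtained by
alternating least squares with an SVD start.

Single-study sgPLS is the M = 1 case; sPLS is sgPLS with alpha = 1 (pure
per-variable shrinkage); lambda = 0 recovers the unpenalized PLS direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import (
    LoadingSet,
    PenaltyParams,
    SelectionResult,
    StructuredDataset,
    VariableGroups,
)
from .errors import (
    DegenerateSolutionError,
    IdentifierError,
    ParameterError,
    RankDegeneracyError,
)
from .penalties import resolve_lambda, sparse_group_prox
from .preprocessing import standardize_within_study

METHODS = ("spls", "sgpls", "joint_sgpls")


@dataclass(frozen=True)
class FitConfig:
    method: str = "joint_sgpls"
    n_components: int = 1
    params: PenaltyParams = field(default_factory=PenaltyParams)
    deflation_mode: str = "regression"
    max_alternations: int = 500
    tolerance: float = 1e-6
    size_weighted: bool = False

    def __post_init__(self):
        if self.method not in METHODS:
            raise ParameterError(f"unknown method '{self.method}'")
        if self.n_components < 1:
            raise ParameterError("n_components must be >= 1")
        if self.tolerance <= 0:
            raise ParameterError("tolerance must be positive")
        if self.deflation_mode not in ("regression", "canonical"):
            raise ParameterError(f"unknown deflation mode '{self.deflation_mode}'")


@dataclass
class CrossProductSet:
    """Per-study cross products Z^(m) = X_m^T Y_m (each p x q)."""

    matrices: list[np.ndarray]
    standardized_input: bool = True

    @property
    def M(self) -> int:
        return len(self.matrices)


def cross_products(dataset: StructuredDataset) -> CrossProductSet:
    """Z^(m) = X_m^T Y_m per study; proportional to within-study correlations
    when the input was standardized (a warning flag is carried otherwise)."""
    mats = []
    for _, rows in dataset.obs_sets.blocks():
        mats.append(dataset.X[rows].T @ dataset.Y[rows])
    return CrossProductSet(mats, standardized_input=bool(dataset.standardized))


def _normalize_columns(U: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(U, axis=0)
    out = U.copy()
    nz = norms > 0
    out[:, nz] = out[:, nz] / norms[nz]
    return out


def _resolved_params(
    U0: np.ndarray, params: PenaltyParams, groups: VariableGroups, size_weighted: bool
) -> PenaltyParams:
    if params.n_groups_kept is None:
        return params
    lam = resolve_lambda(
        U0, groups, params.n_groups_kept, params.alpha,
        size_weighted=size_weighted, strict=False,
    )
    return PenaltyParams(lam=lam, alpha=params.alpha)


def _penalty_value(U, params, groups, size_weighted):
    rows = np.linalg.norm(U, axis=1).sum()
    sq = np.bincount(groups.index, weights=(U**2).sum(axis=1), minlength=groups.K)
    w = np.sqrt(groups.sizes) if size_weighted else np.ones(groups.K)
    return params.lam * params.alpha * rows + params.lam * (1 - params.alpha) * float(w @ np.sqrt(sq))


def solve_joint_component(
    Zs: CrossProductSet | list[np.ndarray],
    params: PenaltyParams,
    groups: VariableGroups,
    config: Optional[FitConfig] = None,
    return_info: bool = False,
):
    """Solve one joint component from the per-study cross products.

    Returns (U, V) with U of shape p x M and V of shape q x M; each nonzero
    column has unit L2 norm.  Raises :class:`DegenerateSolutionError` when
    the penalty zeroes every loading.
    """
    mats = Zs.matrices if isinstance(Zs, CrossProductSet) else list(Zs)
    config = config or FitConfig(params=params)
    p, q = mats[0].shape
    M = len(mats)
    info = {"alternations": 0, "objective": []}

    if q == 1:
        U0 = np.column_stack([Z[:, 0] for Z in mats])
        eff = _resolved_params(U0, params, groups, config.size_weighted)
        U = sparse_group_prox(U0, eff, groups, size_weighted=config.size_weighted)
        if not np.any(U):
            raise DegenerateSolutionError(
                f"penalty lambda={eff.lam:.6g} (alpha={eff.alpha}) zeroed every loading"
            )
        U = _normalize_columns(U)
        V = np.ones((1, M))
        if return_info:
            return U, V, info
        return U, V

    # multivariate outcome: alternate with an SVD start (deterministic)
    V = np.zeros((q, M))
    for m, Z in enumerate(mats):
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        V[:, m] = vt[0]
    U = np.zeros((p, M))
    prev = None
    for it in range(config.max_alternations):
        U0 = np.column_stack([Z @ V[:, m] for m, Z in enumerate(mats)])
        eff = _resolved_params(U0, params, groups, config.size_weighted)
        U = sparse_group_prox(U0, eff, groups, size_weighted=config.size_weighted)
        if not np.any(U):
            raise DegenerateSolutionError(
                f"penalty lambda={eff.lam:.6g} (alpha={eff.alpha}) zeroed every loading"
            )
        U = _normalize_columns(U)
        for m, Z in enumerate(mats):
            vm = Z.T @ U[:, m]
            norm = np.linalg.norm(vm)
            if norm > 0:
                V[:, m] = vm / norm
        obj = sum(
            np.linalg.norm(Z - np.outer(U[:, m], V[:, m])) ** 2 for m, Z in enumerate(mats)
        ) + _penalty_value(U, eff, groups, config.size_weighted)
        info["objective"].append(float(obj))
        info["alternations"] = it + 1
        if prev is not None and np.linalg.norm(U - prev) <= config.tolerance * max(
            1.0, np.linalg.norm(prev)
        ):
            break
        prev = U.copy()
    if return_info:
        return U, V, info
    return U, V


def solve_single_component(
    Z: np.ndarray,
    params: PenaltyParams,
    groups: VariableGroups,
    method: str = "sgpls",
    config: Optional[FitConfig] = None,
):
    """Single-study component: sPLS (row thresholding only) or sgPLS."""
    if method == "spls":
        params = PenaltyParams(lam=params.lam, alpha=1.0, n_groups_kept=None)
    U, V = solve_joint_component([np.asarray(Z, float).reshape(Z.shape[0], -1)], params, groups, config)
    return U[:, 0], V[:, 0]


def deflate(X_m: np.ndarray, Y_m: np.ndarray, u_m: np.ndarray, mode: str = "regression"):
    """Remove the score direction t = X_m u_m from the study blocks.

    Regression mode deflates both X and Y on the X-score; canonical mode
    deflates Y on its own score (here the X-score is reused for Y only in
    regression mode).  A zero loading is an identity deflation.
    """
    if not np.any(u_m):
        return X_m.copy(), Y_m.copy()
    t = X_m @ u_m
    tt = float(t @ t)
    if tt == 0:
        raise RankDegeneracyError("X-scores vanished for a nonzero loading")
    X_new = X_m - np.outer(t, (t @ X_m) / tt)
    if mode == "regression":
        Y_new = Y_m - np.outer(t, (t @ Y_m) / tt)
    else:
        Y_new = Y_m.copy()
    return X_new, Y_new


@dataclass
class FittedModel:
    loadings: LoadingSet
    config: FitConfig
    study_labels: tuple[str, ...]
    variable_ids: tuple[str, ...]
    group_labels: tuple[str, ...]
    var_groups: VariableGroups
    study_stats: dict
    # per component, per study: x-loading (for deflating new data) and
    # regression coefficient of the (standardized) outcome on the score
    regression: list[dict]
    y_is_binary: bool
    class_prior: dict          # per study: mean of the original binary outcome
    n_components_fit: int = 0
    resolved_params: list = field(default_factory=list)


def _original_outcome(dataset: StructuredDataset) -> np.ndarray:
    """Outcome on its original (pre-standardization) scale."""
    if not dataset.standardized or dataset.study_stats is None:
        return dataset.Y.copy()
    Y = dataset.Y.copy()
    for label, rows in dataset.obs_sets.blocks():
        st = dataset.study_stats[label]
        Y[rows] = Y[rows] * st["y_scale"] + st["y_mean"]
    return Y


def fit(dataset: StructuredDataset, config: FitConfig) -> FittedModel:
    """Extract up to ``config.n_components`` components with per-study deflation.

    The dataset is standardized within study first (unless already flagged
    standardized); each study's blocks are deflated with that study's own
    scores, since the studies are coupled only through the penalty.
    """
    if config.method in ("spls", "sgpls") and dataset.M > 1:
        raise ParameterError(
            f"method '{config.method}' is single-study; pool the studies first"
        )
    Y_orig = _original_outcome(dataset)
    data = dataset if dataset.standardized else standardize_within_study(dataset, scale=True)
    y_vals = np.unique(Y_orig)
    y_is_binary = data.q == 1 and len(y_vals) <= 2 and set(y_vals).issubset({0.0, 1.0})

    Xs = {label: data.X[rows].copy() for label, rows in data.obs_sets.blocks()}
    Ys = {label: data.Y[rows].copy() for label, rows in data.obs_sets.blocks()}
    labels = data.obs_sets.labels
    params = config.params
    if config.method == "spls":
        params = PenaltyParams(lam=params.lam, alpha=1.0, n_groups_kept=None)

    loadings = LoadingSet(mode=config.deflation_mode)
    regression: list[dict] = []
    resolved: list[PenaltyParams] = []
    for h in range(config.n_components):
        Zs = [Xs[lab].T @ Ys[lab] for lab in labels]
        # track the lambda actually applied (for auditability)
        try:
            U, V = solve_joint_component(
                CrossProductSet(Zs), params, data.var_groups, config
            )
        except DegenerateSolutionError:
            if h == 0:
                raise
            warnings.warn(
                f"component {h + 1} degenerate; returning {h} component(s)", stacklevel=2
            )
            break
        loadings.components.append((U, V))
        comp_reg = {}
        for m, lab in enumerate(labels):
            u = U[:, m]
            if not np.any(u):
                comp_reg[lab] = {"x_loading": np.zeros(data.p), "coef": np.zeros(data.q)}
                continue
            t = Xs[lab] @ u
            tt = float(t @ t)
            if tt == 0:
                raise RankDegeneracyError(f"zero scores in study '{lab}' at component {h + 1}")
            x_loading = (t @ Xs[lab]) / tt
            coef = (t @ Ys[lab]) / tt
            comp_reg[lab] = {"x_loading": x_loading, "coef": coef}
            Xs[lab] = Xs[lab] - np.outer(t, x_loading)
            if config.deflation_mode == "regression":
                Ys[lab] = Ys[lab] - np.outer(t, coef)
            else:
                omega = Ys[lab] @ V[:, m]
                oo = float(omega @ omega)
                if oo > 0:
                    Ys[lab] = Ys[lab] - np.outer(omega, (omega @ Ys[lab]) / oo)
        regression.append(comp_reg)

    prior = {}
    for lab, rows in data.obs_sets.blocks():
        prior[lab] = float(Y_orig[rows, 0].mean()) if data.q == 1 else None
    return FittedModel(
        loadings=loadings,
        config=config,
        study_labels=labels,
        variable_ids=data.variable_ids,
        group_labels=data.var_groups.labels,
        var_groups=data.var_groups,
        study_stats=data.study_stats,
        regression=regression,
        y_is_binary=y_is_binary,
        class_prior=prior,
        n_components_fit=len(loadings.components),
    )


def predict(model: FittedModel, X_new: np.ndarray, study_id: str):
    """Predict the outcome for new samples of a known study.

    ``X_new`` must have the model's variables in the model's column order.
    Returns the prediction on the outcome's original scale; for a model
    trained on a binary 0/1 outcome, also returns hard labels obtained by
    thresholding at the midpoint of the class codes (0.5 on the original
    scale).
    """
    if study_id not in model.study_labels:
        raise IdentifierError(f"unknown study id '{study_id}'")
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(model.variable_ids):
        raise IdentifierError(
            f"X_new has {X_new.shape[1]} columns, model expects {len(model.variable_ids)}"
        )
    st = model.study_stats[study_id]
    Xc = (X_new - st["x_mean"]) / st["x_scale"]
    m = model.study_labels.index(study_id)
    q = len(st["y_mean"])
    y_std = np.zeros((X_new.shape[0], q))
    for (U, _), comp_reg in zip(model.loadings.components, model.regression):
        u = U[:, m]
        reg = comp_reg[study_id]
        t = Xc @ u
        y_std += np.outer(t, reg["coef"])
        Xc = Xc - np.outer(t, reg["x_loading"])
    y_pred = y_std * st["y_scale"] + st["y_mean"]
    if model.y_is_binary:
        labels = (y_pred[:, 0] > 0.5).astype(int)
        return y_pred, labels
    return y_pred, None


def selected_features(model: FittedModel) -> SelectionResult:
    """Variables with a nonzero loading row in any component, and their groups."""
    p = len(model.variable_ids)
    var_mask = np.zeros(p, dtype=bool)
    for U, _ in model.loadings.components:
        var_mask |= np.any(U != 0, axis=1)
    group_mask = np.zeros(model.var_groups.K, dtype=bool)
    if var_mask.any():
        hit = np.bincount(
            model.var_groups.index, weights=var_mask.astype(float), minlength=model.var_groups.K
        )
        group_mask = hit > 0
    return SelectionResult(
        variables=tuple(v for v, s in zip(model.variable_ids, var_mask) if s),
        groups=tuple(g for g, s in zip(model.group_labels, group_mask) if s),
        variable_mask=var_mask,
        group_mask=group_mask,
    )
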