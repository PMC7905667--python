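"""Simplified self-contained comparator statistics.

Two families are provided as qualitative baselines:

* a subset-search meta-analysis of per-study Wald Z statistics (the
  exhaustive max-|Z(S)| over nonempty study subsets, with a conservative
  Bonferroni-over-subsets or a permutation p-value), able to detect
  opposite-direction effects by dropping discordant studies; and
* a squared score statistic per variable group summed over studies,
  Q = sum_m ||w * X_{m,k}^T Ytilde_m||^2, sign-insensitive by construction,
  with a within-study permutation p-value.

The exact analytic null distributions of the original methods (the
discrete local maxima subset distribution, the mixture-of-chi-squares) are
deliberately not reproduced; permutation and Bonferroni substitutes keep
the statistics comparable without that machinery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_model import StructuredDataset
from .errors import IdentifierError, ParameterError


@dataclass
class WaldRow:
    """Per-study univariate estimate/SE/Z for one variable."""

    variable_id: str
    beta: np.ndarray    # (M,), nan when flagged
    se: np.ndarray
    z: np.ndarray
    sizes: np.ndarray

    @property
    def M(self) -> int:
        return len(self.z)


def _univariate_fit(x: np.ndarray, y: np.ndarray, binary: bool):
    if np.std(x) == 0:
        return np.nan, np.nan
    design = sm.add_constant(x)
    try:
        if binary:
            res = sm.Logit(y, design).fit(disp=0, maxiter=100)
            if not res.mle_retvals.get("converged", True):
                return np.nan, np.nan
        else:
            res = sm.OLS(y, design).fit()
    except Exception:
        return np.nan, np.nan
    beta, se = float(res.params[1]), float(res.bse[1])
    if not np.isfinite(beta) or not np.isfinite(se) or se <= 0 or abs(beta) > 1e3:
        return np.nan, np.nan
    return beta, se


def per_study_wald_stats(
    dataset: StructuredDataset, variable_id: str, model: str = "auto"
) -> WaldRow:
    """Univariate regression of Y on one variable within each study.

    ``model`` is "logistic", "linear" or "auto" (logistic for a binary 0/1
    outcome, linear otherwise).  Constant columns or separated fits are
    flagged as missing for that study.
    """
    if variable_id not in dataset.variable_ids:
        raise IdentifierError(f"unknown variable id '{variable_id}'")
    j = dataset.variable_ids.index(variable_id)
    y_all = dataset.Y[:, 0]
    if model == "auto":
        binary = set(np.unique(y_all)).issubset({0.0, 1.0})
    elif model in ("logistic", "linear"):
        binary = model == "logistic"
    else:
        raise ParameterError(f"unknown model '{model}'")
    M = dataset.M
    beta = np.full(M, np.nan)
    se = np.full(M, np.nan)
    for m, (_, rows) in enumerate(dataset.obs_sets.blocks()):
        beta[m], se[m] = _univariate_fit(dataset.X[rows, j], y_all[rows], binary)
    with np.errstate(invalid="ignore"):
        z = beta / se
    return WaldRow(variable_id, beta, se, z, dataset.obs_sets.sizes.astype(float))


def asset_max_subset(z: np.ndarray, sizes: np.ndarray) -> tuple[float, tuple[int, ...]]:
    """Exhaustive search of max |Z(S)| over nonempty study subsets.

    Z(S) = sum_{l in S} sqrt(n_l / sum_{S} n) * Z_l.  Missing Z entries are
    excluded from the search; ties go to the smaller subset, then
    lexicographic order.  Study indices in the returned subset are 0-based.
    """
    z = np.asarray(z, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    avail = [m for m in range(len(z)) if np.isfinite(z[m])]
    if not avail:
        raise ParameterError("all study statistics are missing")
    if len(avail) > 20:
        raise ParameterError("exhaustive subset search limited to M <= 20 studies")
    best_stat, best_subset = -np.inf, None
    for r in range(1, len(avail) + 1):
        for subset in itertools.combinations(avail, r):
            total = sizes[list(subset)].sum()
            zs = sum(np.sqrt(sizes[l] / total) * z[l] for l in subset)
            stat = abs(zs)
            if stat > best_stat + 1e-15 or (
                abs(stat - best_stat) <= 1e-15
                and best_subset is not None
                and (len(subset), subset) < (len(best_subset), best_subset)
            ):
                best_stat, best_subset = stat, subset
    return float(best_stat), tuple(best_subset)


def asset_pvalue(
    max_stat: float,
    M: int,
    method: str = "bonferroni_subsets",
    dataset: StructuredDataset | None = None,
    variable_id: str | None = None,
    R: int = 500,
    seed: int = 0,
) -> float:
    """P-value for the max-subset statistic.

    ``bonferroni_subsets``: (2^M - 1) * two-sided normal tail, capped at 1
    (conservative).  ``permutation``: within-study label permutations of the
    outcome, recomputing the full max-subset statistic each time (requires
    ``dataset`` and ``variable_id``).
    """
    if method == "bonferroni_subsets":
        return float(min(1.0, (2**M - 1) * 2.0 * stats.norm.sf(abs(max_stat))))
    if method != "permutation":
        raise ParameterError(f"unknown method '{method}'")
    if dataset is None or variable_id is None:
        raise ParameterError("permutation method needs dataset and variable_id")
    import warnings

    if R < 100:
        warnings.warn(f"R={R} permutations is low; p-value resolution is 1/{R + 1}")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(R):
        perm = dataset.copy()
        for _, rows in dataset.obs_sets.blocks():
            perm.Y[rows] = dataset.Y[rng.permutation(rows)]
        row = per_study_wald_stats(perm, variable_id)
        try:
            stat, _ = asset_max_subset(row.z, row.sizes)
        except ParameterError:
            continue
        if stat >= max_stat:
            exceed += 1
    return float((1 + exceed) / (1 + R))


def _centered_outcome(dataset: StructuredDataset) -> np.ndarray:
    """Residuals of an intercept-only model within each study (no covariates)."""
    y = dataset.Y[:, 0].astype(float)
    resid = np.empty_like(y)
    for _, rows in dataset.obs_sets.blocks():
        resid[rows] = y[rows] - y[rows].mean()
    return resid


def metaskat_score(dataset: StructuredDataset, group_id: str, weights=None) -> float:
    """Q = sum over studies of ||w * X_{m,k}^T Ytilde_m||^2 for one group."""
    if group_id not in dataset.var_groups.labels:
        raise IdentifierError(f"unknown group id '{group_id}'")
    k = dataset.var_groups.labels.index(group_id)
    members = dataset.var_groups.members(k)
    ytilde = _centered_outcome(dataset)
    w = np.ones(len(members)) if weights is None else np.broadcast_to(
        np.asarray(weights, float), (len(members),)
    )
    Q = 0.0
    for _, rows in dataset.obs_sets.blocks():
        S = dataset.X[np.ix_(rows, members)].T @ ytilde[rows]
        Q += float(((w * S) ** 2).sum())
    return Q


def metaskat_pvalue_permutation(
    dataset: StructuredDataset, group_id: str, weights=None, R: int = 200, seed: int = 0
) -> float:
    """Within-study permutation p-value, p = (1 + #{Q_perm >= Q_obs}) / (1 + R)."""
    if R < 100:
        raise ParameterError("R must be >= 100")
    q_obs = metaskat_score(dataset, group_id, weights)
    k = dataset.var_groups.labels.index(group_id)
    members = dataset.var_groups.members(k)
    ytilde = _centered_outcome(dataset)
    w = np.ones(len(members)) if weights is None else np.broadcast_to(
        np.asarray(weights, float), (len(members),)
    )
    rng = np.random.default_rng(seed)
    blocks = [(dataset.X[np.ix_(rows, members)], ytilde[rows]) for _, rows in dataset.obs_sets.blocks()]
    exceed = 0
    for _ in range(R):
        q = 0.0
        for Xb, yb in blocks:
            S = Xb.T @ yb[rng.permutation(len(yb))]
            q += float(((w * S) ** 2).sum())
        if q >= q_obs:
            exceed += 1
    return float((1 + exceed) / (1 + R))


def benchmark_table(
    dataset: StructuredDataset,
    method: str,
    R: int = 200,
    seed: int = 0,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Per-variable (subset-search) or per-group (score) statistics and p-values.

    The subset-search p-values are Benjamini-Hochberg adjusted over variables
    and a variable counts as selected when its adjusted p-value < alpha_level.
    """
    if method == "asset":
        rows = []
        for vid in dataset.variable_ids:
            wald = per_study_wald_stats(dataset, vid)
            try:
                stat, subset = asset_max_subset(wald.z, wald.sizes)
                pval = asset_pvalue(stat, int(np.isfinite(wald.z).sum()))
            except ParameterError:
                stat, subset, pval = np.nan, (), np.nan
            rows.append((vid, stat, "+".join(str(s + 1) for s in subset), pval))
        table = pd.DataFrame(rows, columns=["feature_id", "statistic", "subset", "p_value"])
        from statsmodels.stats.multitest import multipletests

        mask = table["p_value"].notna().to_numpy()
        adj = np.full(len(table), np.nan)
        if mask.any():
            adj[mask] = multipletests(table.loc[mask, "p_value"], method="fdr_bh")[1]
        table["p_adjusted"] = adj
        table["selected"] = table["p_adjusted"] < alpha_level
        return table
    if method == "metaskat":
        rows = []
        for i, gid in enumerate(dataset.var_groups.labels):
            q = metaskat_score(dataset, gid)
            pval = metaskat_pvalue_permutation(dataset, gid, R=R, seed=seed + i)
            rows.append((gid, q, pval))
        table = pd.DataFrame(rows, columns=["feature_id", "statistic", "p_value"])
        table["selected"] = table["p_value"] < alpha_level
        return table
    raise ParameterError(f"unknown benchmark method '{method}'")
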