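"""Proximal soft-thresholding operators of the sparse group penalty.

The penalty on a stacked loading matrix ``U`` (p variables x M studies) is

    lambda * alpha     * sum_i ||U_{i,.}||_2          (per-variable rows)
  + lambda * (1-alpha) * sum_k w_k ||U_{P_k,.}||_F    (per-group blocks)

whose proximal solution is computed in two closed-form shrinkage steps:
row-wise soft-thresholding at ``lambda*alpha/2`` followed by block-wise
(Frobenius) soft-thresholding at ``lambda*(1-alpha)/2``.  Because a row or
a block is scaled as a whole, a variable or group is zeroed in *all*
studies simultaneously — the joint selection property.

By default the group step uses the unweighted threshold (w_k = 1); the
``size_weighted`` flag applies the sqrt(p_k) group-size weight instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import PenaltyParams, VariableGroups
from .errors import ParameterError, TieError


def _positive_part(x: np.ndarray) -> np.ndarray:
    # (x)_+ = (|x| + x) / 2; exactly zero at and below the boundary
    return (np.abs(x) + x) / 2.0


@dataclass(frozen=True)
class GroupNormProfile:
    """Per-group Frobenius norms of a loading matrix and the group sizes."""

    norms: np.ndarray
    sizes: np.ndarray

    def __post_init__(self):
        if len(self.norms) != len(self.sizes):
            raise ParameterError("norms and sizes must have equal length")
        if np.any(np.asarray(self.norms) < 0):
            raise ParameterError("group norms must be nonnegative")


def group_norms(U: np.ndarray, groups: VariableGroups) -> GroupNormProfile:
    """Frobenius norm of each group block of U."""
    U = np.atleast_2d(np.asarray(U, dtype=float))
    sq = np.bincount(groups.index, weights=(U**2).sum(axis=1), minlength=groups.K)
    return GroupNormProfile(np.sqrt(sq), groups.sizes)


def soft_threshold_rows(U0: np.ndarray, t: float) -> np.ndarray:
    """Scale each row by (1 - t/||row||_2)_+; rows with norm <= t become zero."""
    if t < 0:
        raise ParameterError(f"threshold must be nonnegative, got {t}")
    U0 = np.atleast_2d(np.asarray(U0, dtype=float))
    norms = np.linalg.norm(U0, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    factor = _positive_part(1.0 - t / safe)
    factor[norms == 0] = 0.0 if t > 0 else factor[norms == 0]
    return U0 * factor[:, None]


def soft_threshold_groups(
    U1: np.ndarray,
    groups: VariableGroups,
    t: float,
    size_weighted: bool = False,
) -> np.ndarray:
    """Scale each group block by (1 - t_k/||block||_F)_+ with t_k = t or sqrt(p_k)*t."""
    if t < 0:
        raise ParameterError(f"threshold must be nonnegative, got {t}")
    U1 = np.atleast_2d(np.asarray(U1, dtype=float))
    profile = group_norms(U1, groups)
    thresholds = t * np.sqrt(groups.sizes) if size_weighted else np.full(groups.K, t)
    safe = np.where(profile.norms > 0, profile.norms, 1.0)
    factor = _positive_part(1.0 - thresholds / safe)
    factor[profile.norms == 0] = 0.0
    return U1 * factor[groups.index][:, None]


def sparse_group_prox(
    U0: np.ndarray,
    params: PenaltyParams,
    groups: VariableGroups,
    size_weighted: bool = False,
) -> np.ndarray:
    """Variable-level then group-level soft-thresholding (the composed prox)."""
    U1 = soft_threshold_rows(U0, params.lam * params.alpha / 2.0)
    return soft_threshold_groups(
        U1, groups, params.lam * (1.0 - params.alpha) / 2.0, size_weighted=size_weighted
    )


def lambda_for_group_count(
    profile: GroupNormProfile,
    g: int,
    alpha: float,
    size_weighted: bool = False,
) -> float:
    """Lambda whose group threshold keeps exactly the g largest-norm groups.

    The profile must be computed *after* the variable-level step.  The
    threshold is placed midway between the g-th and (g+1)-th largest
    (effective) norms; a group survives iff its norm strictly exceeds the
    threshold.  Ties across that boundary make an exact count unattainable.
    """
    K = len(profile.norms)
    if not 0 <= g <= K:
        raise ParameterError(f"g must be in [0, {K}], got {g}")
    if alpha >= 1.0:
        raise ParameterError("alpha must be < 1 to control group count via lambda")
    eff = profile.norms / np.sqrt(profile.sizes) if size_weighted else np.asarray(profile.norms, float)
    order = np.argsort(-eff, kind="stable")
    sorted_norms = eff[order]
    if g == 0:
        t = float(sorted_norms[0])  # norm <= t zeroes every group
    elif g == K:
        positive = sorted_norms[sorted_norms > 0]
        if len(positive) < K:
            raise TieError(
                "cannot keep all groups: some group norms are zero",
                tied_groups=np.flatnonzero(eff == 0).tolist(),
            )
        t = float(positive[-1]) / 2.0
    else:
        hi, lo = float(sorted_norms[g - 1]), float(sorted_norms[g])
        if hi == lo:
            tied = np.flatnonzero(eff == hi).tolist()
            raise TieError(f"tied group norms at the selection boundary ({hi})", tied_groups=tied)
        t = (hi + lo) / 2.0
    return 2.0 * t / (1.0 - alpha)


def group_critical_lambdas(
    U0: np.ndarray,
    groups: VariableGroups,
    alpha: float,
    size_weighted: bool = False,
    n_iter: int = 60,
) -> np.ndarray:
    """Per group, the lambda at which the composed prox zeroes it.

    A group survives ``sparse_group_prox(U0, (lam, alpha))`` iff its
    Frobenius norm after row-thresholding at ``lam*alpha/2`` strictly
    exceeds its group threshold ``w_k * lam*(1-alpha)/2``.  That margin is
    strictly decreasing in lambda, so the critical value is found by
    bisection (vectorized over groups).
    """
    U0 = np.atleast_2d(np.asarray(U0, dtype=float))
    row_norms = np.linalg.norm(U0, axis=1)
    gidx = groups.index
    weights = np.sqrt(groups.sizes) if size_weighted else np.ones(groups.K)

    def alive(lam: np.ndarray) -> np.ndarray:
        # lam: per-group candidate (K,); rows see their own group's lambda
        shrunk = _positive_part(row_norms - lam[gidx] * alpha / 2.0)
        sq = np.bincount(gidx, weights=shrunk**2, minlength=groups.K)
        return np.sqrt(sq) > weights * lam * (1.0 - alpha) / 2.0

    # Per-group upper bound on the critical lambda (keeps the bisection
    # interval tight, so 60 halvings give ~2^-60 relative precision):
    # the group is certainly dead once its unshrunk norm falls at/below the
    # group threshold (lam >= 2*norm_k/((1-alpha)*w_k)), or once every one
    # of its rows is zeroed (lam >= 2*max_row_k/alpha).
    profile = group_norms(U0, groups)
    hi = np.full(groups.K, np.inf)
    with np.errstate(over="ignore", divide="ignore"):
        if alpha < 1:
            hi = np.minimum(hi, 2.0 * profile.norms / ((1.0 - alpha) * weights))
        if alpha > 0:
            row_max = np.zeros(groups.K)
            np.maximum.at(row_max, gidx, row_norms)
            hi = np.minimum(hi, 2.0 * row_max / alpha)
    hi = np.where(np.isfinite(hi), hi, 2.0 * row_norms.max(initial=0.0) + 1.0)
    hi = np.maximum(hi, 1e-300)
    lo = np.zeros(groups.K)
    dead_at_zero = ~alive(lo)
    for _ in range(n_iter):
        mid = (lo + hi) / 2.0
        a = alive(mid)
        lo = np.where(a, mid, lo)
        hi = np.where(a, hi, mid)
    crit = hi
    crit[dead_at_zero] = 0.0
    return crit


def resolve_lambda(
    U0: np.ndarray,
    groups: VariableGroups,
    g: int,
    alpha: float,
    size_weighted: bool = False,
    strict: bool = True,
) -> float:
    """Lambda making the composed prox keep exactly ``g`` groups of U0.

    Chosen as the midpoint of the lambda interval on which the surviving
    group count equals g (the count is non-increasing in lambda).  With
    ``strict`` a count jump across g (possible only through ties) raises
    :class:`TieError`; otherwise the nearest attainable lambda is returned.
    """
    if not 0 <= g <= groups.K:
        raise ParameterError(f"g must be in [0, {groups.K}], got {g}")
    crit = np.sort(group_critical_lambdas(U0, groups, alpha, size_weighted))[::-1]
    # count(lam) = #{k : crit_k > lam}; exactly g iff crit[g] <= lam < crit[g-1]
    upper = float(crit[g - 1]) if g >= 1 else None
    lower = float(crit[g]) if g < groups.K else 0.0
    if upper is None:  # g == 0: zero everything
        return float(crit[0]) * (1.0 + 1e-12)
    if upper <= lower:
        if strict:
            raise TieError(
                f"exactly {g} surviving groups is unattainable (count jumps at lambda={upper})"
            )
        return upper
    if g == groups.K:
        return upper / 2.0
    return (upper + lower) / 2.0
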