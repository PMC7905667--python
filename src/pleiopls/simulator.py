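"""Multi-study genotype/phenotype simulator with ground-truth bookkeeping.

Genotypes are minor-allele counts in {0, 1, 2}.  Within a group (an LD
block) a latent equicorrelated Gaussian vector is drawn and each column is
discretized at the standard-normal quantiles matching the Hardy-Weinberg
genotype probabilities ((1-MAF)^2, 2*MAF*(1-MAF), MAF^2).  A binary
phenotype follows a logistic model on the discrete genotypes.  Studies are
simulated independently from the same causal pattern; under the
opposite-direction designs the second study's causal coefficients have
flipped signs.

The eight stock designs cross (i) same vs opposite effect directions,
(ii) 100% vs 50% of SNPs causal within the 5 causal groups, and (iii) a
total sample size of 200 vs 400 split equally over the 2 studies, with 25
groups of 20 SNPs, within-group latent correlation 0.5 and MAF 0.3.
Causal coefficient magnitudes are exp(0.1) for the 100%-effect designs and
exp(0.5) for the 50%-effect designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import ObservationSets, StructuredDataset, VariableGroups
from .errors import ParameterError

#: case id -> (opposite directions, intra-group causal proportion, total n)
CASE_TABLE = {
    1: (False, 1.0, 200),
    2: (False, 1.0, 400),
    3: (False, 0.5, 200),
    4: (False, 0.5, 400),
    5: (True, 1.0, 200),
    6: (True, 1.0, 400),
    7: (True, 0.5, 200),
    8: (True, 0.5, 400),
}


@dataclass(frozen=True)
class SimulationDesign:
    M: int = 2
    n_per_study: tuple[int, ...] = (100, 100)
    K: int = 25
    p_per_group: int = 20
    rho: float = 0.5
    maf: float = 0.3
    n_causal_groups: int = 5
    intra_group_proportion: float = 1.0
    beta_magnitude: float = math.exp(0.1)
    opposite_directions: bool = False
    intercept: float = 0.0

    def __post_init__(self):
        if not 0 < self.maf <= 0.5:
            raise ParameterError(f"MAF must be in (0, 0.5], got {self.maf}")
        if not (-1.0 / (self.p_per_group - 1) < self.rho < 1.0):
            raise ParameterError(f"rho={self.rho} makes the latent covariance non-positive-definite")
        if not 0 < self.intra_group_proportion <= 1:
            raise ParameterError("intra_group_proportion must be in (0, 1]")
        if len(self.n_per_study) != self.M:
            raise ParameterError("n_per_study length must equal M")

    @property
    def p(self) -> int:
        return self.K * self.p_per_group


@dataclass(frozen=True)
class GroundTruth:
    causal_variables: tuple[str, ...]
    causal_groups: tuple[str, ...]
    beta_per_study: dict  # study label -> signed beta vector (length p)
    causal_mask: np.ndarray = field(repr=False, default=None)
    causal_group_mask: np.ndarray = field(repr=False, default=None)


def build_design(case_id: int) -> SimulationDesign:
    """One of the eight stock simulation designs."""
    if case_id not in CASE_TABLE:
        raise ParameterError(f"case id must be 1..8, got {case_id}")
    opposite, proportion, n_total = CASE_TABLE[case_id]
    magnitude = math.exp(0.1) if proportion == 1.0 else math.exp(0.5)
    half = n_total // 2
    return SimulationDesign(
        n_per_study=(half, n_total - half),
        intra_group_proportion=proportion,
        beta_magnitude=magnitude,
        opposite_directions=opposite,
    )


def genotype_cutpoints(maf: float) -> tuple[float, float]:
    """Standard-normal quantiles separating genotypes 0/1 and 1/2."""
    p0 = (1.0 - maf) ** 2
    p01 = p0 + 2.0 * maf * (1.0 - maf)
    return float(stats.norm.ppf(p0)), float(stats.norm.ppf(p01))


def discretize_genotype(column: np.ndarray, maf: float) -> np.ndarray:
    """Map a (marginally standard-normal) column to {0,1,2} at the HWE quantiles.

    Bins are half-open: x <= q1 -> 0, q1 < x <= q2 -> 1, x > q2 -> 2.
    """
    q1, q2 = genotype_cutpoints(maf)
    column = np.asarray(column, dtype=float)
    return ((column > q1).astype(np.int64) + (column > q2).astype(np.int64))


def simulate_genotype_block(
    n: int,
    p_k: int,
    rho: float,
    maf_vector,
    rng: np.random.Generator,
    return_latent: bool = False,
):
    """Equicorrelated latent Gaussian block discretized column-wise by MAF."""
    if not (-1.0 / (p_k - 1) < rho < 1.0):
        raise ParameterError(f"rho={rho} non-positive-definite for block size {p_k}")
    maf_vector = np.broadcast_to(np.asarray(maf_vector, dtype=float), (p_k,))
    sigma = np.full((p_k, p_k), rho)
    np.fill_diagonal(sigma, 1.0)
    chol = np.linalg.cholesky(sigma)
    latent = rng.standard_normal((n, p_k)) @ chol.T
    geno = np.column_stack(
        [discretize_genotype(latent[:, j], maf_vector[j]) for j in range(p_k)]
    )
    if return_latent:
        return geno, latent
    return geno


def simulate_phenotype(
    X_discrete: np.ndarray, beta: np.ndarray, intercept: float, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli outcome from logit(pi) = intercept + X beta."""
    eta = intercept + np.asarray(X_discrete, dtype=float) @ np.asarray(beta, dtype=float)
    pi = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(len(pi)) < pi).astype(np.int64)


def _draw_causal_pattern(design: SimulationDesign, rng: np.random.Generator):
    """Signed causal coefficients, drawn once per replicate.

    Within each causal group ceil(proportion * p_k) SNPs are causal (chosen
    at random), half with +|beta| and half with -|beta| (the split differs
    by one when the count is odd).
    """
    p = design.p
    beta = np.zeros(p)
    causal_mask = np.zeros(p, dtype=bool)
    for k in range(design.n_causal_groups):
        members = np.arange(k * design.p_per_group, (k + 1) * design.p_per_group)
        n_causal = math.ceil(design.intra_group_proportion * design.p_per_group)
        chosen = rng.choice(members, size=n_causal, replace=False)
        signs = np.ones(n_causal)
        signs[: n_causal // 2] = -1.0
        rng.shuffle(signs)
        beta[chosen] = signs * design.beta_magnitude
        causal_mask[chosen] = True
    return beta, causal_mask


def simulate_study_set(design: SimulationDesign, seed: int) -> tuple[StructuredDataset, GroundTruth]:
    """Simulate every study independently from one causal pattern."""
    rng = np.random.default_rng(seed)
    beta1, causal_mask = _draw_causal_pattern(design, rng)

    width = len(str(design.p))
    variable_ids = tuple(f"snp_{j + 1:0{width}d}" for j in range(design.p))
    group_labels = tuple(f"group_{k + 1:02d}" for k in range(design.K))
    group_index = np.repeat(np.arange(design.K), design.p_per_group)
    study_labels = tuple(f"study_{m + 1}" for m in range(design.M))

    betas = {}
    X_parts, y_parts, sample_ids, study_index = [], [], [], []
    for m, (label, n_m) in enumerate(zip(study_labels, design.n_per_study)):
        beta = -beta1 if (design.opposite_directions and m > 0) else beta1
        betas[label] = beta
        blocks = [
            simulate_genotype_block(n_m, design.p_per_group, design.rho, design.maf, rng)
            for _ in range(design.K)
        ]
        X_m = np.concatenate(blocks, axis=1)
        y_m = simulate_phenotype(X_m, beta, design.intercept, rng)
        X_parts.append(X_m)
        y_parts.append(y_m)
        sample_ids.extend(f"{label}_s{i + 1:04d}" for i in range(n_m))
        study_index.extend([m] * n_m)

    dataset = StructuredDataset(
        X=np.concatenate(X_parts, axis=0).astype(float),
        Y=np.concatenate(y_parts)[:, None].astype(float),
        obs_sets=ObservationSets(study_labels, np.asarray(study_index)),
        var_groups=VariableGroups(group_labels, group_index),
        sample_ids=tuple(sample_ids),
        variable_ids=variable_ids,
        outcome_ids=("phenotype",),
    )
    causal_group_mask = np.zeros(design.K, dtype=bool)
    causal_group_mask[: design.n_causal_groups] = True
    truth = GroundTruth(
        causal_variables=tuple(v for v, c in zip(variable_ids, causal_mask) if c),
        causal_groups=group_labels[: design.n_causal_groups],
        beta_per_study=betas,
        causal_mask=causal_mask,
        causal_group_mask=causal_group_mask,
    )
    return dataset, truth
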