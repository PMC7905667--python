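# Methods

This note describes, in the package's own terms, the statistical model, the
algorithms, the simulator and the numerical choices implemented in
`pleiopls`, together with known limitations.

## Data model

Data are an `n × p` predictor matrix `X` (typically SNP minor-allele counts
in {0, 1, 2}) and an `n × q` outcome matrix `Y` (typically a single binary
phenotype), together with two partitions:

- **observation sets**: the samples are split into `M` studies (sources);
- **variable groups**: the `p` variables are split into `K` disjoint groups
  (genes, LD blocks, pathways).

Variables are kept internally in a canonical order in which group members
are contiguous; files always use string identifiers and the permutation back
to the user's column order is retained.

Every analysis begins by centering and scaling each column *within each
study* (sample SD, ddof = 1).  This absorbs study-specific location/scale
(batch) effects and makes the per-study cross-products proportional to
within-study correlations.  Columns constant within a study are flagged and
zeroed there; they can never be selected.

## The joint component

Writing `Z⁽ᵐ⁾ = Xₘᵀ Yₘ` for the cross-product of study *m*'s standardized
blocks, one component solves, over stacked loadings `U (p × M)` and
`V (q × M)` with unit-norm columns,

```
min  Σₘ ‖Z⁽ᵐ⁾ − U·ₘ V·ₘᵀ‖²_F
     + λ·α·Σᵢ ‖U_{i·}‖₂  +  λ·(1−α)·Σₖ wₖ ‖U_{P_k·}‖_F
```

The first penalty term acts on **rows** of `U` (one variable across all
studies), the second on **group blocks** (all rows of a group).  Because a
row or block is shrunk as a whole, a variable or group is zeroed in every
study simultaneously — this is what makes selection *joint* — while the
signs and relative sizes of the surviving loadings remain study-specific, so
opposite-direction effects are representable.

For a univariate outcome (`q = 1`) the solution is closed-form:

1. `U⁰·ₘ = Z⁽ᵐ⁾` (stack the per-study cross-products);
2. soft-threshold each row at `λα/2` (scale by `(1 − t/‖row‖)₊`);
3. soft-threshold each group block at `wₖ·λ(1−α)/2` in Frobenius norm;
4. renormalize each nonzero column of `U` to unit length; `V = 1`.

By default `wₖ = 1`; `size_weighted=True` uses `wₖ = √pₖ` so that larger
groups are penalized more.  For `q > 1` the pair `(U, V)` is computed by
alternating the same shrinkage step with `V`-updates `V·ₘ ∝ Z⁽ᵐ⁾ᵀU·ₘ`,
starting from each study's leading singular direction.  The alternation is
the standard thresholding heuristic of sparse PLS: because loadings are
renormalized each pass, the tracked objective is not guaranteed monotone,
but the iteration converges rapidly in practice (tolerance 1e−6, at most
500 alternations).

Single-study sparse group PLS (`sgpls`) is the `M = 1` case; sparse PLS
(`spls`) is `sgpls` with `α = 1` (row shrinkage only); `λ = 0` recovers the
unpenalized PLS direction, i.e. the leading singular direction of `XᵀY`.
The "pooled" competitor standardizes each study, concatenates the samples,
and runs the single-study model on the result.

## Calibrating λ via a group count

Users specify the penalty as **the number of groups to keep** rather than a
raw λ.  A group survives the composed shrinkage iff its post-row-threshold
Frobenius norm strictly exceeds its group threshold; that margin is strictly
decreasing in λ, so each group has a well-defined critical λ at which it
dies.  The critical values are found by vectorized bisection on per-group
brackets (60 halvings, ~2⁻⁶⁰ relative precision), and λ for a requested
count `g` is placed at the midpoint of the interval of λ on which exactly
`g` groups survive.  Ties (two groups dying at the same λ) make a count
unattainable; the strict API raises a `TieError`, while model fitting falls
back to the nearest attainable λ.

## Components, deflation, prediction

Components are extracted successively.  After each component, every study's
blocks are deflated with that study's own score `t = Xₘ u·ₘ` (regression
mode deflates both `Xₘ` and `Yₘ` on `t`); studies are coupled only through
the penalty.  The per-component, per-study regression coefficients of the
standardized outcome on the score are stored, so new samples of a known
study can be standardized with the training statistics and pushed through
the same component/deflation sequence.  For a binary 0/1 outcome the
prediction is thresholded at 0.5 on the original scale; a variable selected
by *any* component counts as selected.

## Model selection

**Cross-validation.** Stratified K-fold CV (default L = 5) assigns samples
round-robin within each study × class stratum, so every fold preserves both
the study composition and the class balance to within one sample.  The grid
is (groups kept `g` ∈ {1..K}) × (α ∈ {0.1, 0.5, 0.9}); the error is the
misclassification rate for a binary outcome (RMSE otherwise), averaged over
study blocks weighted by block size.  Degenerate fits score as the
prior/trivial error.  Ties are broken toward fewer groups, then smaller α.

**Bootstrap stability selection.** At fixed penalty parameters the model is
fit once on the full data (the preselection) and on B within-study (and
within-class) bootstrap resamples.  A preselected variable or group is kept
iff its selection rate strictly exceeds the best rate among features the
original model did not select.  This is the recommended second stage when
prediction-based CV is weak (see limitations).

## Simulator

Each group is an LD block: a latent equicorrelated Gaussian vector
(correlation ρ = 0.5 within the block) is discretized column-wise at the
standard-normal quantiles of the Hardy–Weinberg probabilities
((1−MAF)², 2·MAF·(1−MAF), MAF²), MAF = 0.3, giving genotypes {0, 1, 2}.  A
binary phenotype follows `logit(π) = Xβ`.  The 8 stock designs use K = 25
groups of 20 SNPs with the first 5 groups causal and cross:

- same vs **opposite** effect directions (study 2's β = −study 1's β);
- all 20 vs a random 10 of each causal group's SNPs causal, with
  |β| = e^0.1 ≈ 1.105 and e^0.5 ≈ 1.649 respectively;
- total n = 200 vs 400, split equally over M = 2 studies.

Within each causal group, half the causal coefficients are positive and half
negative at random positions.  Studies are simulated independently from one
causal pattern per replicate; ground truth (causal variables, groups, and
per-study β) is returned alongside the dataset.

## Comparators

Two simplified meta-analysis baselines are included for context, not as
reimplementations of any published tool:

- **subset search**: per-study univariate Wald Z statistics (logistic or
  linear, via statsmodels) combined as `Z(S) = Σ_{l∈S} √(n_l/n_S)·Z_l` with
  an exhaustive search over nonempty study subsets; detects
  opposite-direction effects by dropping discordant studies.  P-values are
  either Bonferroni-over-subsets (conservative) or within-study permutation;
  the per-variable table is Benjamini–Hochberg adjusted.
- **group score**: `Q = Σₘ ‖Xₘₖᵀ Ỹₘ‖²` per group with intercept-only
  residuals `Ỹ`, sign-insensitive by construction, with a within-study
  permutation p-value.

The exact analytic null distributions of the original subset-search and
variance-component methods are deliberately out of scope; permutation and
Bonferroni substitutes keep the statistics comparable without that
machinery.

## Numerical choices

- All randomness flows through `numpy.random.Generator`; the benchmark
  harness derives per-case/per-replicate substreams from one master seed via
  `SeedSequence.spawn`, so a replicate's data is identical whichever methods
  run, and all derived integer seeds stay below 2³¹.
- Proximal steps use the exact closed forms; `(x)₊` is computed as
  `(|x|+x)/2` so boundaries threshold to exact zeros.
- The critical-λ bisection brackets each group by analytic upper bounds
  (group-norm death and all-rows-death), keeping 60 iterations sufficient
  for near-machine relative precision.
- Fold assignment, bootstrap resampling and the simulator are all
  deterministic given their seeds; fitted models are fully deterministic.

## Limitations

- With a binary outcome and weak per-variant effects (the e^0.1 designs),
  the misclassification-based CV surface is flat and noisy, so the chosen
  group count is variable and tends to be generous; selection lists should
  then be read together with the bootstrap stability filter.  With a
  quantitative outcome, or stronger effects, the CV surface is sharp.
- The group-count calibration assumes no ties in the group-norm profile;
  exact ties (probability zero for continuous data) fall back to the nearest
  attainable count during fitting.
- The multivariate-outcome (`q > 1`) alternation is a heuristic without a
  monotone objective guarantee (as is standard for normalized sparse PLS).
- Only disjoint variable groups are supported; overlapping group structures
  and group-subgroup (two-level) penalties are out of scope.
- The comparators use permutation/Bonferroni p-values, so their power is not
  directly comparable to implementations with exact analytic nulls.
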