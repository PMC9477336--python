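# Methods

## The question

The dichotomous Rasch model, P(X_pi = 1) = logistic(θ_p − b_i), assumes
local independence: conditional on θ the item responses are independent.
Violations come in two flavours. *Trait dependence* (TD) is hidden
multidimensionality — item subsets share a subset-specific trait on top of
the common one. *Response dependence* (RD) is direct statistical
dependence — answering one item changes the effective difficulty of
others. The package asks whether the global fit indices of the
Rasch-equivalent one-factor categorical model (CFI, TLI, RMSEA under
limited-information, diagonally weighted estimation) register these
violations, and how they compare to PCAR's first eigenvalue, with
parameter-recovery RMSE as the yardstick for how much the violation
actually hurts.

## Generating models

**TD.** For item i in subset s, P(X_ip = 1) = logistic(θ_ps − b_i) with
θ_ps = θ_p + c·θ′_ps. All traits are independent standard normal, so
corr(θ_ps, θ_pt) = 1/(1+c²): 1.0, 0.5, 0.2 at c = 0, 1, 2.

**RD.** The first ("halo") item of each subset follows the ordinary Rasch
model. Every other item j of the subset uses difficulty b_j − d if the
halo response was 1 and b_j + d if it was 0. The shift lives on the logit
difficulty scale; d = 0 recovers ordinary Rasch data. All dependent items
condition on the halo only, not on their immediate predecessor.

**Difficulties.** The I difficulties are equally spaced on [−2, 2]
inclusive (b_k = −2 + 4(k−1)/(I−1)). The ascending grid is cut into
consecutive blocks, one per subset, and each block is rotated so its
maximum leads: the first item of every subset is its hardest, and under RD
that item is the halo. The assignment of grid values to subsets is a
design choice; contiguous blocks keep the subsets' difficulty ranges
comparable.

**Subset structure.** The study design keeps **six dependent subsets at
every test length** — 5 items per subset at I = 30, 10 at I = 60. This is
the configuration under which the study's two signature findings coexist:
the PCAR first eigenvalue grows with test length (the within-subset
residual block grows from 5 to 10 items, lifting the leading eigenvalue
from ≈1+4ρ_w toward ≈1+9ρ_w) while CFI/TLI stay put (the *fraction* of
item pairs inside subsets is nearly the same at both lengths, ≈14–15%, so
the relative misfit of the equicorrelation model barely moves). Scaling
the number of subsets with length instead (fixed subset size 5) makes V1
nearly length-invariant and CFI length-dependent — the opposite pattern.
`SimulationCondition` accepts any subset size; `StudyConfig` holds the
number of subsets at six.

**Degenerate draws.** A replication in which any item comes out all-0 or
all-1 (which would break both the tetrachorics and conditional ML) is
discarded and redrawn from the next derived seed, with the count recorded.
At N ≥ 250 and |b| ≤ 2 this is rare.

**Seeding.** Every replication's seed derives from
SeedSequence([base_seed, condition_index, replication_index]) and is
stored in its record, so single rows are independently regenerable and a
whole run is bit-reproducible.

## Estimation pipeline

**Tetrachorics.** Thresholds are τ_i = Φ⁻¹(P(X_i = 0)). Each pairwise
correlation is the two-stage MLE: with thresholds fixed, ρ̂ solves
Φ₂(τ_i, τ_j; ρ) = p₀₀, found by vectorized bisection to ~1e-15 on
ρ ∈ (−0.99995, 0.99995). Rectangle probabilities use the Owen's-T
representation of the bivariate normal CDF (machine-precision accurate;
verified against scipy's integrator). Tables with a zero cell get 0.5
added to every cell; that pair's thresholds come from the corrected
margins. Because the one-parameter fit reproduces the 2×2 table exactly,
observed and expected information coincide, and the asymptotic variance of
ρ̂ is 1/(N·φ₂²·Σ 1/π_ab) with φ₂ the bivariate density at the thresholds.
If the assembled correlation matrix has an eigenvalue below 1e-8 it is
clipped and rescaled to unit diagonal, and the record is flagged.

**DWLS fit.** The target model is the one-factor model with all loadings
1 and factor variance ψ free; its implied correlation is σ(ψ) = ψ/(1+ψ)
for every pair, so the discrepancy F(ψ) = Σ_k (r_k − σ(ψ))²/w_k is
one-dimensional. Weights w_k are the asymptotic variances of √N·r_k.
Minimization is bounded scalar search on ψ ∈ (1e-6, 100] with tolerance
1e-10, with a grid-and-polish fallback if the minimizer touches a bound.
Thresholds are saturated and contribute nothing. The baseline model sets
every correlation to zero: F_b = Σ r_k²/w_k. Degrees of freedom:
df_t = I(I−1)/2 − 1, df_b = I(I−1)/2.

**Adjusted χ².** N·F is asymptotically a weighted sum of χ²(1) variables
with weights the eigenvalues of UΓ (U the DWLS residual-weighting matrix,
Γ the asymptotic covariance of the correlations). The statistic matches
the first two moments of that sum to a χ² reference (Satterthwaite
`mv_adjust`, default, or `scaled_shifted`), with Γ approximated as
diagonal. With Γ's diagonal equal to the weights, UΓ is a projection and
both variants reduce exactly to χ² = N·F_min on the model df — the code
computes the traces explicitly so a non-diagonal Γ can be supplied. Under
the null (c = 0, N = 1000, I = 30) the statistic's empirical 0.05-level
rejection rate is ≈0.08: the mean is right (the weights are consistent
variance estimates) while the ignored covariances between pairs sharing an
item inflate the variance somewhat. RMSEA's N is the number of persons of
the analyzed matrix; TLI is not truncated; CFI's max(·,0) construction
bounds it in [0,1], with CFI = 1 when both excesses are non-positive.

**Calibration.** Item difficulties are conditional ML: the conditional
likelihood given raw scores involves the elementary symmetric functions
γ_r of ε_i = e^(−b_i), computed by the summation (convolution) recursion
in linear space — with sum-zero-centred difficulties the coefficients stay
many orders of magnitude below float64 overflow even at I = 60, and the
leave-one-out table needed for the score comes from forward/backward
prefix polynomials in O(I³). The concave negative log-likelihood is
minimized by L-BFGS-B over I−1 free parameters (the last difficulty is
minus their sum); the gradient is s_i − Σ_r n_r·E[X_i | r]. Persons with
zero or perfect raw scores carry no conditional information and drop out
of the item fit, but are retained for ability estimation: Warm's weighted
likelihood estimator (root of r − ΣP + J/(2W)) is finite at extreme
scores, so Eq-style RMSEs keep their full N. Calibration is on the logit
scale throughout, so θ̂ and b̂ compare to the generating parameters with
no scale constant; difficulties are sum-zero identified and both
difficulty vectors are centered before RMSE_b.

**PCAR.** Standardized residuals z_pi = (x_pi − P_pi)/√(P_pi(1−P_pi))
with P from the logit calibration (probabilities clamped to
[1e-10, 1−1e-10]); V1 is the largest eigenvalue of their I×I Pearson
correlation matrix (eigenvalues sum to I). Covariance-matrix PCA is an
option; no rotation, no retention rules.

## Study aggregation

One tidy record per replication (condition, indices, RMSEs, V1, flags).
Pooled Pearson correlations of each index with each RMSE are computed
within LD type across all magnitudes, lengths and sample sizes — matching
the one-number-per-LD-type layout of the reference table — with Fisher-z
95% CIs. Per-cell means/SDs and the proportions of CFI/TLI above 0.95 per
magnitude are also emitted. Replications flagged non-convergent are
excluded from aggregates and counted; in practice none arise at the study
sample sizes.

## Problem sizes

The shipped test suite and acceptance script run the grids at reduced
replication counts — 50 per cell for the pooled correlations, 100 per
cell for condition means and threshold proportions (the full-scale design
uses 1000). At these counts the Monte-Carlo standard error of a cell mean
of CFI is ≈0.002–0.004 and of V1 ≈0.02, comfortably inside the tolerances
the checks use, and a full run takes minutes on one CPU.

## What the generator does and does not emulate

The generators produce exactly the stated TD/RD mechanisms with known
ground truth, which is what makes recovery RMSE computable. Real data
differ in ways deliberately outside scope: polytomous responses, missing
data, guessing/discrimination variation, dependence magnitudes varying
across subsets, non-normal trait distributions, and item-level LD
diagnostics (Q3, infit/outfit, DIF). Passing tests therefore demonstrate
the behaviour of the indices under these controlled violations, not their
behaviour under every real-world misfit.

## Known limitations

* The χ² adjustment uses a diagonal Γ; the statistic's null distribution
  is slightly over-dispersed (see above), which the fit indices — built
  from χ² *differences* against a hugely misfitting baseline — barely
  notice.
* Under RD, the generating equations produce genuinely anisotropic
  tetrachorics (halo–dependent pairs far above between-subset pairs — at
  d=1 roughly 0.73 vs 0.32 in the population). The DWLS discrepancy
  against the one-parameter equicorrelation model detects this, so here
  CFI/TLI degrade with d (≈0.85–0.92 across RD cells) rather than staying
  near 1 as the reference results this package checks against report; the
  pooled RD correlation of CFI with RMSE_b is correspondingly stronger
  than its reference value. A full-covariance (influence-function) Γ was
  prototyped and does not remove RD misfit either, while it does degrade
  the TD length-invariance, so the diagonal form is kept. Directions of
  all pooled correlations, and the TD results in full, reproduce.
* Tetrachoric agreement with other implementations is claimed to ~1e-3
  (the pairwise grid-oracle tolerance), not bit-for-bit.
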