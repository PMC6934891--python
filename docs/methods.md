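# Methods

This note documents the statistical model behind `phyloexpr`, the
estimators it implements, the numerical choices made where the design was
open, and what the simulation-based tests do and do not establish.

## The stationary OU model

Expression of a gene in a given tissue is modelled as an Ornstein–Uhlenbeck
diffusion: mutational drift with variance rate σ² pulled toward an optimal
level μ by stabilizing selection of strength w (Gaussian fitness
exp(−w(x−μ)²/2); the exponent is negative so that fitness is maximized at
μ).  With effective population size Nₑ, the population-scaled parameters
are the conservation strength W = 2Nₑw and the evolutionary rate β = Wσ².
Conditional on a parent value x₀, after time t

    E[x | x₀]   = x₀·e^(−βt) + μ·(1 − e^(−βt)),
    Var[x | x₀] = (1 − e^(−2βt)) / W.

The *stationary* assumption — the tissue originated long before the root
of the species tree — puts the root itself in the stationary law
N(μ, 1/W).  Every node of the phylogeny then has mean μ and variance 1/W,
and the covariance between any two nodes at path time d is e^(−βd)/W.
This matrix is independent of root placement, which the test suite checks
by rerooting.  The tissue-origin time is deliberately *not* a parameter:
the stationary limit is hard-coded.

Working scale: correlations and all OU quantities are computed on
log2-transformed expression (log2(x+1) by default), which stabilizes
variances and is closer to the Gaussian OU assumption than raw TPM/RPKM.
A flag allows raw values; the simulator generates directly on the analysis
scale (its output can be negative, and is tagged accordingly).  Whether
the correlation should be taken on raw or log values is genuinely open;
both are exposed and the worked reproductions take r₁₂ as given, so the
choice affects only full-pipeline runs.

## Expression distances and π

Among genes the optimum varies: μ_g ~ N(μ, V_μ).  The total stationary
variance is V_T = 1/W + V_μ and the between-species correlation of a
random gene is r₁₂ = π + (1−π)e^(−2βt) with π = V_μ/V_T.  Inverting this
curve gives the three distance estimators (Pearson 1 − r₁₂; constant-μ
−ln r₁₂; variable-μ −ln[(r₁₂−π)/(1−π)]), all approximating D₁₂ = 2βt, and
ordered Pearson ≤ constant-μ ≤ variable-μ on their common domain.
Neglecting optimum variation biases the constant-μ estimator downward —
materially so for D₁₂ ≳ 0.5, which the acceptance tests demonstrate at
true 2βt = 0.7, π = 0.4.

**π estimation.** π and a shared β are fitted per tissue by bounded
nonlinear least squares of r_ij = π + (1−π)e^(−β·d_ij) over all species
pairs, with d_ij the tree path time, 0 ≤ π < min r_ij and β ≥ 0 (three
starting points, best fit kept; boundary solutions flagged).  This is the
package's interpretation of "estimable from n ≥ 3 species": the decay
curve is a two-parameter function through the (d_ij, r_ij) cloud, so at
least three species (three pairs) — and, importantly, *at least two
distinct divergence times* — are needed.  On a star phylogeny all pairs
are equidistant and (π, β) are confounded; the fit will sit at a boundary
and should not be trusted (it is flagged).

**Undefined distances.** r₁₂ ≤ 0 (constant-μ) or r₁₂ ≤ π (variable-μ) is
beyond the resolvable range; such entries are flagged NaN, never silently
clipped, and tree building refuses matrices containing them.  π is always
estimated and applied per tissue, never pooled.

**Bootstrap.** Standard errors come from resampling orthologous genes with
replacement (default B = 100, one RNG stream per matrix) and taking the
per-entry SD across replicate distance matrices.

**Rates.** A distance converts to a per-year rate as β̂ = D₁₂/(2t) given a
divergence time t.

## Ancestral inference

Under the stationary model, an ancestral value y and the tips x of a gene
are jointly multivariate normal, so E[y|x] = b₀ + Σbᵢxᵢ with
b = Cov(y,x)·Cov(x,x)⁻¹ and b₀ = μ(1 − Σbᵢ).  The coefficients depend
only on the tree and (β, W) and are obtained by dense linear solves —
O(n³) in the species count, trivial at the dozens-of-species scale this
package targets.  The posterior variance Var(y) − b·Cov(x,y) is reported
per node (constant across genes sharing parameters).

Two facts worth stating because intuition suggests otherwise:

- Σbᵢ may exceed 1.  Tips are *attenuated* signals of the ancestor
  (E[xᵢ|y] = μ + (y−μ)e^(−βt)), so conditioning de-attenuates: with many
  concordant tips the estimate can legitimately overshoot the common tip
  value away from μ.  Σbᵢ → 1 only in the Brownian-motion limit (β → 0
  with β/W fixed), where the estimate reduces to the classical
  pruning/weighted-average reconstruction — verified against an
  independent Felsenstein-pruning oracle.
- The weights are non-negative on ultrametric trees (checked numerically
  over random clock trees), and a profile constant at μ is reconstructed
  as exactly μ.

Per-gene plug-ins for empirical Bayes: μ_g is the gene's across-species
mean (a grand-mean alternative is available), β comes from the π fit, and
the per-gene W from the conservation module below.  Whether these should
instead be fitted jointly per gene is not settled; the plug-in scheme is
this package's documented choice.

## Strength of expression conservation

Gene k's profile is x_k ~ MVN(μ_k·1, corr/W_k) with corr_ij = e^(−βd_ij)
and gene-specific W_k ~ Gamma(α, λ).  The phylogeny-corrected variability

    Q(x_k) = (x_k − μ_k·1)ᵀ corr⁻¹ (x_k − μ_k·1)

reduces to the plain sum of squares on a star tree.  Conjugacy gives the
posterior W|x_k ~ Gamma(α + m/2, λ + Q/2), whose mean is a/(c+Q) with
a = 2α + m, c = 2λ.  Because μ_k is plugged in rather than integrated out,
one degree of freedom is consumed: m = n − 1 by default (`df_correction`
flag restores m = n; with it off the constants read a = 2α + n).  The
identification is unit-tested against numerical quadrature of the
conjugate posterior.  The plug-in is the arithmetic tip mean; on trees
whose correlation structure is equicorrelated this coincides with the GLS
mean and the χ²_{n−1} sampling law of Q·W is exact, otherwise it is an
approximation.

Hyperparameters (α, λ) maximize the closed-form marginal likelihood of Q
(a beta-prime-type compound of χ²_m and the gamma prior), with
moment-matched starting values, L-BFGS-B on log-parameters, and bounds
α ∈ [10⁻³, 10⁶].  Near-constant W across genes drives α̂ to the upper
bound; such fits are flagged `near_degenerate` rather than reported as
meaningful.  At least 50 genes are required.  Posterior W is monotone
decreasing in Q, so gene rankings by conservation and by variability are
exact mirror images.  The all-genes versus expressed-genes filter
(raw value > 1 in ≥ 1 sample of every species, by default) changes the
fitted hyperparameters but not the interface; running both and comparing
is recommended practice.

## Tree inference and rate tests

- **NJ**: standard Saitou–Nei agglomeration (via scikit-bio, cross-checked
  in tests against dendropy's independent implementation); exact on
  additive matrices; negative branch lengths kept with a warning.
- **Bootstrap support**: genes resampled with replacement, distances and
  NJ recomputed; support is the percentage of replicates containing each
  non-trivial bipartition of the point tree; replicates with undefined
  distances are dropped from the denominator.
- **Least-squares mapping**: branch lengths on a fixed (derooted) topology
  minimize Σ(D_ij − path_ij)² subject to non-negativity, solved by NNLS on
  the path-incidence system; rank-deficient systems are refused; the
  pinned-at-zero KKT behaviour is tested against a bounded-least-squares
  oracle.
- **Relative rate test**: Δ_AB = D_AC − D_BC with outgroup C.  The paired
  gene bootstrap (genes resampled jointly so the two distances stay
  correlated) yields SE(Δ); z = Δ/SE is referred to a standard normal,
  two-sided.  Calibration: empirical type-I error 0.038 at nominal 0.05
  over 500 simulated equal-rate trios (1,000 genes each) in the acceptance
  suite.
- **Quartet decomposition**: for two species × two tissues, the six
  pairwise distances determine exactly (6 equations, 6 unknowns) four
  pendant edges plus two internal split lengths — γ_E across the species
  split and γ_D across the tissue split.  The γ estimates are the split
  contrasts given in the code; pendants come from solving the full linear
  system.  Negative estimates are reported unclipped and flagged.  Whether
  the source framework intended least-squares network estimates or
  model-based quantities is not determinable here; the exactly-determined
  split-system solution is this package's interpretation.

## The simulator and what tests show

`simulate_expression` draws per-gene optima μ_g ~ N(μ, V_μ), per-gene
W_g ~ Gamma (optional), a stationary root value, and then exact OU
transition-kernel samples down every edge — no Euler discretization, hence
no discretization tolerance.  Given a seed, output is deterministic.

Test problem sizes were chosen so that sampling error is well below the
assertion tolerances: 5,000 genes × 6 species × 20 replicates for π
recovery (observed spread ≈ ±0.035 around the true 0.4); 10,000 genes for
gamma hyperparameter recovery (α within ±0.3, λ within ±0.2); 20,000 genes
× 5 taxa × 20 replicates for NJ consistency; 500 trios for rate-test
calibration.

The generator emulates the *model's* world: Gaussian log-scale expression,
a single shared β, independent genes, no measurement error, and no
among-tissue correlation.  Real RNA-seq adds count noise, normalization
artefacts, correlated genes (co-expression), and lineage-specific optimum
shifts, none of which are simulated — so passing tests certify the
estimators under their own assumptions, not robustness to violations of
them.  Non-stationary OU (shifting optima), multi-optima models, and
likelihood/parsimony tree search are out of scope.

## Degenerate inputs and tie-breaking

Zero-variance sample columns are refused with the offending column named;
duplicated zero-length tips make the tip covariance singular and raise a
jitter suggestion; NJ ties resolve deterministically (fixed agglomeration
order), and all bootstrap paths take explicit seeds.  Ultrametricity is
checked to a relative tolerance of 1e-8; time trees must carry a length on
every non-root edge.
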