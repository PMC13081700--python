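# Methods

## Model and hypotheses

At each analyzable location `v = 1…V` the package fits, across `N` subjects,

    Y_v = β₀ᵥ + (nuisance coefficients) + β_target,v · x_target + ε_v

by ordinary least squares and summarises the brain–phenotype association with
the target t-statistic `T_v = β̂_target,v / SE(β̂_target,v)` (alternatively the
partial Pearson correlation `r = t/√(t²+df)` or the unsigned `F = t²`, with
`df = N − (1 + #nuisance + 1)` residual degrees of freedom). Locations with
zero residual variance are flagged invalid and dropped consistently from the
observed and every permuted map, so the in/out set sizes `m`, `n` are constant
across permutations.

Enrichment of a network `N ⊂ {1…V}` is a composite, intersection–union
hypothesis: the null is kept unless in-network associations are **both**
stochastically greater than out-of-network associations **and** greater than
zero in mean (right side; mirrored for a left side). Rejecting only when both
component tests reject is what protects the procedure in the two regimes
where purely competitive or purely self-contained tests fail — globally
nonzero effects with no in/out contrast, and zero in-network effects with
negative out-of-network effects.

## The ODC statistic and the adaptive truncation

With `G_m` the in-network and `F_n` the out-of-network empirical CDF, the
plug-in ordinal dominance curve is `ODC(t) = F_n(G_m⁻¹(t))`, where `G_m⁻¹` is
the left-continuous generalised inverse and `F_n` is right-continuous with
ties counted as ≤. The curve is constant on `((i−1)/m, i/m]` with height
`c_i = F_n(y_(i))`, and the truncated shifted integral

    D_γ = Σᵢ c_i · |((i−1)/m, i/m] ∩ (γ, 1]| − (1 − γ²)/2

is evaluated exactly (a γ inside a step splits that step's contribution; no
quadrature). A documented consequence of the tie convention: identical in- and
out-of-network samples give `D₀ = 1/(2m)`, not 0.

Null maps come from Freedman–Lane permutation: every `Y_v` is regressed on
the reduced model (intercept + nuisance), the residual rows are permuted by a
single subject reordering shared across locations, the reduced fits are added
back and the full model is refit. Sharing the reordering preserves the map's
spatial correlation under the null, which is the property that makes the
downstream enrichment p-values valid under arbitrary spatial autocorrelation.
Permutations are drawn uniformly (identity not excluded, duplicates allowed);
a stratified scheme restricted to within-stratum reorderings is available for
family-structured samples.

Per γ on the fixed grid (default 0, 0.05, …, 0.95) an intermediate p-value
`p_γ = (1 + #{D_γ⁽ᵏ⁾ ≥ D_γᵒᵇˢ})/(K+1)` is computed with inclusive ties, and
`q = min_γ p_γ` (ties broken toward the smallest γ, which is also the value
reported as the selected truncation). Because a minimum of p-values is
anti-conservative, `q` is calibrated against its own leave-one-out null:
each permuted map `k` is treated as observed against the other `K−1`,
`p_γ⁽ᵏ⁾ = (1 + #{k₁≠k : D_γ⁽ᵏ¹⁾ ≥ D_γ⁽ᵏ⁾})/K`, `q⁽ᵏ⁾ = min_γ p_γ⁽ᵏ⁾`
(computed by per-γ ranking in O(K log K) and verified against the quadratic
double loop). The two printed denominators (K+1 for the observed pass, K for
the leave-one-out pass) are kept exactly as defined. Finally

    p_diff = (1 + #{q⁽ᵏ⁾ ≤ q})/(K+1),
    p_zero = (1 + #{T̄_N⁽ᵏ⁾ ≥ T̄_Nᵒᵇˢ})/(K+1),
    p      = max(p_diff, p_zero).

All permutation p-values use the (1+count)/(K+1) form, so `p ≥ 1/(K+1)` and
no p-value can print as zero. `p_zero` compares against the permutation null
of the in-network mean; a nonzero reference mean is deliberately not
supported. Networks with fewer than 100 in-network locations trigger a
warning, as the ODC estimate becomes unstable for small `m`.

**Left-sided tests.** The implementation negates every association map and
runs the right-sided machinery. For `p_zero` and for γ = 0 this is identical
to flipping the comparison inequalities; for γ > 0 it additionally mirrors the
truncation onto the correct (negative) tail, and it makes left- and
right-sided results exactly symmetric under sign flip of the data — a
property the flipped-inequality shortcut does not have. The standalone
`gamma_p_values` / `null_q_distribution` / `p_zero` utilities still accept a
`side` argument implementing the literal flipped inequality for callers that
orient their own statistics.

## Comparator tests

* **Thresholded Fisher's exact (RIGEA).** Counts `s` significant in-network
  and `S` significant total statistics at a configurable threshold (default
  1.96; negated for left-sided tests) and returns the exact hypergeometric
  upper tail, computed with integer arithmetic.
* **Spin test.** Difference-in-means enrichment score against spherically
  rotated surrogate maps; x/y/z angles uniform on [0°, 360°), the right
  hemisphere receiving the same x-rotation and negated y/z rotations to keep
  contralateral symmetry. Values are reassigned by nearest rotated vertex
  within hemisphere (exact distance ties, measure-zero for float coordinates,
  fall to the KD-tree's deterministic choice); vertices that receive a
  rotated-in medial-wall value are discarded from score computation.
* **Variogram-matched surrogates.** The map is permuted across locations,
  smoothed with Gaussian distance kernels over a geometric width grid, and
  each smoothed variogram (25 equal-count distance bins, optional pair
  subsampling) is regressed onto the observed variogram; the width minimising
  the regression SSE wins and the fitted transform is applied (values scaled
  by √slope, the intercept realised as added white noise). Surrogate values
  are not rank-matched back to the original values.
* **Weighted-KS.** A GSEA-style running sum over locations ranked by
  statistic, in-network steps `+|T_v|/Σ_N|T|` (weight exponent 1, the GSEA
  default) and out-of-network steps `−1/n`; the score is the signed maximum
  deviation and the p-value compares it against phenotype-permutation null
  maps. The exact weighting of the published NEST package is defined in
  external work; this implementation is a documented approximation and
  comparator conclusions are validated qualitatively, not numerically.

None of the comparators aims for bit-compatibility with BrainSpace,
BrainSmash, or NEST.

## Synthetic data generator

The generator emulates the benchmark's structure on a 50×50 toroidal grid
(V = 2500) or a Fibonacci-sampled sphere:

* **Networks.** Contiguous patches grown by randomised BFS; the default
  partition has a 400-location network in two patches (default-mode-like), a
  250-location patch (motor-like) and a 150-location patch (visual-like),
  with everything else background.
* **Noise.** Per subject, white Gaussian noise smoothed with a wrap-around
  Gaussian kernel and rescaled so the marginal variance at every location is
  exactly σ². Two regimes: *low SA* (σ² = 0.09, baseline β₀ = 3,
  cortical-thickness-like) and *high SA* (σ² = 0.36, β₀ = 0,
  task-activation-like). Kernel widths are 0.5 and 1.5 grid units: width 1.5
  gives a correlation FWHM of ≈3.5 cells, about a quarter of the diameter of
  the default network patches, matching the proportion between the smoothness
  of activation maps (FWHM ≈ 15 mm) and the extent of a cortical functional
  network (≈50–80 mm); the low-SA width is threefold smaller, emulating the
  much weaker autocorrelation of unsmoothed morphometry.
* **Effects.** `Y_iv = β₀ + 0.05·x₁ − 0.05·x₂ + β₃ᵥ·x₃ + ζ_iv` with
  `x₁ ~ Bernoulli(0.5)`, `x₂, x₃ ~ N(0,1)`; the matched analysis model is
  `1 + x₁ + x₂ + x₃`. Four β₃ configurations: directional null (in 0 /
  out −0.03), equal null (0.04 everywhere), shifted alternative (in 0.06 /
  out 0.04), and variance alternative (in ~ Γ(2, 40), out ~ Γ(20, 400),
  shape–rate parameterisation — the only reading under which both have mean
  0.05 while the in-network field is tenfold more variable). Gamma fields are
  redrawn independently per location and per replicate, so the "true"
  associations vary across space in every simulation.

**What the generator does *not* emulate.** Real analyses resample actual
cortical residuals, whose autocorrelation is non-stationary, long-ranged and
anatomically structured; the smoothed Gaussian fields here are stationary and
isotropic, and V = 2500 with networks of 150–400 locations is an order of
magnitude below real surface meshes (V ≈ 19k–57k, networks of thousands of
vertices). Level-control results transfer — permutation validity under
exchangeability does not depend on the noise field — but absolute power does
not: the ODC statistic's precision grows with the number of (effectively
independent) in-network locations, so power in the variance-enrichment regime
at this scale (≈15–25 % per network at N = 200, rising with N) sits far below
the >88 % reported on full-resolution data, even though the qualitative
orderings (power ≫ mean-difference surrogate tests, monotone in N) hold.
Passing simulation tests therefore certify calibration and relative ordering,
not absolute power on real data.

## Numerical and design choices

* Target t-statistics are computed through the Frisch–Waugh–Lovell identity
  (orthonormal basis of the reduced model plus the residualised target), one
  small GEMM per permutation; the observed map goes through the identical
  kernel with the identity permutation, so Freedman–Lane with the identity
  reordering reproduces observed statistics bit-for-bit. Exactness against
  direct `lstsq` fits is tested to 1e-10.
* Degeneracy floors: a location is degenerate when its values are constant or
  when the target absorbs the reduced-model residual to relative precision
  1e-12; locations whose reduced-model residual is itself numerically zero
  (noise-free nuisance combinations) get t = 0 rather than 0/0.
* Permutation p-values use inclusive ties throughout (conservative).
* One permutation-null ensemble per map is reused across all networks tested
  on it, so the BH-FDR correction across networks operates on p-values sharing
  a common null; FDR is the only multiplicity correction offered.
* The rejection-rate driver derives per-replicate RNGs from a master
  `SeedSequence`, making every study reproducible from (config, seed); output
  files are byte-identical across reruns.
* Default study sizes (V = 2500, K = 200, 150–1000 replicates depending on
  the check; the test suite runs 60–250 replicates per condition) are the
  package's desk-scale defaults; `docs` report all problem sizes alongside
  results.

## Known limitations

Asymptotic (Brownian-bridge) inference for the ODC statistic is out of scope —
inference is purely permutation-based. Weight functions other than the step
`1{t > γ}` are not implemented. Volumetric and CIFTI inputs are not supported.
The spin test requires spherical vertex coordinates for both hemispheres; the
variogram surrogates assume Euclidean distances on the supplied coordinates
(geodesic distances are the caller's responsibility for meshes).
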