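# Methods

## Acquisition schemes

Three IVIM protocols are provided as presets, all built from the same
drift-robust looping rule: at global step t the b-value index is
`t mod len(b_sequence)` and the direction index is
`(t + t // lcm(len(b_sequence), n_directions)) mod n_directions`. The extra
unit offset per completed lcm cycle guarantees that every (b, direction)
combination is covered even when the sequence length shares factors with
the direction count (the looping rule is otherwise ambiguous; this is the
one consistent reading that achieves full coverage). b = 0 entries carry no
direction but consume a direction slot, so b = 0 is effectively acquired as
repetitions. The canonical direction succession is x, y, z, −x, −y, −z.

* **sIVIM**: b-sequence 0, 200, 800, 200, 0, 200 s/mm² (2/3/1 repetitions
  of 0/200/800 per cycle) × 6 cycles = 36 volumes.
* **diffusive**: the 10 b-values 0–800 s/mm² in "low–high" order
  (0, 800, 5, 500, …) × 6 cycles = 60 volumes.
* **ballistic**: 7 b-values 0–200 s/mm² in low–high order × 6 cycles, as
  two scans — flow-compensated (FC, c = 0) and non-flow-compensated
  (NC, c > 0 for b > 0) — of 42 volumes each.

The per-volume interval defaults to 7.5 s, which reproduces scan durations
of 4.5, 7.5 and 10.5 min for the three protocols. The NC flow-encoding
factors are a synthetic table c(b) = 0.3·√(b/200) s/mm: for a fixed bipolar
waveform with varying gradient amplitude, b ∝ G² and c ∝ G, and 0.3 s/mm at
b = 200 s/mm² is representative of published bipolar ballistic-IVIM
protocols. c values are inputs (cval sidecar), never derived from waveform
timings.

The *ordered* (drift-sensitive) variant of any scheme sorts by ascending b
with directions in direct succession, reassigning indices and times.

## Synthetic phantom

The phantom is an ellipsoidal "brain" (semi-axes 0.47 of the grid) with
piecewise-smooth parameter maps drawn from seeded Gaussian random fields
(smoothing σ = 3 voxels) rescaled exactly onto healthy-brain ranges:
D ∈ [0.6, 1.0] µm²/ms, f ∈ [0.01, 0.06], D* ∈ [5, 30] µm²/ms,
v_d ∈ [0.5, 3] mm/s, S0 ∈ [500, 1500] a.u. Three disjoint cubic ROIs sit at
spatial extremes mimicking prefrontal white matter (anterior), centrum
semiovale (superior-central) and cerebellum (posterior-inferior). Axes are
RAS; the default voxel size is 2 × 2 × 5 mm.

Forward signals use the biexponential representation for the sIVIM and
diffusive regimes (so the segmented estimator's bias on biexponential data
can be studied) and the flow-encoding representation for the ballistic
regime. b is stored in s/mm² and converted (×10⁻³) to ms/µm² before
multiplying by D, so printed units stay verbatim at all interfaces;
c (s/mm) times v_d (mm/s) is dimensionless.

### Drift generator

Drift is multiplicative and lives in exactly the model family the
spatiotemporal correction estimates. Given target drift rates (% per 5 min)
at named poles (ROI centroids), the generator builds

    F(n; x,y,z) = 1 + (r(x,y,z)/100) · [(1−κ)·u + κ·u²/u_last],

with u = n·Δt/300 the elapsed time in 5-minute units, κ the temporal
curvature fraction (default 0.3, i.e. 30 % of the end-of-scan drift is
carried by the quadratic term), and r an affine spatial profile. F is 1 at
n = 0 everywhere, and the end-of-scan drift evaluated at each pole centroid
equals the target exactly.

The pole constraints leave free directions in the affine profile. Those
null-space directions are calibrated (coarse grid search plus simplex
polish) so that the masked **median-signal** trajectory over the b = 0
volumes is flat. This makes pole drift a genuinely spatial effect that a
whole-mask (global) summary cannot see, rather than an artifact of how the
random S0 texture happens to correlate with the drift gradient; it is what
"antisymmetric drift with near-zero whole-mask drift" means operationally,
since every drift summary in the package is a median-signal quantity. A
side effect is that the unweighted per-voxel median of the field's drift
may sit slightly off zero. Profiles are kept within ±20 %/5 min.

### Noise

Rician by default (magnitude MRI): √((S+e₁)² + e₂²) with independent
zero-mean Gaussians of standard deviation σ; a truncated-Gaussian option
exists. σ is conveniently set relative to the masked median b = 0 signal
(`sigma_for_snr`); the studies in the test suite use SNR 100. All
randomness flows through explicit integer seeds.

What the phantom does **not** emulate: anatomy, partial volume, motion,
eddy currents, susceptibility distortion, or spatially correlated noise.
Passing tests therefore demonstrate correctness of the estimation
machinery under the stated models, not robustness to real-scanner
artifacts outside the drift model family.

## Drift fitting

* **Global / voxelwise**: ordinary least squares of the quadratic in n on
  the b = 0 subset (whole-mask median signal, or per masked voxel). At
  least 3 b = 0 volumes are required. Voxels whose fitted polynomial is
  nonpositive anywhere in the scan are dropped from the correction mask
  with a logged warning.
* **Spatiotemporal**: voxelwise normalization to the first b = 0 volume,
  then iteratively reweighted least squares on the 81-term design with the
  Tukey biweight loss (tuning constant 4.685, MAD residual scale, at most
  50 iterations, tolerance 1e−8), via statsmodels' robust linear model.
  Spatial coordinates are affinely mapped to [−1, 1] over the mask bounding
  box and the temporal variable is normalized for conditioning; the stored
  coefficients are mapped back to the raw acquisition-index basis. If the
  initial least-squares fit is already exact to 1e−9 (noiseless in-family
  data), IRLS is skipped — its MAD scale is degenerate at zero residuals.
  The fit requires at least 5 × 81 masked b = 0 samples.

The correction field is the fitted polynomial divided by its value at the
first b = 0 acquisition, so it equals 1 there and corrected data keep the
scale of the start of the scan. IVIM estimates are invariant to this
normalization (S0 absorbs scale); it is recorded because the FC/NC
normalization downstream is not scale-free across scans. The correction is
applied to all b-values. The temporal variable is the acquisition index,
not wall time.

### Acquisition-order simulation

Spatiotemporally corrected data are permuted into ascending-b order and the
inverse correction is applied at the new indices, yielding an uncorrected
series as if the same drift had acted on a b-ordered protocol. Note that
re-correcting this series with the same model reproduces (a permutation of)
the corrected mixed data exactly — the only corrected ordered/mixed
comparison this construction admits — so after correction the two orderings
give identical estimates by design.

## IVIM estimation

Signals are direction-averaged with a geometric mean per unique
(scan, b, c) group (zeros floored to a configurable epsilon), which keeps
log-linearity for repeated b = 0/b = 200 volumes and mitigates
background-gradient cross terms. For the ballistic protocol the FC and NC
averages are each divided by their masked median b = 0 signal before being
concatenated.

* **sIVIM** is closed-form; f is clipped to [0, 1] with the out-of-range
  fraction logged; voxels with nonpositive signals are NaN. On
  biexponential input the segmented f slightly *under*estimates: the
  residual pseudo-diffusion signal at b = 200 s/mm² inflates the
  extrapolated intercept A, and f = 1 − A/S0 shrinks (verified by
  closed-form forward evaluation over the phantom ranges).
* **Diffusive** and **ballistic** fits run per voxel with scipy's
  trust-region-reflective bounded least squares (numeric Jacobian,
  tolerances 1e−12, at most 200 function evaluations). Bounds:
  D ∈ [0.1, 3.5] µm²/ms, D* ∈ [5, 100] µm²/ms, f ∈ [0, 0.5],
  v_d ∈ [0, 10] mm/s, S0 ∈ (0, 10 × max signal]. The D* lower bound of
  5 µm²/ms reflects the floor behavior observed in practice for
  pseudo-diffusion estimates; truth below the bound comes back clipped at
  the bound. Initialization is segmented: a monoexponential log-linear fit
  on b ≥ 200 s/mm² (ballistic: the upper half of the c = 0 b-values) gives
  D and the intercept, f starts at 1 − A/S(0), D* at 10 µm²/ms, v_d at
  1 mm/s. Non-converged or non-finite voxels become NaN and are excluded
  from ROI statistics. All three estimators are invariant to global
  rescaling of the input.

Goodness of fit is the per-voxel root-mean-square difference between model
and averaged data. The flexible diffusive biexponential largely absorbs
drift into its parameters (small residual change, systematic bias); the
rigid sIVIM and ballistic fits show drift as enlarged residuals — hence the
residual-contrast checks use the ballistic fit.

## Statistics

* Drift per ROI: 100·(median(S_last b0)/median(S_first b0) − 1)·300/Δt in
  % per 5 min; or the slope of a linear fit of ROI-median signal against
  time, with one intercept per encoding direction for b > 0 (fixed
  per-direction intercepts stand in for a random intercept — the slope
  point estimate is identical under balanced designs and avoids a
  mixed-model dependency), expressed as percent of the mean intercept.
* Repeatability: mean and absolute difference of the two repetitions' ROI
  medians, invalid voxels excluded.
* **Exact Friedman test**: χ²_F = 12/(nk(k+1))·ΣR_j² − 3n(k+1) with average
  ranks on ties; the permutation null enumerates all (k!)^n within-block
  rank assignments via a rank-sum convolution (states keyed by 2×-scaled
  integer rank-sum tuples), so the exact p is affordable well beyond naive
  enumeration. A configurable cap (default 10⁷ notional assignments) falls
  back to the χ² approximation with a logged note. On null data at n = 20,
  k = 3 the exact and asymptotic p agree to a few percent pointwise (the
  exact null is discrete).
* **Exact Wilcoxon signed-rank**: zero differences dropped, average ranks
  on tied magnitudes, two-sided p by enumerating all 2^n sign assignments
  (integer convolution; the null is symmetric about half the total rank
  sum). Normal approximation beyond n = 25.
* Representative-case selection ranks |value − column median| within each
  (ROI, scan) column and returns the (subject, repetition) with the lowest
  rank sum, ties broken by lowest indices.

Significance conventions: a Friedman gate at p < 0.05 before pairwise
signed-rank tests at p < 0.05.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run on 32 × 32 × 8 phantoms
(≈ 3600 masked voxels) with the full 36/60/84-volume presets; estimator
recovery uses 20-point truth grids and 500-voxel noise studies at SNR 100;
the acquisition-order experiment uses ten seeded phantoms with fitting
restricted to the frontal ROI. These sizes were chosen so each stage
completes in seconds while every estimate remains well-conditioned. Every
random quantity is derived from explicit seeds; repeated runs are
reproducible.

## Known limitations

* The drift family is second order in time and space; higher-order or
  per-slice drift, and drift–motion interactions, are out of scope.
* The spatiotemporal IRLS reports non-convergence but still returns the
  last iterate.
* The ballistic fit fixes D_b; misspecification propagates into f and v_d.
* Exact tests are limited by the enumeration cap; above it, p-values are
  asymptotic.
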