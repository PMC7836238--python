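# Methods

## Model and target

We observe N subject-level scalar fields on a 2-D or 3-D voxel lattice with
an in-domain mask,

    Y_i(s) = μ(s) + ε_i(s),   i = 1..N,

with i.i.d. mean-zero Gaussian errors of pointwise sd σ(s) and unspecified
spatial correlation ρ(s,t). The inferential target is the excursion set of
the Cohen's d field d(s) = μ(s)/σ(s) at a user-chosen threshold c,
A_c = {s : d(s) ≥ c}. The output is a pair of nested boolean maps
(upper CS ⊆ point estimate ⊆ lower CS) bracketing A_c with simultaneous
confidence 1 − α, plus the bootstrap critical value k that calibrated them.

## Estimators and small-sample constants

The summary fields are the voxelwise mean, sd and d̂ = mean/sd. **The sd
uses divisor N − 1 everywhere.** With that convention √N·d̂ is exactly
noncentral t with N − 1 degrees of freedom and noncentrality √N·d, and
d̂ = t/√N for the one-sample t statistic. (The divisor is genuinely
ambiguous in parts of the literature on this construction; N − 1 is the
choice that makes the noncentral-t characterization exact, and every
downstream constant here is consistent with it.)

From the noncentral-t law:

* bias factor C_N = √((N−1)/2)·Γ((N−2)/2)/Γ((N−1)/2), with the classical
  approximation (1 − 3/(4N−5))⁻¹ (relative error < 0.1% for N ≥ 10);
  evaluated via log-gamma differences so large N cannot overflow;
* finite-sample variance Var(d̂) ≈ a + b·d² with a = (N−1)/(N(N−3)) (the
  exact central-t value) and b = (8N²−17N+11)/((N−3)(4N−5)²) (obtained by
  inserting the C_N approximation into the exact second-moment formula).

The variance-stabilizing transformation (VST) is x ↦ α*·arcsinh(β*·x)
with

    α* = (N·b)^(−1/2),   b* = 1/α*,   β* = √(b/a) = (N(8N²−17N+11)/((N−1)(4N−5)²))^(1/2).

α* and b* are reciprocal powers of the same polynomial ratio (their product
is exactly 1); β* is fixed by the requirement that the transform's
derivative equal 1/√(N·Var(d̂)), which is what stabilizes the variance.
Asymptotically α* → √2 and β* → 1/√2, recovering the classical
√2·arcsinh(x/√2) stabilizer for an estimator with variance (1 + x²/2)/N.
The stabilized pivot also carries a second-order skewness offset
(a delta-method mean correction, the `vst_threshold` bracket term); its
calibration is pinned by simulation: the 90th percentile of the stabilized
pivot is within 2% of Φ⁻¹(0.9) for N ≥ 60 across d ∈ [0, 1.2] (tested).

## Residuals

The wild bootstrap needs residuals whose spatial covariance matches the
*limiting field of d̂*, not the error field. A first-order Taylor expansion
of (mean, variance) ↦ mean/sd gives

    R_i = (Y_i − Ȳ)/σ̂ − (Ȳ/(2σ̂))·((Y_i − Ȳ)²/σ̂² − m),

where the centering constant m is the empirical mean of (Y_i − Ȳ)²/σ̂²
(= (N−1)/N under the N−1 divisor). Centering on the empirical mean rather
than the constant 1 makes Σ_i R_i(s) = 0 hold exactly for every N and
either divisor convention; the mean-zero identity is treated as the binding
contract. Three standardizations are offered, one per algorithm: division
by the limiting sd √(1 + d̂²/2); division by the pointwise residual sample
sd σ̂_R = √(mean_i R_i²) (divisor N, so the standardized second moment is
exactly 1); and multiplication by the VST derivative
α*β*/√(1 + β*²d̂²). Plain standardized residuals (Y_i − Ȳ)/σ̂ are kept
only as an internal reference: a test demonstrates that their bootstrap
covariance converges to ρ(s,t) instead of the limiting-field covariance
(ρ + ρ²d²/2)/(1 + d²/2), which is why they are not a user-facing option.

## Boundary, bootstrap, and set construction

The plug-in boundary {d̂ = τ}, τ = c·(1 − 3/(4N−5))⁻¹, is located at
sub-voxel resolution on axis-aligned lattice edges (4-/6-connectivity);
an edge straddling the level contributes a point at fractional position
w = (τ − f(u))/(f(v) − f(u)). Exact ties give w ∈ {0, 1} (a zero-measure
event, handled deterministically); edges with an endpoint outside the mask
are skipped. For algorithm 3 the crossings and weights are computed on the
arcsinh-transformed field with the correspondingly transformed τ — a
monotone transform keeps the same crossing edges but moves the interpolated
positions, and the supremum being bootstrapped lives on that scale.

Residuals are linearly interpolated onto the boundary points. Each of B
bootstrap replicates draws N Rademacher signs (replicate-major from a
single seeded generator), forms G̃*(p) = √N · mean_i(s_i R̃_i(p)) / σ̂*(p)
with σ̂*(p) the **centered** sd (divisor N − 1) of the signed values — the
source procedure does not state whether the studentizer centers; we center,
matching the package-wide convention — and records sup_p |G̃*(p)|. Because
signs square to one, the second moment of the signed values is
sign-invariant, so σ̂* is computed from the signed mean alone without
materializing the signed residuals. k is the nearest-rank (ceil) (1 − α)
percentile of the B suprema: deterministic and conservative; at B = 5000
the difference from interpolated percentiles is negligible. Default
B = 5000.

The sets are thresholded decision fields (kept on the output for sub-voxel
assessment): d̂ − τ ∓ band for algorithms 1–2, and the transformed field
minus the VST threshold ∓ k/√N for algorithm 3. The point-estimate set uses
the bias-corrected threshold τ, which makes the nesting
upper ⊆ point ⊆ lower exact for algorithms 1–2 and holds for algorithm 3
in all practical regimes (the skew offset is O(1/N) while the band is
O(k/√N)). An empty estimated boundary (d̂ never approaches τ inside the
mask) legitimately occurs, e.g. under the complete null; no k can be
bootstrapped, so both CSs collapse to the point estimate and the result is
flagged degenerate with a warning rather than erroring.

## Synthetic data generator

The generator reproduces a standard simulation design for this method
family; its defaults are the study conditions, not tuning knobs.

* **Signals** (magnitude 1): a 2-D linear ramp rising 0 → 1 along axis 0
  with inclusive endpoints and no smoothing; a radius-30 disk centered in a
  100×100 grid smoothed with a 3-voxel-FWHM Gaussian (not rescaled after
  smoothing — its plateau keeps value ≈ 1); radius-5 and radius-30 spheres
  in 100³, smoothed then imagewise rescaled to max 1; and a four-sphere
  configuration where each phantom is smoothed and rescaled to peak 1
  individually, summed, and overlap clipped back to 1 so every phantom
  center sits exactly at the nominal magnitude. The four-sphere geometry
  (radii 5/8/10/12 voxels at symmetric centers on the 100³ grid, scaled
  with the grid) is fixed here once as a representative multi-cluster
  layout.
* **Noise**: white standard-normal noise smoothed by direct truncated
  Gaussian convolution (separable, truncation 4σ, zero padding outside the
  grid), then divided by the *exact* pointwise sd of the smoothed noise —
  computed by convolving a ones field with the squared 1-D kernels, which
  handles edge truncation exactly — and multiplied by the sd field:
  homogeneous 1, or rising linearly 0.5 → 1.5 along the last axis
  (variance consequently quadratic). With homogeneous sd the true d field
  equals the signal. FWHM defaults to 3 voxels (≈ 6 mm at 2 mm voxels, a
  typical analysis smoothness).
* **Axis convention**: the ramp runs along axis 0, the sd gradient along
  the last axis, keeping the two orthogonal.

What the generator does *not* emulate: non-Gaussian errors, spatially
varying smoothness, inter-subject misregistration, or missing data.
Passing coverage here therefore establishes correctness of the procedure
under its own Gaussian assumptions, not robustness to real fMRI noise.

## Coverage assessment

A trial covers iff (a) on the lattice, upper ⊆ A_c and A_c ⊆ lower, and
(b) at every interpolated point of the **true** boundary (edges where the
noise-free d field crosses c, weights from the true field), the linearly
interpolated upper decision field is ≤ 0 and the lower decision field is
≥ 0. Assessing on a discrete set of boundary points can miss sub-grid
violations, which biases empirical coverage upward — more so for long
boundaries and low confidence levels; the reported over-coverage of the
ramp design at the 80% level is expected behavior of this assessment, not
a defect of the sets. Upper-CS sensitivity is |upper ∩ A_c| / |A_c|,
the power-like operating characteristic; it errors on an empty A_c.

## Experiment harness and problem sizes

`run_experiment` aggregates per-(N, level, algorithm) coverage and mean
sensitivity with binomial MC standard errors into a tidy table. It is fully
seed-deterministic, and all algorithms/levels of a trial share the same
simulated sample (so algorithm contrasts are paired). Full study scale is
3000 trials × B = 5000 with N ∈ {30, 60, 120, 240, 480} and levels
{0.80, 0.90, 0.95}; the packaged acceptance runs use 200–300 trials and
B = 500, sizes chosen so the whole reproduction completes in minutes on one
CPU while keeping MC standard errors near 1–2 percentage points.

## Numerical and design notes

* Zero-variance (degenerate) voxels are excluded from the mask with a
  warning by default (real masks contain constant voxels at edges);
  an error mode is available.
* Residuals are never clipped; non-finite values abort with a diagnostic.
* `wild_t_bootstrap` draws all signs up front, so results do not depend on
  the internal batch size (beyond BLAS summation order).
* Bitwise reproducibility holds for fixed seeds end-to-end, including file
  outputs.
* The NIfTI layer accepts a 4-D stack or an ordered list of 3-D volumes,
  requires matching grids/affines (no resampling), and writes masks as
  uint8, d̂ as float32, with a JSON sidecar of all parameters.

## Known limitations

Gaussian-error theory only; one-sample designs only (no GLM contrasts);
a single threshold per bootstrap run; no FDR-style error control; no
surface (CIFTI) support. Sensitivity of the upper CS is intrinsically low
below ~100 subjects at c = 0.8 — the method is valid there but will
confidently localize few voxels.
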