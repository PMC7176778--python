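# Methods

## Model and procedure

A radial acquisition with `L` readout samples and `M` views is stored as a
complex matrix of spokes with the DC sample at row `L // 2`. The centered
1D inverse DFT of each spoke gives one parallel-beam projection (the
projection-slice theorem in discrete form); the stack is the sinogram
`p(n, m)`. Complex sinograms are reduced to magnitude before any
estimation or reconstruction — the estimator and FBP operate on real
data, and phase is discarded (a documented limitation, not an
approximation of it).

View filling works pairwise on adjacent measured views. The displacement
function `u(n)` relating `p₂(n) ≈ p₁(n + u(n))` is found by evaluating the
objective

    F(u) = [p₂(n) − p₁(n + u)]² + λ · [sign(Δp₂(n)) − sign(Δp₁(n + u))]²

at all `2N + 1` integers `u ∈ [−N, N]` and keeping the minimizer,
independently per radial index. This bounded exhaustive search replaces
iterative descent: the cost is proportional to `2N + 1` per index, and
there are no convergence questions. Intermediate views at fractions
`t = j/factor` are synthesized by sampling `p₁` at `x = n + t·u(n)` with
linear interpolation between the two neighboring integer positions;
`t = 0` reproduces the measured view bit-identically, and measured views
are never overwritten.

## Parameters

* `bound_N = 12` (dimensionless, radial samples). The search bound must
  cover the largest per-gap feature motion. In the packaged geometries the
  fastest feature trace moves ≈ 9 samples per measured gap, safely inside
  the bound; a feature at radius `r` (field of view `[−1, 1]`) with view
  gap `Δγ` moves about `r · Δγ_rad · L/2` samples.
* `lambda_reg = 0.001` (dimensionless). Weight of the slope-sign
  penalty, which takes values `{0, 1, 4}`. Because the data term scales
  with the square of the sinogram intensity while `λ` is fixed, the
  balance is only meaningful at a defined intensity scale:
* `normalize = True`. The sinogram is scaled to unit maximum (one scale
  for the whole sinogram, so every pair sees the same balance) during
  estimation; synthesis uses the original values. Without this, the same
  `λ` would mean different things for data recorded in different units.
* FBP: frequency-domain ramp filter with power-of-two zero padding and
  linear-interpolation backprojection (scikit-image's `iradon` behind the
  module surface). No apodization window. 360°-coverage sinograms are
  first folded to 180° by averaging each view with the radially mirrored
  conjugate partner. Pixels outside the inscribed circle are zero.
  `output_size` follows `iradon` semantics — it crops or extends the grid
  in radial-sample units rather than resampling the field of view.

## Numerical choices

* Radial grid: `s_n = (n − L//2) · (2/L)`, so the rotation center is the
  sample at index `L // 2`, consistent with the DFT centering. For even
  `L` the radial mirror maps index `n → L − n`; the unpaired edge sample
  inherits its own value, which is zero for any object inside the field of
  view.
* Tie-breaking: candidates are scanned in the order `0, −1, +1, −2, +2, …`
  and the first minimum is kept, so ties prefer the smallest deformation
  and `−k` over `+k`. This makes the estimator fully deterministic.
* Out-of-range samples (`n + u` etc. outside `[0, L)`) read as zero:
  projections vanish outside the object support. The slope penalty is
  defined as zero at `n = 0`, where no backward difference exists.
* Angular wrap: with 360° coverage the last measured view pairs with the
  first; with 180° coverage it pairs with the radially mirrored first view
  (conjugate symmetry). The sinc baseline upsamples by zero-padding the
  view-axis DFT; for 180° coverage the sinogram is first extended to a
  full period by its conjugate views so the periodicity assumption is
  true rather than approximate.
* Image RMSE in the experiment driver is computed on intensities
  normalized by the gold standard's maximum (flag available to disable),
  putting reported RMSEs on a unit-intensity scale.

## The synthetic generator

All experiments run on analytic ellipse phantoms: projections are sums of
closed-form ellipse line integrals, and k-space is the centered forward
DFT of each projection, so there is no rasterization or quadrature error
in the inputs. Three phantoms are packaged: a centered disk (every
projection identical — useful as a null case), a ten-ellipse head phantom,
and the default `rotating_features` phantom used by the ordering
experiments.

`rotating_features` was designed around where the displacement model is
valid, after a systematic exploration of the trade-offs:

* Features must move by *several* radial samples per measured view gap —
  sub-sample motion cannot be represented by integer displacements, and
  linear averaging is already near-optimal there. The two packaged
  features sit at radius 0.7, moving up to ≈ 9 samples per 6° gap.
* Feature edges must have bounded slope. A hard ellipse edge has an
  unbounded derivative, so the ±half-sample residual of integer
  displacement produces large pointwise errors, and the edge's angular
  spectrum aliases the sinc baseline badly. Each feature is therefore a
  stack of six nested concentric shells — a smooth-edged dome that is
  still exactly an ellipse list.
* A single-valued `u(n)` cannot describe two structures passing through
  each other, so feature-trace crossings produce localized glitches
  proportional to the crossing speed. The two features share one radius
  with a 20° separation: their traces merge slowly instead of sweeping
  through each other.
* An anisotropic background ellipse has a "breathing" rim whose
  sub-sample edge motion penalizes only the displacement method; the
  packaged background is an exact circle (static projections, neutral to
  every method) at low intensity (0.2).

What the generator does **not** emulate: measurement noise (a seedable
complex-noise option exists but defaults off, as the packaged simulations
are noise-free), phase structure and coil sensitivities of real complex
k-space, non-rigid through-plane motion, and objects whose inter-view
change is not a radial displacement. Passing tests therefore demonstrate
the method's behavior in its intended regime, not robustness on arbitrary
anatomy.

## Known limitations

* **Integer displacement quantization.** True motion is continuous; the
  estimator rounds to integers, leaving residuals up to half a sample per
  gap times the local slope. On very smooth, slowly moving data the
  linear and sinc baselines can beat the displacement method.
* **Peak-error brittleness.** The *summed* error ordering across methods
  is a stable property of the packaged regime (it holds for every
  orientation of the phantom relative to the view grid), but *maximum*
  errors of both the displacement and linear methods are single localized
  glitches of similar size, and which one is larger can flip with
  sub-degree changes of phantom orientation. Treat maximum-error
  comparisons accordingly.
* **Ghost-weight floor.** The rotated-ghost decomposition fits an image
  as `w₀·main + w₊·rot(+Δγ) + w₋·rot(−Δγ)`. The average of the two
  rotated copies is an angularly smoothed main image, so *any*
  reconstruction that suppresses streaks — including the ground-truth
  full-view FBP — picks up substantial rotated-component weight
  (≈ 0.22 each in the packaged experiment, versus ≈ 0.28 for linear
  interpolation). The fitted weights measure ghost content only *in
  excess of* that floor; the displacement method sits essentially on the
  floor, but no streak-suppressing method can reach weights near zero.
* **Per-index independence.** The estimator has no spatial regularity
  across `n` beyond the slope-sign penalty; in flat sinogram regions the
  field is ragged (harmlessly, since the values moved are nearly equal),
  and in overlap regions of two feature traces it can misassign samples.
* The method shares one displacement field per adjacent pair; it does not
  exploit temporal redundancy across repeated frames, multi-coil data, or
  sub-integer candidate displacements.
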