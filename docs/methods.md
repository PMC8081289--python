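# Methods

This note documents the models, algorithms, parameters and design
choices behind `octinpaint`, and what its synthetic benchmarks do and do
not demonstrate about real OCT data.

## Saturation model and detection

A spectrometer pixel stores at most its full well capacity of charge;
stronger input clips the interferogram at that ceiling, and the
reconstructed A-line becomes a bright vertical streak.  Detection
operates purely in the spectral domain: A-line *j* is saturated iff its
spectrum contains a maximal run of at least `min_run` consecutive points
with charge ≥ `capacity`.

* `capacity` (default 99 975.6 charge counts) is an instrument-measured
  value for one particular SD-OCT system, not a universal constant; it
  must be recalibrated per spectrometer.
* Comparison uses `>=` rather than `==` because the capacity is a real
  number while stored charges may be integer-quantized.
* `min_run` defaults to 1 — a single clipped point flags the A-line,
  matching the plain capacity rule.  Real clipped spectra show runs of
  several consecutive capacity-valued points per peak, so `min_run` is
  exposed as a robustness knob against isolated noise spikes; any value
  up to the shortest physical clipping run leaves detection exact.
* When only a reconstructed B-scan is available (no raw spectra) the
  mask must be supplied externally.  No image-domain brightness heuristic
  is implemented: bright tissue interfaces would confound it, and the
  spectral rule is both necessary and sufficient for clipping.

## Dictionary learning

Overlapping 8×8 patches, vectorized row-major and zero-meaned, train an
overcomplete dictionary (64 × 128 by default) with K-SVD.  Sparse coding
during training is error-constrained — atoms are added until the
*squared* ℓ2 residual of a patch falls below ε — with ε = 5.28 on the
8-bit intensity scale, interpreted per patch vector.

Two practical choices deserve explanation:

* **Sparsity cap during training.**  On speckled patches the ε target is
  far below the noise floor, so an uncapped error-driven pursuit would
  code nearly full rank at great cost.  Training codes are therefore
  additionally capped at `max_sparsity` atoms (default: a quarter of the
  patch dimension, i.e. 16 for 8×8 patches).  The inpainting stage is
  unaffected — it always uses the sparsity-constrained form with p = 2.
* **Monotone objective.**  The classical alternating scheme does not
  guarantee a non-increasing objective: greedy OMP re-coding occasionally
  produces a worse code than the one carried from the previous iteration.
  After each coding pass, just enough of the worst-offending signals are
  reverted to their previous codes to keep the mean squared
  representation error non-increasing; all other support switches are
  kept, preserving the exploration the factorization needs.  The reported
  `error_history` is exactly the objective of the codes actually used.

Housekeeping between iterations, without which K-SVD reliably stalls in
local minima: atoms used by no signal, and near-duplicate atom pairs
(|inner product| > 0.99), are re-seeded from the worst-represented
training vectors.  A duplicate's coefficients are first folded into its
twin (so the representation barely moves), the seeding signal receives
the exact 1-sparse code on its new atom, and the whole replacement is
rolled back in the rare case it would raise the total error — keeping
the objective monotone.  Atom updates use an exact rank-1 factorization
via the small `ab × ab` eigenproblem (patch dimension 64), in ascending
atom order; randomized order and multi-sweep variants were tried and
performed no better.

On the planted-dictionary benchmark (16×24 dictionary, 2000 noiseless
2-sparse signals, 50 iterations) this implementation re-identifies
typically 20–24 of 24 atoms at |correlation| > 0.99; recovery is
initialization-dependent by a couple of atoms, which is characteristic of
K-SVD rather than of this implementation.

Full-scale training sets run to millions of patches; at desk scale
patch pools are extracted at stride 1 and uniformly
subsampled to `max_training_patches` (default 200 000; the built-in
benchmark uses 15 000) — dictionary quality saturates well below that.

## Inpainting

Each 8×8 patch that is processed is zero-meaned with the mean taken over
**valid (unsaturated) pixels only** — saturated values are meaningless
and must not pollute the mean.  The saturated entries are removed from
the patch vector and the matching rows from the dictionary; OMP codes
the surviving pixels with sparsity p = 2.  Column norms of the reduced
dictionary are no longer 1, so atom selection normalizes internally
while coefficients are solved against the unnormalized columns.  The
code applied to the full dictionary predicts the missing pixels, and the
stored mean is added back.

* `process_all_patches` (default on) also sparse-codes clean patches,
  which acts as speckle suppression over the whole image; switched off,
  unsaturated pixels pass through bit-identical and only saturated
  pixels are replaced.
* A patch with fewer than `max(3p, 8)` valid pixels is unrecoverable and
  contributes nothing.  With 8-wide patches at stride 1 this first
  happens when a saturated run reaches the patch width: runs of ≤ 7
  columns always leave every covering patch a valid column.  Pixels left
  uncovered by any recoverable patch are filled by row-wise cubic
  interpolation through the covered columns — the explicit fallback for
  runs wider than the patch.
* Output intensities are clipped to [0, max_val] after aggregation.

## Aggregation weights

Patch estimates are combined by weighted averaging with the separable
map W[i,j] = W_a[i]·W_b[j].  A literal linear taper from 1 at the center
to 0 at the edge would zero the weight of image-border pixels that only
patch edges cover, so the default triangle is

    W_a[i] = 1 − |2i − (a−1)|/a ,  i = 0..a−1

(strictly positive everywhere, 1/8 at the edges and 7/8 beside the
center for a = 8).  The strict zero-edge variant is available behind
`zero_edges=True`.  Weights normalize: a uniformly predicted region
aggregates to exactly that prediction regardless of overlap count, and
identity processing reproduces the input to float precision.

## Phantom simulator

The generator emulates what the pipeline assumes about display-domain
OCT images, not OCT physics:

* piecewise-constant reflectivity layers (default boundaries at
  fractional depths ~0.16/0.35/0.59/0.82, reflectivities 180/110/150/70
  of 255) under per-pixel exponential attenuation (0.004/px) below the
  surface, with a fixed gentle lateral undulation (3 px) so rows are not
  constant;
* multiplicative gamma speckle, unit mean, shape 4 (intensity contrast
  0.5 — representative of displayed OCT speckle);
* the reference image averages `n_average = 5` independent speckle
  realizations of the same structure, cutting speckle variance fivefold,
  as frame averaging does;
* spectra are DC-plus-cosines signals scaled to peak at 80% of capacity,
  or 150% for columns designated to clip, then hard-clipped — so
  detection ground truth is exact by construction.

Not modeled: dispersion, sensitivity roll-off, k-linearization, motion
between averaged frames, shadowing, or the true lateral correlation of
speckle.  Consequently the benchmark shows that the pipeline recovers
structured images from column loss under realistic noise levels and that
its advantage over column interpolation grows with run width; it does
not certify dB values on tissue.  Images are generated directly in the
display (8-bit-range) domain, which is the domain the pipeline processes.

Saturation masks follow the x×y protocol: x disjoint runs of y
consecutive saturated A-lines (the five benchmark patterns 30×2, 20×3,
15×4, 12×5, 10×6 all total 60), placed uniformly at random among all
non-adjacent configurations so every run remains maximal of exactly
length y.

## Evaluation

PSNR restricts the MSE to pixels in saturated columns; SSIM averages the
standard local SSIM map (11×11 Gaussian window, σ = 1.5, K1 = 0.01,
K2 = 0.03, L = max_val) over the same pixels, with a full-image option.
No border margin is added around the saturated region.  The baseline
replaces each saturated column, row by row, with a cubic spline through
the row's unsaturated columns, clamping beyond the outermost support to
the nearest support value to avoid extrapolation blow-up.

The built-in benchmark (256×256 phantom, dictionary from 5 phantom
realizations with q = 128, ε = 5.28, 20 iterations; unseen layer
geometry for the test phantom) gives masked PSNR ≈ 22 dB for the
proposed method on both sparse (30×2) and dense (10×6) patterns — a drop
of ~0.3–0.7 dB — versus ~12 dB falling to ~8 dB for the spline baseline.

## Numerical details

* OMP tie-breaks equal correlations by lowest atom index; batch OMP
  (precomputed Gram matrix, progressive Cholesky factors of the selected
  sub-Grams) matches per-signal OMP to ~1e−14 and is purely a
  performance device.  A signal's pursuit stops at the sparsity cap, at
  the squared-error target, when the residual is numerically zero, or
  when the best remaining normalized correlation is numerically zero.
* `process_image` groups patches by their validity pattern (column-wise
  masks make the pattern depend only on the patch's column position), so
  each reduced dictionary is factored once per group rather than once
  per patch.
* Degenerate inputs: zero signals code to the empty support; fully
  saturated patches raise/skip as unrecoverable; an all-identical
  training set is rejected; dictionaries with zero columns are rejected
  by normalization.
* `low_coherence_frame` builds unit-norm frames with mutual coherence
  below a target (default 1/3, the 2-sparse OMP recovery threshold) by
  alternating Gram-shrinkage and rank projection — random Gaussian
  frames in R^16 are far too coherent for recovery guarantees.

## Known limitations

* Runs wider than the patch (≥ 8 columns at the default size) cannot be
  sparse-coded and fall back to row interpolation; larger patches would
  extend reach at quadratic memory/compute cost.
* Processing is ~seconds per B-scan at stride 1 in pure NumPy; no
  real-time claim.
* One generic dictionary serves all tissue types by design; tissue with
  patch statistics far from the training images will inpaint with more
  bias.
* ε and the intensity scale are coupled: images not in the 8-bit range
  must rescale ε accordingly.
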