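# octinpaint

Detection and dictionary-based sparse inpainting of **saturation
artifacts** in spectral-domain OCT (SD-OCT) B-scans.

## The problem

SD-OCT reconstructs each depth profile (A-line) from a spectral
interferogram measured by a line camera.  A strong specular reflection
can push the detected signal past the spectrometer's *full well
capacity*: the spectrum is clipped, and the reconstructed A-line shows up
as a bright vertical streak across the B-scan.  These streaks corrupt
whole columns of the image and degrade any downstream analysis
(segmentation, thickness measurements).

`octinpaint` treats artifact correction as an **inpainting** problem and
solves it with patch-based sparse representation:

1. **Detection** — an A-line is labeled saturated when its raw spectrum
   contains a run of points at or above the capacity threshold
   (default 99 975.6 charge counts); the result is a column-wise mask.
2. **Dictionary training** — overlapping 8×8 patches from high-SNR
   (frame-averaged) images, vectorized in lexicographic order and
   zero-meaned, train an overcomplete dictionary X ∈ ℝ^(ab×q) (ab < q,
   default q = 128) by K-SVD, solving

       α̂ = argmin ‖α‖₀   s.t.  ‖y_train − Xα‖₂² ≤ ε        (ε = 5.28)

3. **Patch-wise inpainting** — for a patch with n saturated pixels, those
   entries are dropped from the patch vector y and the matching rows from
   X, giving y′ ∈ ℝ^(ab−n) and X′ ∈ ℝ^((ab−n)×q); orthogonal matching
   pursuit (batch variant with precomputed Gram matrix) solves

       α̂ᵢ = argmin ‖y′ᵢ − X′ᵢαᵢ‖₂²   s.t.  ‖αᵢ‖₀ ≤ p        (p = 2)

   and the **full** dictionary predicts the whole patch, saturated pixels
   included: Zᵢ = X α̂ᵢ + mᵢ, where mᵢ is the stored patch mean.
4. **Aggregation** — overlapping patch estimates are averaged with a
   separable triangular weight W = W_a(x̄_a)·W_b(x̄_b) that is maximal at
   the patch center and falls off linearly toward the edges.

No real OCT data is needed anywhere: a phantom module generates layered,
speckled B-scans, frame-averaged references, clipped interferogram
spectra, and the x×y random mask protocol (x runs of y consecutive
saturated A-lines, 60 in total), so the whole pipeline is testable and
benchmarkable offline.  Quality is scored by PSNR and SSIM restricted to
the saturated region, against a cubic-spline column-interpolation
baseline.

## Worked example

```sh
octinpaint simulate --shape 256x256 --pattern 10x6 --seed 1 --outdir demo
# seed=1 mask=60 saturated A-lines -> demo

octinpaint train --images demo/reference.tif --out demo/dict.h5 \
    --atoms 128 --iterations 20 --max-patches 15000 --seed 0
# ...
# iteration 20: mean squared representation error 3261.7917
# dictionary (64x128) -> demo/dict.h5

octinpaint inpaint --image demo/corrupted.tif --dict demo/dict.h5 \
    --mask demo/mask.csv --out demo/inpainted.tif --diff demo/diff.png
# patches total=62001 saturated=31623 unrecoverable=0 fallback_px=0

octinpaint evaluate --image demo/phantom.tif --reference demo/reference.tif \
    --dict demo/dict.h5 --patterns 30x2,10x6 --seeds 1
# proposed  30x2 seed=1 PSNR=22.22 dB SSIM=0.4915
#   spline  30x2 seed=1 PSNR=11.88 dB SSIM=0.2851
# proposed  10x6 seed=1 PSNR=21.92 dB SSIM=0.4083
#   spline  10x6 seed=1 PSNR=7.78 dB SSIM=0.1229
```

Reading the numbers: the masks saturate 60 of 256 A-lines.  In the
saturated region the sparse-representation method scores ~22 dB masked
PSNR against the 5-frame-averaged reference for both the sparse (30×2)
and dense (10×6) patterns — a drop of only ~0.3 dB as the runs get six
columns wide — while row-wise cubic-spline interpolation falls from
11.9 dB to 7.8 dB.  The training log shows the K-SVD objective (mean
squared representation error per 64-pixel patch) decreasing monotonically.

The same operations are available as a library
(`octinpaint.detect_saturation`, `ksvd_train`, `process_image`,
`psnr_masked`, ...); see `docs/methods.md` for the model details and
design choices.

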