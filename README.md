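# rgscodec

ROI-aware compression for grayscale medical images. The package extracts the
diagnostically informative region of an MR slice with a region-growing-guided
fuzzy c-means segmentation (RG-FCM), then compresses that region and the
background as two independent wavelet/SPIHT/Huffman streams at different bit
rates — high fidelity where it matters, aggressive compression where it does
not. It is aimed at people studying non-uniform medical image coding:
everything is scriptable from Python or the `rgsc` command line, and a seeded
phantom generator provides brain-like test images with exact ground truth so
the whole chain is reproducible without patient data.

## Method

**Segmentation (RG-FCM).** Otsu's threshold `t = argmax_t ω₀ω₁(μ₀−μ₁)²`
splits the histogram; the foreground pixel closest to the foreground mean
seeds a breadth-first region growing that admits an 8-connected neighbour
`p` while `|I(p) − mean(region)| ≤ tol`. Fuzzy c-means then clusters every
pixel on the feature `x_j = (I_j, λ·M_j)` — intensity plus a scaled
indicator of the grown region — minimising

    J = Σ_i Σ_j U_ij^p ‖x_j − V_i‖²,   Σ_i U_ij = 1,

with the classical alternating updates
`U_ij = 1 / Σ_k (d_ij/d_kj)^{2/(p−1)}` and
`V_i = Σ_j U_ij^p x_j / Σ_j U_ij^p`. The cluster overlapping the grown
region most becomes the ROI; holes are filled and the largest component
kept. Quality is scored by Jaccard `J = |R∩G|/|R∪G|`, Dice
`D = 2|R∩G|/(|R|+|G|)`, precision/recall/F, and normal confidence intervals
`mean ∓ z·SD/√N` (z = 1.65, 1.96, 2.58).

**Codec.** Each half-image (ROI, background; the other part zero-filled) is
decomposed with the biorthogonal 4.4 wavelet into a Mallat pyramid, rounded
to integers, and coded by SPIHT — bitplane-wise significance tests
`max|C_ij| ≥ 2ⁿ` over spatial-orientation trees with the LIP/LIS/LSP list
dynamics — truncated exactly at `floor(bpp·H·W)` bits, then entropy-packed
by a canonical byte-wise Huffman coder. The mask travels run-length encoded
so the decoder can fuse the two reconstructions. Rates are reported as
`CR = original bytes / coded bytes` and `bpp = 8/CR`; distortion as MSE,
`PSNR = 10·log₁₀(255²/MSE)` and SSIM.

## Worked example

```sh
rgsc phantom --seed 0 --noise 10 -o mri.png --mask-out gt.png
rgsc segment mri.png -o roi.png
rgsc evaluate-seg roi.png gt.png
```

prints

```
area_pct=6.01806640625
dice=1.0
jaccard=1.0
...
```

— on this 256×256 phantom (lesion covering 6.0% of the frame, Gaussian
noise σ=10) the recovered ROI matches the ground truth pixel for pixel.
Compressing with the recovered mask, ROI at 1.0 bpp and background at
0.25 bpp:

```sh
rgsc compress mri.png --mask roi.png --bpp-roi 1.0 --bpp-bg 0.25 -o mri.rgsc
rgsc evaluate mri.png mri.rgsc
```

```
cr_full=8.06001721805436
psnr_full=29.017109085722485
psnr_roi=58.60014005111296
ssim_full=0.9843158362043953
```

The whole frame compresses 8.1:1; the lesion region is reconstructed at
58.6 dB (mean squared error 0.09 gray levels²) while the noisy background
absorbs nearly all of the loss. `rgsc compress --uniform --bpp 0.5` gives
the single-stream SPIHT baseline, and `rgsc report` sweeps the rate grid
over a phantom batch and prints a rate/distortion table with confidence
intervals.

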