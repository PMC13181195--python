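# Methods

## Segmentation model

The pipeline assumes the informative region is the brightest coherent
structure in the slice — the contrast situation of a contrast-enhancing or
T2-bright lesion on darker parenchyma. Under that assumption Otsu's
between-class-variance threshold isolates the lesion, the seed (the
foreground pixel nearest the foreground mean intensity) lands inside it, and
region growing recovers its extent.

Region growing is breadth-first with 8-connectivity and the fixed neighbour
order N, S, W, E, NW, NE, SW, SE. A frontier pixel is admitted when its
intensity is within `tol` of the *running* region mean, the mean being
updated after every admission; each pixel is tested exactly once, at its
first visit. One-shot testing makes the algorithm deterministic and
guarantees termination, at the cost that a pixel rejected early is never
reconsidered even if the mean later drifts toward it — acceptable because
fuzzy c-means refines the result anyway. The tolerance defaults to
`0.15 × |mean_fg − mean_bg|` of the Otsu split: a fraction of the
image's own global contrast, so it adapts to acquisition scaling.

How a region-growing result should enter the fuzzy c-means objective is
genuinely open; of the candidate realizations (feature, penalty term,
initialization) this package encodes it as a second feature dimension,
`x_j = (I_j, λ·M_j)` with `M_j ∈ {0,1}` the region indicator. This keeps
the plain Euclidean FCM objective and update formulas intact while letting
spatial evidence pull the clustering. `λ` (default 128) sets how many gray
levels of intensity difference one unit of spatial disagreement is worth;
at 128 it is half the intensity range, strong enough to separate
equal-intensity structures inside/outside the grown region without swamping
intensity altogether.

FCM details: fuzzifier `p = 2`, cluster count `m = 2` (informative vs
rest; raise to 3–4 for white/gray-matter work), convergence when
`max|ΔU| < 1e-5` or 200 iterations, centroids initialized uniformly over
the per-feature data range from a seeded generator, so every run is
bit-reproducible. Zero distances assign full membership to the first
coincident centroid. The objective is recorded each iteration; alternating
minimization makes the trace non-increasing, which the tests assert.

The hard ROI is the maximum-membership cluster that overlaps the grown
region most (ties to the brighter centroid), hole-filled, largest
8-connected component only. With an empty region-growing mask and no
overlap evidence the ROI is reported empty rather than guessed.

## Phantom generator

Phantoms emulate a single axial brain-like slice: an elliptical "head" of
parenchyma (intensity 60) over dark background (10), one or more bright
elliptical lesions (220) jointly covering a target 2.5–8% of the frame
(drawn per seed when not fixed), a smooth ±10% multiplicative bias field
built from four random-phase low-frequency sinusoids, and additive Gaussian
noise (Rician behind a flag, since MR magnitude noise is Rician). The mask
is the exact lesion support before noise, and generation is bit-identical
per seed.

The tissue level is deliberately placed in the lower half of the range:
with the lesion far above both other classes, the histogram's maximal
between-class split isolates the lesion, which is the operating regime the
segmentation pipeline is designed for (bright tumor on darker parenchyma).
Had tissue sat midway between background and lesion, Otsu's split would
fall at the background/head boundary and the pipeline would segment the
head — a different, also legitimate, task, but not the one evaluated here.

What the phantom does *not* model: anatomical texture, partial-volume
boundaries (lesion edges are binary), multi-tissue structure, slice
geometry. Passing the phantom suite therefore demonstrates correctness of
the algorithms under their stated assumptions, not clinical segmentation
accuracy on real MRI.

## Wavelet stage

bior4.4, periodized filtering, `L = min(⌊log₂(min(H,W))⌋ − 2, 6)` levels so
the coarsest LL is at least 4×4. Periodization (rather than half-sample
symmetric extension) is used because it halves every subband exactly, which
the SPIHT spatial-orientation tree requires; perfect reconstruction is
preserved (measured < 1e-9, asserted < 1e-8). Non-dyadic sides are padded
symmetrically to a multiple of 2^(L+1) — the extra factor keeps the
coarsest LL even so its 2×2 root groups are complete — and cropped after
synthesis. Coefficients are rounded half-away-from-zero to integers;
magnitude-zero pixels carry sign +1.

## SPIHT

Classical LIP/LIS/LSP list dynamics. The tree: inside the coarsest LL each
2×2 group's top-left member is rootless; the other three root the
same-level HL/LH/HH 2×2 blocks (group `(a,b)`, offset `(oi,oj)` → block at
`(oi·llh + 2a, oj·llw + 2b)`); below the LL, children sit at doubled
coordinates. Set significance is answered from precomputed
descendant-maximum tables. Significance convention is `≥ 2ⁿ`; passes run
from `b_max = ⌊log₂ max|C|⌋` down to plane 0, and the encoder truncates
mid-pass, mid-entry, exactly at the bit budget — this exact rate control is
what makes measured CR equal `8/bpp` at binding budgets.

Decoding mirrors the lists; a coefficient newly significant at plane `n` is
reconstructed at `±1.5·2ⁿ` and each refinement bit halves its uncertainty
interval. When the stream covers all planes the midpoint estimates equal
`magnitude + 0.5` exactly and are rounded to the exact integers: full-depth
coding is lossless on the integer plane. Note that midpoint reconstruction
makes squared error non-increasing in prefix length *in aggregate* but not
bit-by-bit in corner cases (a refinement bit can move a single estimate off
a luckily-exact value); the tests assert monotonicity at spaced checkpoints
on random planes, where it holds.

## Huffman stage

The SPIHT bitstream is packed into bytes (MSB first, final byte
zero-padded; the true bit count travels in the container so padding is
never decoded) and Huffman-coded byte-wise — the alphabet is a design
choice, made so the entropy stage has real redundancy to exploit. Merging
ties break deterministically (lowest count, then smallest symbol, then
oldest internal node); lengths become canonical codes so the packet header
stores only (symbol, length) pairs. The header costs at most
2 + 2·256 + 4 bytes, the bound the cascade-overhead test asserts.

## Container and rate accounting

The `.rgsc` container (big-endian) records dims, levels, wavelet id, the
two rates, the two `b_max` values (255 encodes −1 for an all-zero plane),
the two exact SPIHT bit counts, the run-length-encoded mask (alternating
u16 run lengths starting with zeros; 65535-runs chain with zero-length
runs), and the two Huffman packets. The mask must be transmitted for fusion
to be possible, so its bytes are charged to the full-image rate:
`CR_full = H·W / (E_r + E_nr + mask_bytes)` with `E_r`, `E_nr` the packet
byte lengths; regional ratios use `H·W / E`. Uniform (single-stream) mode
is accounted SPIHT-only — original bits / emitted SPIHT bits — the
convention under which a binding budget gives exactly `8/bpp`.

Each half-image has its masked-out part zero-filled before the transform
(mean-fill behind a flag); zeros maximize wavelet sparsity so the bit
budget concentrates on actual content.

## Numerical limits and degenerate inputs

- Full-depth ROI-mode coding is *near*-lossless, not lossless: the mask
  split creates sharp edges whose bior4.4 coefficients are non-integer, and
  rounding them perturbs the reconstruction by up to ~0.9 gray level
  (measured), i.e. at most ±1 after final rounding. Uniform mode on content
  whose coefficients round exactly (e.g. constant images) is exactly
  lossless at full depth.
- Constant images raise a degenerate-histogram error in segmentation (no
  two classes exist); empty Otsu foregrounds and out-of-bounds seeds raise
  typed errors rather than guessing.
- Empty masks produce a header-only packet for the empty stream
  (`b_max = −1`, zero bits).
- Two empty masks score Jaccard = Dice = 1; 0/0 in precision/recall/F is
  reported as 0. The z values 1.65/1.96/2.58 are used exactly as printed in
  standard tables rather than at full precision.

## Problem sizes in the test suite

Segmentation experiments run at the native 256×256; the rate-monotonicity
sweep uses 128×128 phantoms and the lossless/property tests use 8×8–64×64
planes, sizes at which the pure-Python SPIHT lists remain quick while
exercising every code path (multi-level trees, budget truncation, padding).
The acceptance script runs the full 256×256 uniform coder.

## Known limitations

- 2-D, 8-bit, single-channel only; no DICOM, no 3-D trees, no
  arithmetic-coded SPIHT variant.
- The segmentation operating regime assumes a bright ROI; inverted-contrast
  lesions would need an inverted intensity feature.
- Boundary-based precision/recall uses a distance-band definition (default
  2 px) since no single standard exists; pixel-wise is the default.
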