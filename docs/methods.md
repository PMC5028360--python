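# Methods

This note documents the models and numerical choices behind `dermseg`:
what each stage computes, which parameters matter, what the synthetic
phantoms do and do not emulate, and where the design was genuinely open.

## Pipeline model

The pipeline assumes one pigmented lesion per frame, darker than the
surrounding skin, in an 8-bit RGB dermoscopic image. Stages run in a
fixed order — corner masking, hair removal, channel extraction, wavelet
segmentation, morphological cleanup — and every stage is a pure function
of its inputs and the `PipelineConfig`, so a run is bit-reproducible
from its config snapshot.

### Channel enhancement

Lesion/skin contrast is strongest and most uniform on the blue channel,
which is the default selector. Alternatives exposed for comparison:

* luminance `0.2989 R + 0.5870 G + 0.1140 B` (Rec. 601 weights), kept
  real-valued;
* the maximum-entropy channel: per-channel 256-bin histogram entropy
  `−Σ p log₂ p` (non-negative, so "highest entropy" = most gray levels);
  exact ties break toward blue, then green, matching the pipeline's
  preference for blue;
* CIE L\*a\*b\* components, computed under sRGB companding and the D65
  white point (ranges L ∈ [0,100], a,b ∈ [−128,127]).

### Otsu thresholding

All thresholding stages share one exhaustive Otsu search: the image is
quantized to 256 uniform bins over its declared value range (so
real-valued channels such as CIELAB `a` are binned consistently), every
split `t ∈ [0,254]` with two non-empty classes is scored by the
intra-class variance `ω₁σ₁² + ω₂σ₂²`, and the smallest minimizing `t` is
returned (deterministic tie-break). The implementation uses cumulative
moments; tests verify exact agreement with a brute-force loop.

### Dark corners

Circular dermatoscope lenses leave dark rounded corners whose intensity
is close to the lesion's, so they must be masked before segmentation.
The corner detector Otsu-binarizes the channel image dark-is-foreground,
**opens the dark mask with a 4-px disc**, and keeps components touching
an image corner. The opening is load-bearing: dark hairs are thin
bridges that otherwise connect the central lesion to the corner
components, making the "corner" mask swallow the lesion. With the
opening, corners are recovered at Dice ≥ 0.9 against phantom ground
truth and never intersect a centered lesion.

### Hair removal

*Enhancement.* A difference of two anisotropic Gaussians, sampled on the
integer grid and mean-subtracted to sum exactly to zero:
`g(x,y) = k₁ exp(−x²/2σx₁² − y²/2σy₁²) − k₂ exp(−x²/2σx₂² − y²/2σy₂²)`,
defaults `k₁=1, k₂=0.4`, first Gaussian narrow across the line
(σx₁=1.5, σy₁=6), second broader (σx₂=3, σy₂=9), half-size
`⌈3·max σ⌉`. The kernel is rotated to 12 orientations (15° steps) by
bilinear resampling; responses are negated so dark lines score positive
(equivalent to filtering the inverted image); the pixelwise maximum over
orientations is the enhancement map, the argmax the orientation map.
Zero-sum kernels give exactly zero response on constant images, and the
bank attributes rendered lines at any multiple of 15° to the correct
orientation.

*Segmentation.* No single global threshold separates hairs from other
edges: hairs crossing the dark lesion respond three to four times weaker
than hairs on skin, overlapping the response of the blurred lesion
boundary. The default strategy therefore combines
(1) a two-stage Otsu: the Otsu split of the response map, then the Otsu
split of the values above it, isolating the strongest response mode;
(2) an absolute floor `contrast_floor × line_gain`, where `line_gain` is
the bank's measured peak response to a rendered unit-contrast dark line
(cached per parameter set) and `contrast_floor` defaults to 60 intensity
units — dermoscopic hairs are far darker than skin, while the lesion
boundary's effective line contrast stays below this; and
(3) hysteresis growth from those cores down to 0.35× the core threshold,
which attaches the dimmer hair segments crossing the lesion.
Components are then filtered by skeleton shape: keep those whose
skeleton length is ≥ 15 px and ≥ 3× the mean component width. An
ellipse-axis-ratio filter was evaluated and rejected: crossing hairs
form X-shaped networks whose ellipse ratio is near 1, which zeroed the
recall; the skeleton ratio keeps such networks while still rejecting
blobs. Fixed-value and quantile strategies remain available
(`fixed:<v>`, `quantile:<q>`), and the pipeline excludes a dilated
corner region from detection since corner arcs are strong line-like
responders.

*Inpainting.* Masked pixels (hair mask dilated by 2 px so halos are
filled too) are seeded by nearest-neighbor fill and updated for 50
iterations of the classical inpainting PDE: the gradient of the
Laplacian is transported along the isophote direction (perpendicular to
the intensity gradient), with a stabilizing diffusion sweep inside the
hole every 5 steps (time step 0.1). Pixels outside the dilated mask are
returned bit-exact; a constant image is a fixed point. Each RGB channel
is inpainted independently, followed by a 3×3 reflective-boundary median
filter that clears residual specks without blurring edges.

### Wavelet segmentation

The channel image (corners pre-filled with the median of non-corner
skin, so they cannot drag the threshold) is decomposed by a 2-level
separable DWT with half-sample symmetric extension. Supported mother
wavelets: `haar`/`db1`, `db4`, `sym4`, `bior6.8` (default) and `cdf97` —
the CDF 9/7 biorthogonal pair, provided by PyWavelets under the name
`bior4.4`. Perfect reconstruction holds below 1e-8 for every family.

The level-2 approximation A2 is binarized (Otsu dark-is-foreground by
default; `fixed:<v>` available, with values on the A2 scale — lowpass
gain is 2 per level) and upsampled to full resolution by nearest
neighbor. Two registration details matter:

* **Group-delay compensation.** Under symmetric extension, coefficient
  `k` of an L-tap filter is not centered at `4k`; the offset is measured
  once per (wavelet, level) by decomposing 1-D impulses at every
  subsampling phase and averaging the energy centroids (the phase
  average resolves the half-sample bias of short filters). Without this,
  bior6.8 masks land ~24 px off target.
* **Half-up rounding.** The index map uses `⌊x+0.5⌋`, not banker's
  rounding: `rint`'s half-to-even rule alternates with coefficient
  parity and silently breaks shift covariance. With both details, a 4-px
  translation of a noiseless phantom translates the raw mask exactly.

### Postprocessing

Corner subtraction, then hole filling (background regions not
4-connected to the border become foreground), then island management:
the largest component is kept; other components are kept only if their
area is ≥ `min_island_area` (default 100 px) and their distance to the
main component is ≤ `merge_distance` (default 20 px, ≈2.5 % of a 768-px
frame), in which case a closing with a disc of radius
`merge_distance/2` bridges them; a single opening
(erosion+dilation, radius 3) follows, and if it re-splits the mask only
the dominant component survives — the final mask always has at most one
component. The boundary is smoothed by extracting the closed contour as
an ordered subpixel coordinate sequence (marching squares on the 0.5
level set), applying a circular moving average of window `W` (default
15, odd) to the row and column sequences independently, and
re-rasterizing the polygon. `W=1` is the identity; a circle is nearly a
fixed point; corners of a square are rounded with < 5 % area change.
The smoothing operates on boundary coordinates, not on the image — an
image-domain blur would shrink the mask and blur the area estimate.

### Evaluation metrics

Rates are fractions per image and percentages in batch averages. `TDR =
TPR = tp/#GT`; `FNR = fn/#GT` (so TDR+FNR = 1); `FPR = fp/#GT` — false
positives normalized by ground-truth area, the convention used in
dermoscopy ATDR/AFPR tables — while the standard fall-out `fp/(fp+tn)`
is reported separately as `fallout`; `TNR = tn/(tn+fp)`; `EP =
(fallout+FNR)/(TPR+fallout+TNR+FNR)`, a proper error probability in
[0,1] built from the standard rates. `DICE = 2tp/(|SR|+|GT|)`. Batch
averages are unweighted means; pairs that fail (empty ground truth) are
excluded and flagged. All metrics are verified exactly against a
pixel-loop oracle.

## Synthetic phantoms

A phantom is a 256×192 frame (the 768×560 PH2 aspect ratio scaled down
for fast suites; full size available) rendered from a `PhantomSpec`:

* **skin** — uniform warm tone (225,165,140);
* **lesion** — an ellipse (default semi-axes 42×58 px) of color
  (115,70,50), alpha-blended with an alpha map blurred by
  `edge_softness` (σ = 3 px), emulating the smooth skin–lesion
  transition of real dermoscopy; ground truth is the 0.5-alpha level
  set, whose area matches πab within 2 %;
* **hairs** — quadratic Bézier strokes of thickness 2 px and color
  (55,40,35), with endpoints on opposite borders so they cross the
  frame, and frequently the lesion — the hard case;
* **bubbles** — bright discs with darker rims (gel proxy; no ground
  truth needed since no stage is scored on bubbles);
* **corners** — the four quarter-disc complements of radius
  `corner_radius`, painted near-black;
* **noise** — additive Gaussian (σ = 4 intensity units), clipped to
  [0,255].

Artifact placement and pixel noise draw from separate seeded
substreams, so two specs differing only in artifact counts share the
same noise field — this makes the with/without-hairs twin pairing an
exact ground truth for inpainting error. Suites jitter lesion position,
size (±25 %/+15 %) and contrast (fading the lesion up to 25 % toward
skin) from a single suite seed; generation is bit-reproducible.

The phantoms deliberately omit pigment networks, skin texture, uneven
illumination and multi-lesion frames. Passing the phantom suites
therefore demonstrates artifact robustness and internal consistency of
the pipeline, not clinical accuracy; on real data the contrast between
lesion and skin is lower and more variable, and scores will be lower.

## Problem sizes and runtime

Default suites are 10–20 phantoms at 256×192; a full pipeline run takes
roughly 0.3–0.5 s per phantom on one CPU (the filter bank uses FFT
convolution on a reflect-padded image). The acceptance script
(`scripts/acceptance.py`) runs all checks in well under a minute.

## Known limitations

* Single-lesion assumption: multi-lesion frames yield only the dominant
  component.
* The hair contrast floor (60 units) targets dark hairs; blond or
  gray hairs with contrast below it are left to the wavelet stage's
  artifact shedding.
* Double rotation of the sharp default kernel by 45°+45° differs from a
  single 90° rotation by up to ~10 % of the kernel peak — the cost of
  bilinear resampling at σ = 1.5; the filter bank itself always rotates
  the unrotated kernel once per orientation, so this affects no
  pipeline path.
* Otsu-based stages assume a roughly bimodal histogram; a frame that is
  all lesion (or all skin) raises a degenerate-histogram error rather
  than guessing.
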