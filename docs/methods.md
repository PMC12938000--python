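# Methods

This package re-enacts, at desk scale, a "probe-plus-AI" fluorescence
angiography workflow: a probe emitting in the long-wave second
near-infrared window (NIR-IIa, >1300 nm) yields sharp, low-background
vessel images, while the clinically convenient first window (NIR-I,
700–1000 nm) suffers scattering, tissue autofluorescence and a dominant
hepatic signal.  A supervised image-to-image network trained on
co-registered pairs of the two channels translates low-quality NIR-I
frames into NIR-IIa-like frames.  Because no in vivo image data are
deposited with the source study, the package ships a synthetic paired
phantom generator whose statistics emulate the two channels, and every
quantitative claim is made on those phantoms.

## Phantom model (`nir2a.phantom`)

**Geometry.** A random branching vessel tree is grown from 2–4 stems
entering at the frame border.  Segments have uniform random length
(10–22 px), jittered headings (sd 0.45 rad), and radii that decay by
0.82 per generation from 3.2 px down to a 0.7 px floor, so each frame
contains both coarse vessels (radius ≥ 2 px) and sub-1.5 px
microvessels.  Trees are rasterized once with a Gaussian cross-section
(sigma = radius/2, combined across segments by maximum); the binary
ground-truth mask is the set of pixels within one radius of any
centerline.  Both channels derive from this single rasterization, so the
pair is co-registered by construction.  Default frames are 120×120 px —
the smallest comfortable size satisfying the network's
divisible-by-40 contract (three stride-2 convolutions, then 5×5
patches); for other sizes the tree density should be re-scaled (the
40-pixel-grid tests use 2 stems).

**Optics.** The ideal scene is `background_floor + (vessel_peak −
background_floor) · profile` with defaults 0.22 and 0.85.  The NIR-IIa
channel applies a narrow scattering PSF (Gaussian, sigma 0.6 px).  The
NIR-I channel applies a wide PSF (sigma 3.0 px), adds a smooth
autofluorescence field (white noise blurred at correlation length 8 px,
min-max scaled, amplitude 0.8 of the vessel peak) and one elliptical
hepatic hotspot (amplitude 0.9, axes 16×11 px, placed randomly in the
central lower band).  Both channels receive Poisson shot noise (2000
photons per intensity unit) and Gaussian read noise (sd 0.01), then clip
to [0, 1]; clipping more than 5 % of pixels raises a saturation flag in
the pair metadata.  These defaults were calibrated once against the
package's own auto-ROI SBR so that the NIR-IIa channel sits near SBR 2.6
and the NIR-I channel near 1.5 — the contrast regime the two physical
windows exhibit — and were then frozen.

**What the phantoms do not model:** anatomy (no organ atlas, no
perfusion), 3-D light transport, depth-dependent blur, motion, or
detector fixed-pattern noise.  Passing tests therefore demonstrate that
the pipeline recovers structure under the three named degradations, not
that it reaches in vivo image quality.

## Enhancement network (`nir2a.network`)

Encoder: three Conv(3×3, stride 2) → BatchNorm → ReLU stages with
channels 1→32→64→128.  Bottleneck: the deepest feature map is cut into
5×5 patches, each flattened (3200 values) and linearly embedded into
128-dimensional tokens with a learned additive positional table; three
Swin blocks follow (layer-norm → windowed multi-head self-attention →
residual → layer-norm → 2-layer GELU MLP, expansion 4 → residual), the
middle block using cyclically shifted windows with the standard region
mask whenever the window is smaller than the token grid (at 120×120 the
grid is 3×3, one full-grid window, so shifting is inactive); tokens are
projected back and re-assembled.  Decoder: three (2× nearest-neighbour
upsample → concatenate skip → Conv(3×3, stride 1) → BatchNorm → ReLU)
stages with channels 128, 64, 32, consuming the second and first encoder
features and finally the raw input frame as skips, then a 1-channel
convolution and sigmoid.

Choices made where the architecture left gaps: spatial (not
channel-wise) 5×5 patching; embed 128 / 4 heads / window = full grid up
to side 8 (otherwise the largest divisor ≤ 8) / shift = window//2;
nearest-neighbour-plus-convolution upsampling (avoids checkerboard
artifacts); sigmoid output; the bottleneck output feeds the decoder
directly without a residual addition of the deepest feature; the raw
frame serves as the third skip source.  Training: L1 loss (robust to the
heavy-tailed hotspot; L2 available), Adam at 1e-3, batch 4, per-image
min-max normalization of inputs **and** targets (the physical channels
differ by orders of magnitude in exposure), checkpoint at the best
validation loss.  All initialisation and shuffling derive from one seed;
training is bit-reproducible on a fixed machine.

The network runs on a small reverse-mode automatic-differentiation
engine written on numpy (`nir2a.autodiff`): convolution is evaluated
channels-last as k² shifted BLAS GEMMs over the flattened padded plane,
and every backward rule is verified against central finite differences
in the test suite.

## Quantification (`nir2a.metrics`)

* **SBR** = mean of 3 vascular ROI means / mean of 3 adjacent background
  ROI means.  ROIs are disks (default radius 4 px).  Automatic placement
  puts signal ROIs on the three brightest, mutually separated
  skeleton points of the vessel mask and background ROIs at a minimum
  distance (default 6 px + radius) from every vessel pixel; a seed
  breaks exact intensity ties only.
* **Line profiles** are sampled bilinearly at unit-pixel spacing;
  **FWHM** subtracts an endpoint-mean baseline (vessel profiles ride on
  tissue background), then locates half-maximum crossings by linear
  interpolation on both flanks of the interior peak.  For a sampled
  Gaussian this matches the closed form 2√(2 ln 2)σ within 2 % at
  spacing ≤ σ/4; profiles without a resolvable peak raise an error (the
  pipeline records them as missing).
* **Photophysics**: Stokes shift = emission-peak minus absorption-peak
  wavelength (ties break toward the longer wavelength and are flagged);
  photostability retention = final/initial intensity; hemolysis % =
  (OD_test − OD_neg)/(OD_pos − OD_neg) × 100.
* **Circulation**: blood-signal decay is fit as A·exp(−ln 2·t/t½) by
  least squares, initialised deterministically from a log-linear
  regression; non-decaying series return a divergence flag instead of an
  estimate.

## The end-to-end experiment (`nir2a.pipeline_io`)

`run_experiment` chains generate → train → enhance → quantify and writes
a JSON report plus CSV tables.  ROIs are placed once per test pair on
the target channel and shared across input/enhanced/target so the three
SBRs are comparable; FWHM is measured along a stored cross-section
through each pair's widest vessel.  Every number in the report is
recomputable from the persisted images and the stored ROI specs with the
metrics module alone, and reports contain no timestamps, so identical
configurations produce byte-identical reports (timestamps live in the
run log).

**Problem sizes.** The canonical experiment (`reenactment_config`)
uses 80 pairs at 120×120 (64 train / 8 val / 8 test) and 15 epochs at
batch 4.  On this task the validation loss flattens well before 15
epochs, and the trained model already enhances the held-out split
decisively (in the packaged run: median SBR 1.45 → 6.24 against a
target of 2.62; median |FWHM − target| 0.61 mm → 0.082 mm), so longer
schedules only add compute; the library default of 50 epochs remains for
harder translation problems.  Note the enhanced SBR can exceed the
*raw* target's SBR: the network predicts the min-max-normalized target,
whose background is stretched toward zero — background suppression
beyond the raw target is expected, and FWHM (affine-invariant) is the
sharpness check.

## Known limitations

* Phantom realism as above; no claim about in vivo imaging quality or
  about the source study's trained weights.
* Bit-exact determinism holds per machine/BLAS build, not across
  different BLAS implementations.
* Automatic ROI placement assumes a usable vessel mask; on real data the
  mask would have to come from segmentation, which is out of scope.
* The positional-embedding table is learned for the training grid;
  inference on other divisible-by-40 sizes bilinearly resizes it, which
  is standard but untested beyond smoke level.
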