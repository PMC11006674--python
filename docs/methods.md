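# Methods

This note documents the models, conventions and numerical choices behind
`aorpe`, in the order data flows through the package.

## Synthetic acquisition model

**Cell mosaic.** RPE cells are laid out as a triangular lattice of spacing
`s = cell_spacing_um / pixel_scale_um` pixels (row pitch `s·√3/2`), each
center jittered uniformly by up to `position_jitter_frac · s` per axis
(default 0.1, bounded below 0.5 so neighbours cannot swap).  Reflectance is
rendered per pixel from the distance `d` to the nearest center as a cosine
dip, `R = 1 − depth·(1 + cos(π·min(d/(s/2), 1)))/2`, giving the dark-center /
bright-surround phenotype with contrast `center_dip_depth` (default 0.8).
Spacings below 3 px are rejected as unresolvable.  Defaults — 300 px canvas,
14 µm spacing, ~1.45 µm/px (1.5° field over 300 px through the schematic
eye) — are the acquisition conventions the package targets.

**Speckle.** Each frame draws a zero-mean circular complex Gaussian field
with per-pixel variance proportional to reflectance, low-passes the real and
imaginary parts with an isotropic Gaussian of width `psf_sigma_px`
(grain size; default 1.0 px, a free parameter of the simulation), and takes
the squared magnitude.  The marginal intensity is then exponential, so a
single look has speckle contrast (SD/mean) exactly 1 and `M` incoherently
averaged looks have contrast `1/√M`.  The intensity is renormalised by the
expected filtered power — the variance map correlated with the *squared*
discrete kernel — so `E[I]` equals the reflectance to within boundary effects
of the mirror-padded filter (a border of about one kernel radius, which
evaluation code excludes).  Per-(frame, look) seeds come from a
`SeedSequence` spawn key, making frames statistically independent given the
reflectance — the decorrelated regime that makes incoherent averaging work.

**Eye motion.** A 2D random walk sampled once per scan row across the whole
acquisition (step SD `drift_sd_px_per_row`) plus saccade-like jumps
(`saccade_rate_per_frame` expected events per frame, amplitude
`saccade_amp_px`, random direction).  Raster distortion resamples the
reflectance row by row at the trace displacement (bilinear, mirror fill,
validity mask recorded), so each frame carries a unique intra-frame
distortion and frames differ by bulk shifts — the two artifact classes that
make multi-reference augmentation productive.

## Ground-truth construction

Registration is whole-frame rigid translation: normalised cross-correlation
via FFT on lightly smoothed frames (Gaussian σ 2 px, so the cell-scale
structure rather than the speckle grain drives the correlation), integer
peak refined per axis by a quadratic fit through three samples.  Because a
quasi-periodic mosaic correlates with itself at lattice displacements, a
single speckled reference invites alias locks; registration therefore runs
**two passes**: the better-scoring half of pass-1 frames is averaged into a
low-speckle template on the reference grid and all frames are re-registered
to it.  Frames scoring below `min_score` (default 0.2 against the template)
are excluded from the average; a count map records per-pixel contributions.

Averaged images from different references sit on different grids, so the
"similar pair" fed to the twin discriminator (two averaged renditions of the
same tissue) is re-registered onto the current reference grid before patches
are cut.  Pair counting is exact:
`n_references × patches_per_image × (2 if flipped)`, with patch offsets
`range(0, size − patch + 1, stride)`; the package reports its own count
formula and does not target any externally quoted dataset size.

## Networks, losses, training

The networks run on a small in-package reverse-mode autodiff engine
(`aorpe.nn`): conv2d by im2col, nearest-neighbour upsampling, channel
concatenation, leaky-ReLU/sigmoid/tanh/softplus, Adam.  Every op's backward
pass is checked against central finite differences in the test suite.

* **Generator** — `depth` (default 4) stride-2 conv levels, channels
  `base·2^k` capped at 128, bottleneck conv, decoder of upsample+conv with
  encoder skip concatenation, sigmoid head bounding the output to [0, 1].
  Inputs not divisible by `2^depth` are reflect-padded and cropped back.
  The exact layer table of the original architecture is not public; depth
  and width are configuration, and these defaults are assumptions.
* **CNN discriminator (D2)** — 3 stride-2 conv levels and a 1-channel logit
  map (patch-level real/fake).
* **Twin discriminator (D1)** — one weight-shared trunk applied to both
  inputs (single parameter storage, so weight sharing is structural).  Two
  intermediate tap levels (default mid-depth) and the last level are each
  globally average-pooled, scaled by the WFF weights (default 0.2, 0.2, 1.0),
  and concatenated; the similarity head is a linear map on the element-wise
  absolute difference of the two fused vectors, squashed by a sigmoid.
  Weights (0, 0, 1) reproduce the no-WFF ablation (last-layer pooling only).
* **Losses** — non-saturating binary cross-entropy for both adversarial
  paths and L1 content loss, weights (1, 1, 100) by default.  The functional
  forms and relative weights are not specified by the source architecture's
  public description; these are the package's documented choices.  D1's
  positive pairs are two averaged renditions of the same patch from
  different references — the only naturally available "same scene, different
  instance" positives; with a single reference the positive degenerates to
  an identical pair.  Training is simultaneous per batch (D2 step, D1 step,
  then G against both critics plus content), Adam lr 2·10⁻⁴, betas
  (0.5, 0.9), 100 epochs, batch 8; losses above 10⁶ abort as divergence.
  Discriminators are discarded after training.

**Inference** tiles images larger than the training patch with ≥ 25 % overlap
(default 50 %), blending with a separable sine window normalised so per-pixel
weights sum to one; a patch-sized input is a single forward pass.

## Quantification

The radial PSD mean-subtracts a centred square ROI (default 200 px), applies
a 2D raised-cosine taper (suppressing edge leakage that would bias the
left-minimum search; `window="none"` is available), takes `|FFT|²` and
averages over annuli of one frequency-sample width (membership by rounded
radial index).  Annulus sums over the full spectrum (corners included)
account for all non-DC power exactly, which the tests verify as a Parseval
identity.  The peak is the highest strict local maximum inside the search
band (default: spacings 6–40 µm converted through the supplied scale,
bracketing human RPE spacing across eccentricity); peak distinctiveness is
its log₁₀ height above the nearest strict local minimum at lower frequency
(global minimum in `(0, f_peak)` as fallback).  The peak frequency is
refined by a quadratic fit over three bins — at ROI 200 the raw bin width
alone corresponds to ~2 µm of spacing at 20 µm, so sub-bin refinement is what
brings the recovery error to ~0.1 µm.  For a triangular mosaic the spectral
ring sits at the reciprocal *row* spacing, so center-to-center spacing is
`(2/√3)/f_peak`.

The µm conversion traces a paraxial chief ray (entering the corneal vertex at
1°) through three refracting surfaces — cornea, lens front, lens back — with
2×2 refraction/translation matrices in the reduced-angle convention.
Defaults are a standard simplified schematic eye (cornea 7.8 mm, lens
+10/−6 mm with 3.6 mm thickness, indices 1.336/1.413/1.336, axial length
24 mm; ≈ 291 µm/deg), with the three clinically measured quantities (axial
length, corneal radius, anterior chamber depth) overridable per eye.  The
exact surfaces of the original three-surface model are not reproduced in the
public description; these constants are documented assumptions, and the
µm/deg value is surfaced in every report for auditability.

Voronoi statistics exclude cells whose region is unbounded or touches the
image bounds; neighbor distances are center-to-center over Voronoi-adjacent
interior pairs, density is interior count over summed interior region area,
and `fraction_hexagonal` is the share of interior cells with exactly six
neighbors.  Adjacency is validated against Delaunay duality in the tests.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the method assumes —
quasi-hexagonal geometry, fully developed multiplicative speckle that
decorrelates between frames, bulk shifts and raster shear — but not real
tissue: no cell-size gradients with eccentricity, no pathology, no vascular
shadowing, no axial (3D) structure, no aberrations or chromatic effects, and
speckle grain size is a free parameter rather than derived from the imaging
optics.  Passing tests therefore demonstrate correctness of the machinery
and the *direction* of the contrast-enhancement effect on matched synthetic
conditions, not clinical performance: quantities such as the toy run's PD
gain depend on the simulated dataset and are not comparable in magnitude to
values measured on human data.

## Problem sizes and reproducibility

Tests and the acceptance script run desk-scale configurations chosen as the
package's own defaults for CPU work: 64 px patches, depth-3 / 8-channel
networks, ~500 training pairs, 10 epochs for the end-to-end check; 120-frame
stacks at 128 px for the averaging law; 20 mosaics at 260 px for spacing
recovery.  Every stochastic component is seeded (mosaics, speckle looks,
motion, batch order, weight init), and the same seed regenerates pipeline
reports bit-identically on the same machine; floating-point results may
differ across BLAS builds.

## Known limitations

Whole-frame rigid registration (no strip-wise nonrigid correction as in full
AO-OCT processing chains); no automated cell-center detection (Voronoi input
is a marked-centers CSV); perceptual metrics that require external trained
networks are out of scope; the NumPy engine is single-threaded-friendly but
not suited to the original work's full training scale.
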