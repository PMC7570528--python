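# Methods

## Scope and model

`endospec` implements the image-processing chain of a stereo-multispectral
filter-wheel endoscope used to delineate cholesteatoma in the middle ear.
One acquisition yields, per camera, a broad-band RGB frame plus one RGB frame
per narrow-band illumination (centres 400–500 nm in 20 nm steps, FWHM
~20 nm).  The chain exploits one optical contrast — cholesteatoma reflects
markedly more than bone over 400–575 nm, while both look white under white
light — and one geometric resource, a calibrated stereo rig, to produce (a)
an augmented RGB view in which cholesteatoma turns bluish and (b) a metric
3D point cloud carrying the tissue information.

### Reflectance calibration (spectral)

Within 400–500 nm the red channel of the RGB sensor has no notable
sensitivity and green only responds from ~480 nm, so all quantitative work
uses the blue channel (`use_green_above_480` optionally averages G and B for
the 480/500 nm bands; default off, keeping the single-channel rule uniform).
Raw frames are flat-field corrected per band, `(raw − dark)/(white − dark)`,
clipped to [0, 1]; pixels whose white reference does not exceed the dark
frame carry no calibration signal and are flagged invalid and zeroed.
Clipping is a deliberate choice: the downstream overlay arithmetic assumes
bounded reflectance.  An optional per-image max normalisation after
flat-fielding is available but off by default.

### Overlay (enhance)

The overlay adds the calibrated narrow-band map to the blue channel only,
after dividing each broad-band channel by its own image maximum; the blue sum
is clipped to 1 rather than tone-mapped so R and G — and with them the
familiar colour impression — are untouched.  The narrow-band map is
`y = B_nb/B_cor` thresholded at `t`: zero below, the ratio itself above.
Design points where the procedure is under-determined:

* **Low-pass shape.** "Simple low-pass" is realised as a radial Gaussian
  attenuation in the frequency domain, `exp(−½(ρ/ρ_c)²)` with
  `ρ_c = cutoff × Nyquist` (default cutoff 0.25).  A brick-wall filter would
  ring at tissue edges; the Gaussian is monotone and leaves DC untouched, so
  the image mean is preserved exactly.
* **Auto threshold.** `t="auto"` is Otsu's split of the non-zero ratio
  histogram.  The scene premise is a bright cholesteatoma mode against a
  darker bone mode; Otsu finds that valley without per-scene hand tuning.  A
  fixed scalar can be supplied instead.  The auto rule assumes the dominant
  bimodality is bone-vs-cholesteatoma; it holds on the phantom because
  shading variation (see below) is kept smaller than the class separation.
* **Specular handling.** The intensity/saturation classifier
  (`I ≥ 0.8`, `S < 0.1`) marks highlight pixels.  The channel maxima for
  normalisation are computed *outside* the (dilated, default 1 px) mask —
  otherwise a single saturated pixel dims the whole channel — and the tissue
  contribution is zeroed on the mask.  An all-zero channel uses divisor 1
  with a warning.

### Stereo reconstruction (stereo3d)

Rectification consumes a calibration profile (Brown distortion coefficients
and per-camera rectifying rotations); calibration *estimation* is out of
scope.  Disparity follows a propagation/random-search scheme: random integer
initialisation inside the search window, per-iteration adoption of
neighbouring hypotheses (±1 row/column and ±3 columns) plus a random
perturbation whose radius halves each iteration, ZNCC cost over a 9×9
window, and a final three-point parabola fit for sub-pixel precision.
Because the search windows in endoscopic use are moderate (tens of pixels
around the working-distance disparity), candidate hypotheses are scored
against a precomputed per-integer-disparity cost volume; this keeps every
window comparison exact (each pixel's window is compared under a single
hypothesis) while preserving the propagation scheme's semantics.

Validity filtering is two-fold: a left–right consistency check (tolerance
1 px; the right-reference pass reuses the same matcher on the mirrored pair)
and a best-cost ceiling (`max_cost = 0.5`, i.e. ZNCC < 0.5) that removes
texture-free or saturated windows where the correlation carries no signal.
Holes are left as gaps; no inpainting.  Triangulation is closed form
(`z = f_px·B/d`, left-camera frame, x right / y down / z forward,
`d = x_left − x_right`), with `d ≤ 0.5 px` rejected as divergent.  The
sensor pixel pitch is not published for the reference device; the default
0.002 mm is an explicit assumption and mandatory to set for other hardware.

### Optical QC (optics_qc)

Charts are synthetic with exact frequency annotations, so no chart-detection
step exists and the measurement isolates the computation itself.  Modulation
is `(I_max − I_min)/(I_max + I_min)` of the region profile (row-averaged for
line charts, annulus pixels for circle charts), measured on the region
interior (edges are trimmed where blur mixes in the background).  MTF50 and
MTF10 come from linear interpolation between the bracketing samples after a
running-minimum isotonic cleanup; an unbracketed level is reported as
censored with the last frequency as a lower bound.  The degree of sharpness
is the finest circle group with modulation above 0.1.  Group summaries are
plain arithmetic means.

## Phantom generator

The phantom stands in for clinical recordings and defines the test
conditions:

* **Spectra.** Piecewise-linear reflectance curves: cholesteatoma 0.58–0.70
  and bone 0.27–0.40 over 400–575 nm (separation ≥ 0.15 everywhere in that
  window), soft tissue strongly blue-absorbing (0.08–0.18) rising in the
  red.  Only the ordering and the spectral window are constrained by tissue
  optics; absolute levels are plausible placeholders, configurable per
  scene.
* **Geometry.** A height field over the left-camera grid: smooth relief
  (default ±0.4 mm at ~48 px correlation length) about a base working
  distance (default 40 mm) inside the 20–60 mm working interval, optionally
  with an exact ray-traced sphere.  At the default rig a 512 px frame spans
  ~9 mm of tissue, so sub-millimetre relief is what keeps surface slopes in
  a realistic, mostly fronto-parallel regime.  True disparity and per-camera
  label maps follow in closed form; the right view is rendered by exact
  inverse warping through the true disparity field.
* **Shading and highlights.** Lambertian shading with the light co-located
  at the reference camera (coaxial endoscope illumination); a specular lobe
  (smooth bumps over ~1 % of pixels by default) added equally to all
  channels so the highlight classifier has real work.  Occlusion is not
  modelled (surfaces are smooth height fields); neither are subsurface
  scattering, wavelength-dependent penetration depth, inter-reflections, or
  motion between filter-wheel frames.  Passing tests therefore demonstrate
  the correctness of the computations under the stated image-formation
  model, not robustness to every clinical artefact.
* **Sensor.** Linear response `offset + gain × signal` (defaults 0.02 and
  0.75, leaving headroom so diffuse white tissue stays below the specular
  intensity threshold), Gaussian read noise and optional Poisson shot noise,
  both seeded.  Band radiances fall from 1.0 at 500 nm to 0.25 at 400 nm,
  reproducing the weak deep-blue illumination of the filter wheel.
* **Charts.** Sinusoidal gratings (as on sine-modulated resolution charts;
  square-wave bars are available as an option — note a blurred square wave
  measures the CTF, not the sine MTF).  Gratings are cosine-phase-aligned to
  the region origin, and the QC tests choose frequencies whose period is an
  even integer number of pixels, so sampled extrema are exact and the
  measured modulation matches the analytic Gaussian transfer function to
  ~1e−4.

## Problem sizes and tolerances

Test and acceptance runs use 128-row frames whose width is the standoff
disparity plus ~270 px of stereo overlap (512–760 px), three working
distances (25/40/55 mm) with 40 point-pair measurements each, and a
21×21×21 exhaustive RGB grid for the specular classifier.  These sizes give
stable statistics (disparity RMSE and IoU vary by < 0.02 across seeds) while
keeping a full suite run in the tens of seconds.  Numerical tolerances worth
knowing: the parabola sub-pixel stage shows classic pixel-locking of up to
~0.1 px near half-integer disparities; flat-field and triangulation
identities hold to machine precision; MTF10 interpolation error grows where
frequency samples are sparse in the exponential tail, so closed-form checks
are asserted on MTF50.

## Known limitations

* The disparity search window must be placed near the expected
  working-distance disparity (`min_disparity`); the default rig's standoff
  disparity (160–480 px over 20–60 mm) exceeds any practical blind search
  range at small frame widths.
* Per-wavelength chromatic aberration and distortion are not corrected; the
  rectification consumes a single broad-band calibration.
* The PLY writer/loader handles exactly the attribute layout this package
  emits (xyz float32 mm, RGB uint8, tissue float32, binary little-endian).
* `measure_distance` is pixel-addressed; it does not search for the nearest
  valid disparity, callers must handle invalid pixels.
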