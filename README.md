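# endospec

Multispectral stereo-endoscopy analysis for image-guided cholesteatoma
surgery.

Cholesteatoma is a destructively growing squamous-epithelium mass of the
middle ear.  Under white surgical light it looks just like the surrounding
bone, which makes complete resection — the only cure — hard even for
experienced surgeons.  Two optical facts make it tractable: cholesteatoma
reflects markedly more light than bone throughout 400–575 nm, and a
calibrated stereo endoscope turns image coordinates into millimetres.
`endospec` implements the resulting processing chain for a filter-wheel
stereo endoscope that alternates broad-band (white) illumination with
narrow-band illumination at 400–500 nm (~20 nm FWHM):

* **spectral** — narrow-band reflectance calibration.  Within 400–500 nm only
  the blue sensor channel carries signal, so analysis uses B only; each raw
  frame is flat-field corrected, `(raw − dark) / (white − dark)`.
* **enhance** — the augmented overlay.  With per-channel max normalisation,

      R_res = R_bb / max(R_bb)
      G_res = G_bb / max(G_bb)
      B_res = B_bb / max(B_bb) + B_nb_cal

  where `B_nb_cal = y·[y ≥ t]`, `y = B_nb / B_cor`, is the thresholded,
  calibrated narrow-band map: cholesteatoma turns bluish, everything else
  keeps its colour balance.  Specular highlights — intensity
  `I = (R+G+B)/3 ≥ 0.8` with saturation `S < 0.1`, where
  `S = 3/2 (R − I)` if `(B+R) ≥ 2G` else `3/2 (I − B)` — are excluded from
  the enhancement.  Frequency-domain Gaussian low-pass filtering suppresses
  sensor noise in the weak deep-blue frames.
* **stereo3d** — rectification, dense sub-pixel disparity by a
  propagation/random-search (PatchMatch-style) matcher with ZNCC cost and
  parabolic refinement, and closed-form triangulation `z = f_px·B/d` into a
  metric spectral point cloud (PLY) on which point-to-point distances are
  measured in mm.
* **optics_qc** — MTF50/MTF10 readouts from line charts, degree of sharpness
  from concentric-circle charts, and group averages (deep-blue bands vs the
  rest) quantifying the wavelength dependence of endoscope sharpness.
* **phantom** — a synthetic middle-ear phantom generator (tissue spectra,
  depth-varying surface, stereo projection with the reference rig geometry —
  focal length 4.63 mm, inter-axial distance 4.16 mm — specular lobes, sensor
  noise, test charts) that provides every pipeline input with ground truth.
* **app** — a `click` CLI (`endospec run / phantom / enhance / reconstruct /
  measure / qc`) and a reproducible end-to-end pipeline runner.

## Worked example

```python
import numpy as np
from endospec import enhance, phantom, spectral, stereo3d
from endospec.rig import CameraRig

rig = CameraRig()  # f = 4.63 mm, baseline = 4.16 mm, pixel pitch 0.002 mm
scene = phantom.make_scene(phantom.SceneConfig(seed=1, shape=(128, 512),
                                               cholesteatoma_fraction=0.3))
render = phantom.render_sequence(scene, rig)
calib = phantom.render_calibration_frames(shape=scene.shape)

band = render.left.band(420)  # deep-blue narrow-band frame
raw = spectral.select_analysis_channel(render.left.narrowband[band], band)
refl = spectral.flat_field_correct(raw, calib.dark, calib.white[band], band=band)
tissue = enhance.compute_tissue_map(refl, None, t="auto")
overlay = enhance.compose_overlay(render.left, tissue)
print(f"auto threshold t = {tissue.threshold_used:.3f}")
print(f"tissue pixels    = {100 * (tissue.values > 0).mean():.1f} % of frame")

disparity = stereo3d.estimate_disparity(render.left.broadband, render.right.broadband,
                                        search_range=16, min_disparity=233, seed=1)
cloud = stereo3d.triangulate(disparity, rig)
cloud = stereo3d.attach_spectral(cloud, overlay, tissue)
print(f"valid disparity  = {100 * disparity.valid.mean():.1f} % of pixels")
print(f"3D points        = {len(cloud)}")
mm = stereo3d.measure_distance(cloud, (40, 300), (90, 430))
print(f"distance (40,300)-(90,430) = {mm:.3f} mm")
```

prints

```
auto threshold t = 0.415
tissue pixels    = 30.1 % of frame
valid disparity  = 52.3 % of pixels
3D points        = 34288
distance (40,300)-(90,430) = 2.483 mm
```

The Otsu-selected threshold 0.415 sits between the bone (~0.3) and
cholesteatoma (~0.6) reflectance modes, so the 30.1 % of enhanced pixels
track the requested 30 % cholesteatoma coverage.  Valid disparities cover the
stereo-visible part of the frame (the standoff disparity at 40 mm is ~241 px),
and the measured 2.48 mm distance agrees with the ground-truth separation of
those two surface points to a few micrometres.

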