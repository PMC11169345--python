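# pmrf

Analysis toolkit for **polarization-split, pupil-matched remote-focusing
(pmRF) light-sheet microscopy**.

Remote focusing scans a microscope's focal plane by translating a small
mirror behind a second, "remote" objective instead of moving the sample or
the heavy detection objective. Fluorescence is unpolarized, so a
polarizing beam splitter normally discards half of it; the split design
modeled here sends the S- and P-polarized halves through the remote module
separately and recombines them on the camera, recovering the light at the
cost of two overlaid images that must be registered to sub-pixel accuracy.
This package implements the computational machinery around such an
instrument:

* **`pmrf.optics`** — paraxial ABCD ray tracing of the folded detection
  path. Rays are reduced-angle vectors `[nα, y]ᵀ`; translations are
  `[[1, 0], [d/n, 1]]`, thin lenses `[[1, −n/f], [0, 1]]`, and the remote
  module is traced twice (forward and backward pass) with the mirror
  travel as a variable gap. Gives the effective focal length
  `f_obj = f_tube·n/M`, the S/P image separation `ΔL = f_obj2·θ`,
  image-plane positions, magnification-vs-scan curves, and a geometric
  collection-efficiency model.
* **`pmrf.registration`** — sub-pixel S/P image and stack registration via
  scaled cross-correlation with polynomial peak interpolation, plus the
  interactive alignment monitor.
* **`pmrf.psf`** — bead detection, per-axis Gaussian FWHM
  (`2√(2 ln 2)·σ`) measurement on MIP slabs, axial-segment resolution
  summaries, and light-sheet waist/FOV quantification from the
  tilt-corrected axial-width profile `FWHM_z(y′)`, `y′ = y − a·z`.
* **`pmrf.magnification`** — relative zoom and absolute magnification from
  parallel-line calibration targets (peak spacing Δd, pixel size
  `10 µm/Δd`).
* **`pmrf.pipeline`** — the dual-color live-cell chain: crop, MIP-based
  drift correction, channel registration, Richardson–Lucy deconvolution,
  isotropic resampling, 99.95 %-quantile normalization.
* **`pmrf.tracking`** — granule trajectory linking, time-averaged MSD,
  and bound-constrained fits of `MSD(t) = 6Dt + v²t² + o` with
  Brownian-vs-directed classification.
* **`pmrf.simulate` / `pmrf.workflows`** — seeded generators for every
  input above (bead stacks under a tilted Gaussian light sheet, S/P
  pairs, line targets, dual-color granule movies with drift and noise),
  and closed-loop generate→measure protocols with ground truth.

See `docs/methods.md` for the models, defaults, and their limitations.

## Worked example

```python
from pmrf.optics import build_detection_model, as_built_model, \
    trace_field, magnification_vs_scan
from pmrf.workflows import bead_resolution_protocol, brownian_recovery

model = build_detection_model(all_4f=True)
res = trace_field(model)
print(f"f_obj = {model.f_obj:.2f} mm, delta_L = {model.delta_l:.3f} mm")
print(f"4f lateral magnification: {res.lateral_magnification:.4f}")

for off, m in magnification_vs_scan(as_built_model(), [-40, 0, 40]):
    print(f"offset {off:+.0f} um -> M = {abs(m):.3f}")

beads = bead_resolution_protocol(seed=1)
print(f"n = {len(beads)} beads: FWHM x/y/z = "
      f"{beads.fwhm_x.mean():.0f}/{beads.fwhm_y.mean():.0f}/"
      f"{beads.fwhm_z.mean():.0f} nm")

d, fits = brownian_recovery(d_um2_s=0.41, seed=1)
print(f"median D = {d:.3f} um^2/s over {len(fits)} tracks")
```

prints

```
f_obj = 6.65 mm, delta_L = 1.396 mm
4f lateral magnification: 1.3333
offset -40 um -> M = 1.343
offset +0 um -> M = 1.422
offset +40 um -> M = 1.512
n = 20 beads: FWHM x/y/z = 569/665/923 nm
median D = 0.381 um^2/s over 200 tracks
```

Reading the numbers: the 40×/0.8 water objective with a 200 mm design tube
lens has a 6.65 mm effective focal length, and an 8° S/P launch angle
separates the two images by 1.40 mm at the remote mirror. In the ideal 4f
limit the remote image is magnified by ≈ 4/3 — the water-to-air
refractive-index ratio required for aberration-free remote focusing — while
the as-built (non-4f) preset lands near 1.42 with a smooth few-percent
drift across the ±40 µm scan. The bead round trip recovers the generator's
570/666/924 nm resolutions from rendered, noisy bead fields, and the MSD
fit recovers a 0.41 µm²/s diffusion coefficient (median 0.38 over 200
simulated 80-frame tracks at 8.3 volumes/s with 30 nm localization noise).

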