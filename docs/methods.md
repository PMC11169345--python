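# Methods

`pmrf` models and analyzes a polarization-split, pupil-matched
remote-focusing (pmRF) detection path for light-sheet microscopy. This note
records the models, the numerical choices, and what the synthetic-data
round trips do and do not demonstrate.

## Paraxial model of the detection path (`pmrf.optics`)

Rays are reduced-angle vectors `[n·α, y]ᵀ` (radians·index, mm) propagated by
left-multiplication with 2×2 unimodular matrices: translations
`[[1, 0], [d/n, 1]]` and thin lenses `[[1, −n/f], [0, 1]]`. The medium index
is 1.33 (water) up to and including the detection objective and 1 (air)
afterwards. The objective's effective focal length follows the
manufacturer's convention `f_obj = f_tube·n/M_obj`; for the 40×/0.8 water
objective with its 200 mm design tube lens, 6.65 mm.

The folded pmRF module — polarizing beam splitter, fold mirrors, remote
objective (obj2), quarter-wave plate, and the voice-coil mirror — is
unfolded for matrix algebra: folds are bookkeeping rotations that leave the
ray state unchanged (paraxial ABCD propagation is fold-invariant), and the
module appears twice in the element sequence to model the forward and
backward pass. The mirror travel becomes a variable gap between the two
copies of obj2. The S/P image separation at the mirror is
`ΔL = f_obj2·θ` with θ the launch angle (8° in the shipped preset, giving
ΔL ≈ 1.40 mm with f_obj2 = 10 mm).

Image planes are located from the imaging condition `T[1,0] = 0` of the
object-to-plane transfer matrix `T`; because any single gap enters exactly
one translation matrix, solving for the mirror gap that holds the
de-scanned image distance S3 fixed is an exact linear solve, not an
iteration. Lateral magnification at an image plane is `T[1,1]`. For an
exactly afocal configuration (the ideal 4f limit with the object at the
front focal plane) the last finite ray crossing — the stationary
intermediate image at the mirror — is reported instead, and the scan
surrogate restores afocality (`T[0,0] = 0`) rather than a finite S3.

Two configurations ship:

* **4f-nominal** — every gap equals the sum of the adjacent focal lengths.
  Its remote magnification is analytically `M_obj·f_obj2/f_L5 = 4/3` with
  the catalogue lenses (f_L4 = 200, f_L5 = 300, f_obj2 = 10 mm),
  independent of the immersion index; it equals `n_water/n_air` exactly
  only when f_L5 is chosen for perfect pupil matching
  (`f_L5 = M_obj·f_obj2/n_water ≈ 300.75 mm`). Both variants are exercised
  in the tests.
* **as-built preset** — the instrument's non-4f values (obj1→L4 ≈ 100 mm,
  PBS→obj2 ≈ 500 mm, S1 = 6.695 mm) with the unknown L5→PBS distance
  (150 mm) and de-scanned image distance (S3 = 20 mm) carried as
  *estimates*. With these estimates the traced magnification is ≈1.42 with
  a smooth, monotone ≈6 %-per-80 µm scan dependence — qualitatively the
  as-built behavior; the exact values depend on distances that were only
  ruler-measured on the instrument and are not reproducible at a desk.
  The d1/S1 calibration helpers fit those scalars to measured
  magnification data by bounded scalar least squares.

Collection efficiency uses a deliberately simple clipping model: the
returning beam footprint at obj2's aperture is a disk of radius
`R·(f_obj2+|defocus|)/f_obj2` centered at the lateral field offset, with
`R = f_obj2·NA_obj2`; the efficiency is the closed-form two-circle
intersection area over the footprint area. A literal flat-mirror double
pass returns every ray to its original aperture height, and a one-sided
defocus model is not symmetric in the defocus sign, so the magnitude
`|defocus|` enters the footprint — this keeps the model symmetric,
monotone, and consistent with a Monte-Carlo ray-fan oracle to < 0.01,
while remaining qualitative: it is not the instrument's full vignetting
analysis.

θ selection is a 0.1° grid search over a footprint objective
`r_beam + f_obj2·θ/2 + c/θ` whose last term models the growing PBS→obj2
distance required for the fold mirrors to clear each other at small θ
(`c = 0.1` mm·rad by default, configurable); only the trade-off shape, not
the constant, is asserted anywhere.

## Sub-pixel S/P registration (`pmrf.registration`)

The offset between the S- and P-polarized images is the peak of the scaled
circular cross-correlation: both images are mean-subtracted and the FFT
correlation is normalized by the product of their Euclidean norms, so the
noiseless autocorrelation peaks at exactly 1. Sub-pixel refinement fits a
second-order polynomial per axis through the peak ±w samples (w = 2 by
default; w = 1 reproduces the closed-form three-point vertex
`(a−c)/(2(a−2b+c))`). Integer ties break toward the smallest absolute lag.

A `gaussian` interpolation method fits the parabola to the log of the peak
samples instead, which is exact when the correlation peak is
Gaussian-shaped. Volumetric registration of PSF-limited spot content uses
it by default because the plain parabola shows ~0.1 px peak-locking bias on
peaks only 1–2 px wide; 2D S/P image registration keeps the plain
parabolic default. Offsets are reported in index order, positive when the
second image is displaced toward increasing index.

The alignment monitor replays the hardware procedure (reference from one
blocked path, streamed frames from the other) and flags convergence when
the max-norm offset stays under a threshold (0.1 px default) for k
consecutive frames (3).

## Bead and light-sheet characterization (`pmrf.psf`)

Per-axis resolution is the FWHM (`2√(2 ln 2)·σ`) of a least-squares
Gaussian-plus-baseline fit to the bead intensity profile. Lateral profiles
are taken from a maximum-intensity projection of 10 slices spaced 500 nm
around the bead (matching the bead-figure protocol; raw-profile mode is
available), the axial profile from the raw stack. The estimator is exact
to < 1e−6 relative error on noiseless sampled Gaussians for σ between 1.5
and 6 px.

Beads are detected on the Z MIP by normalized cross-correlation against
the PSF model's Z MIP (`match_template`), with three selection rules:
correlation threshold (0.5), a brightness floor of median + 5·MAD-σ of the
background, and a separation rule that rejects *both* members of any pair
closer than `min_separation` (overlapping profiles corrupt both fits).
Sub-resolution candidate clusters (≤ 3 px apart — one bead centered
between voxels produces a correlation plateau) are merged before the
separation rule. The PSF model itself is parametric (3D Gaussian) or
loaded from an array; inverse PSF modeling from bead data is out of scope.

Light-sheet geometry: because the sheet waist translates in Y as Z is
scanned (coverslip tilt), bead Y positions are corrected to
`y′ = y − a·z`. The tilt `a` is estimated by locating the Y of minimum
axial width per Z slab (local parabola vertex) and regressing it on Z.
`FWHM_z(y′)` is then fit with an even polynomial; the waist is the
polynomial minimum and the usable FOV the width at twice the minimum.
The even degree defaults to 6: for an exact Gaussian-beam profile
(`W0·√(1+(y′/yR)²)`, FOV `2√3·yR`) sampled over ±2.5–3 yR, a degree-4
even fit biases the waist and FOV by 2.5–10 % while degree 6 stays under
1.5 %, inside the 2 % accuracy the quantification is expected to hold on
exact profiles.

Resolution summaries group measurements into 5 µm axial segments (each
measurement in exactly one segment; empty segments omitted), reporting
mean ± s.d. per axis with an optional polynomial trend over segment means.

## Magnification calibration (`pmrf.magnification`)

Relative magnification between scan positions: the isotropic zoom of the
best-fit similarity map to the reference image, found by maximizing the
translation-invariant scaled correlation over a bounded zoom search
(coarse grid, then bounded scalar refinement to 1e−5), on 700×700 center
crops. Shear is ignored; only the zoom factor is consumed.

Absolute magnification: the line-target profile is averaged along the line
direction (auto-detected from profile variance), smoothed with a centered
30 px running average (reflected edges), and all peaks with ≥ 10 %
prominence are located with parabolic sub-pixel refinement. The sample-
plane pixel size is `spacing/Δd` (10 µm line period) and the magnification
`camera_pixel / pixel_size`. The 30 px window presumes the real system's
~85 px line spacing; for coarser renderings the window is a parameter. The
curve anchors the absolute value at the reference position (closest to
0 µm by default) and propagates it through the zoom factors.

## Live-cell pipeline (`pmrf.pipeline`)

Stages, in order: user crop → per-time-point drift estimation (2D
registrations of the three MIPs; each axis is observed by two projections
and the two estimates are averaged, with per-channel estimates averaged
over channels) → drift correction (linear-interpolation shifts, edges
filled with background) → single rigid inter-channel shift (estimated
after time-averaging each channel) → Richardson–Lucy deconvolution
(`skimage.restoration`, unit-sum PSF, clip disabled; 20 iterations by
default) → linear resampling along the scan axis to the lateral pitch →
per-(time, channel) normalization: subtract a scalar background (default:
histogram mode of the first frame), clamp at zero, divide by the 99.95 %
quantile, which also flattens photobleaching. The drift reference is the
first time point. All stages before normalization are 1-homogeneous, so
rescaled inputs give identical normalized outputs.

## Granule tracking and MSD analysis (`pmrf.tracking`)

Linking is greedy mutual-nearest-neighbor between consecutive frames
within a displacement gate — deliberately simple plumbing (no gap closing
or merge/split handling, which full cost-matrix trackers provide).

The time-averaged MSD uses all ordered pairs per lag, with lags limited to
1/4 of the track length (longer lags average too few, strongly correlated
pairs). The motion model is

    MSD(t) = 6 D t + v² t² + o

with D the diffusion coefficient, v a constant transport speed, and o an
offset absorbing localization error. The model is linear in (D, v², o),
fit by bound-constrained (D ≥ 0, v² ≥ 0, o free) generalized least squares
with the standard time-averaged-MSD variance approximation
`var(MSD_k) ≈ MSD_k²(2k²+1)/(3k(N−k))`; unweighted fits let the noisy long
lags dominate and skew the per-track estimates low. A strict mode fits the
degenerate variant `6Dt² + v²t² + o` for comparison; there the two motion
terms share one time power and only their sum is identifiable, which is
why the distinct-powers form is the default.

Classification: when the trajectory is available, directed motion is
detected by Hotelling's T² on the per-frame steps — under pure Brownian
motion the steps are i.i.d. zero-mean Gaussian, making the test exactly
calibrated (measured type-I error 4.4 % at α = 0.05 on 80-frame tracks,
power ≈ 1 at 0.1 µm/s over 80 frames at 0.6 volumes/s); localization noise
only makes it conservative. The curve-only fallback is a nested-model
F-test of the quadratic term, documented as anticonservative because
TA-MSD values are correlated across lags (~38 % empirical type-I on the
same tracks). The reported (D, v, o) come from the selected model:
pure-diffusion values (v = 0) for a Brownian call, full-model values for a
directed one — keeping an unsupported quadratic term would siphon variance
from the diffusive slope and bias D low (~19 % at the reference
conditions).

Population summaries filter at D > 0.001 µm²/s, report histograms, the
empirical CDF of D, and a fold change between two populations as the ratio
of mean D.

## Synthetic data (`pmrf.simulate`, `pmrf.workflows`)

All generators are pure functions of a `SimulationSpec` and its seed.
Defaults mirror the characterization conditions: 104 nm lateral / 500 nm
axial pitch, PSF FWHMs (570, 666, 924) nm in (X, Y, Z), light-sheet waist
850 nm with Rayleigh-like length yR = 2.3 µm and Y-per-Z tilt 0.14, Z scan
of ±10 µm at 500 nm steps, granules at D = 0.41 µm²/s sampled at 8.3
volumes/s for 80 frames. Noise is Poisson on expected photons plus
Gaussian read noise (σ = 2) and a 100-count camera offset. Beads are 3D
Gaussians (the 200 nm bead diameter is well below the PSF width); when the
light-sheet envelope is enabled the axial width at each bead follows
`W0·√(1+(y′/yR)²)`. yR is a free parameter rather than derived from an
illumination NA.

Granule walks use per-axis steps `N(v·Δt, √(2DΔt))` with reflecting
boundaries so track lengths stay fixed. Movies render the granules with
the PSF each frame (channel 0); channel 1 is a membrane-like spherical
shell (30 % of the smallest volume extent, so drift never clips it at the
boundary — truncation biases registration) plus a configurable fraction
(0.5) of the granule signal, because a second channel with *no* shared
structure would make the inter-channel shift unobservable to
content-based registration, as it is in any real two-color cell only
approximately. Global drift accumulates per frame; the second channel is
additionally displaced by the configured inter-channel offset.

The `workflows` module chains generate → detect → measure for the
round-trip protocols (bead resolution on a 20-bead jittered grid with a
3 µm border margin clear of the detector's edge-exclusion zone;
light-sheet quantification on 60 beads spread over Y and Z; D and v
recovery on 200 tracks). These closures validate the estimators against
known truth under the model's own assumptions — Gaussian PSFs, scalar
background, rigid drift, ideal labeling. They do not probe aberrated or
spatially varying PSFs, structured background, sample deformation, or
detection/linking failures in dense fields, so passing them bounds
implementation error, not real-data performance.

## Problem sizes

Default test and acceptance runs use 20-bead fields (220×220×41 voxels),
60-bead light-sheet fields (128×128×41), 5-frame dual-color movies
(48×48×24), and 200–1000 simulated tracks of 80 frames — sizes chosen so
each round trip isolates one estimator with comfortable statistics while
the whole suite stays quick to iterate on.

## Known limitations

* Paraxial, aberration-free optics: no Zernike/vectorial modeling, no
  polarization-dependent Fresnel losses; collection efficiency is a
  qualitative clipping model.
* The as-built magnification curve depends on gap estimates for distances
  the instrument's builders measured with a ruler; only its qualitative
  shape is meaningful.
* Registration assumes pure translation (no rotation/scale between S and
  P beyond the calibration module's zoom estimate).
* The tracker stand-in has no gap closing or merge/split handling.
* MSD classification assumes constant-velocity transport; per-step motion
  state switching is not modeled.
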