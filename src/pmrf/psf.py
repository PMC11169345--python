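"""Bead-based resolution and light-sheet characterization.

Resolution is quantified from sub-diffraction (200 nm) beads: beads are
detected by normalized cross-correlation against the Z maximum-intensity
projection of a PSF model, per-axis intensity profiles are fit with a
Gaussian plus baseline, and the full width at half maximum
(FWHM = 2*sqrt(2 ln 2)*sigma) is reported in nm.  Lateral widths are
measured on a MIP of 10 slices spaced 500 nm around the focal plane by
default; the axial width comes from the raw Z profile.

The light-sheet dimensions are recovered from the Y-dependence of the axial
width: because the sheet waist translates in Y while the volume is scanned in
Z (tilt coefficient ``a``), bead Y positions are first corrected to
``y' = y - a*z``; FWHM_z(y') is then fit with an even polynomial whose
minimum is the waist and whose doubling width is the usable field of view
(for a Gaussian beam, FOV = 2*sqrt(3)*y_R).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage.feature import match_template, peak_local_max

__all__ = [
    "VolumeStack",
    "PSFModel",
    "FWHMMeasurement",
    "LightSheetQuant",
    "FWHM_PER_SIGMA",
    "gaussian_psf_model",
    "crop_lightsheet_region",
    "detect_beads",
    "measure_fwhm",
    "measure_bead_fwhm",
    "mip_slab",
    "summarize_resolution",
    "quantify_lightsheet",
]

#: FWHM of a Gaussian in units of sigma.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class VolumeStack:
    """3D intensity volume in (Z, Y, X) order with physical voxel pitch.

    ``pitch`` is (z, y, x) in um/voxel.  Z is the scan (detection) axis and Y
    the light-sheet propagation axis.
    """

    voxels: np.ndarray
    pitch: tuple
    z_is_scan_axis: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("VolumeStack expects a 3D (Z, Y, X) array")
        self.pitch = tuple(float(p) for p in self.pitch)
        if len(self.pitch) != 3 or any(p <= 0 for p in self.pitch):
            raise ValueError("pitch must be three positive values (z, y, x)")


@dataclass
class PSFModel:
    """Small 3D PSF array, unit sum, centered; optionally parametric."""

    model_stack: np.ndarray
    pitch: tuple
    sigma_um: tuple | None = None  # (z, y, x) if parametric

    def __post_init__(self):
        self.model_stack = np.asarray(self.model_stack, dtype=float)
        s = self.model_stack.sum()
        if s <= 0:
            raise ValueError("PSF model must have positive total intensity")
        self.model_stack = self.model_stack / s

    def z_mip(self) -> np.ndarray:
        return self.model_stack.max(axis=0)


def gaussian_psf_model(fwhm_nm, pitch_um, n_sigma: float = 4.0) -> PSFModel:
    """Parametric 3D Gaussian PSF with per-axis FWHM (z, y, x) in nm."""
    fwhm = np.asarray(fwhm_nm, dtype=float) * 1e-3  # nm -> um
    pitch = np.asarray(pitch_um, dtype=float)
    sigma_um = fwhm / FWHM_PER_SIGMA
    sigma_vox = sigma_um / pitch
    half = np.maximum(3, np.ceil(n_sigma * sigma_vox).astype(int))
    grids = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
    r2 = sum((g / s) ** 2 for g, s in zip(grids, sigma_vox))
    return PSFModel(model_stack=np.exp(-0.5 * r2), pitch=tuple(pitch),
                    sigma_um=tuple(sigma_um))


# --------------------------------------------------------------------------
# cropping and projections
# --------------------------------------------------------------------------

def crop_lightsheet_region(stack: VolumeStack, fov_length: float,
                           tilt_a: float, y0: float | None = None):
    """Per-slice Y-crop of width ``fov_length`` (um) tracking the waist line.

    The sheet waist sits at ``y_waist(z) = y0 + a*z`` (um, with a the Y shift
    per um of Z travel); each Z slice is cropped around it.  Windows align to
    integer voxels with the fractional remainder carried so the mean window
    center tracks the waist line exactly.  Returns ``(cropped, clipped)``
    where ``clipped`` flags slices whose window hit the volume edge.
    """
    pz, py, _ = stack.pitch
    nz, ny, nx = stack.voxels.shape
    if fov_length > ny * py:
        raise ValueError("fov_length exceeds the Y extent of the stack")
    if y0 is None:
        y0 = 0.5 * ny * py
    half_vox = max(1, int(round(0.5 * fov_length / py)))
    width = 2 * half_vox

    out = np.zeros((nz, width, nx), dtype=stack.voxels.dtype)
    clipped = np.zeros(nz, dtype=bool)
    carry = 0.0
    any_inside = False
    for iz in range(nz):
        z_um = (iz - nz // 2) * pz
        center_exact = (y0 + tilt_a * z_um) / py + carry
        c = int(round(center_exact))
        carry = center_exact - c
        lo, hi = c - half_vox, c + half_vox
        lo_c, hi_c = max(lo, 0), min(hi, ny)
        if lo_c >= hi_c:
            clipped[iz] = True
            continue
        any_inside = True
        out[iz, lo_c - lo:hi_c - lo, :] = stack.voxels[iz, lo_c:hi_c, :]
        clipped[iz] = (lo_c != lo) or (hi_c != hi)
    if not any_inside:
        raise ValueError("waist line exits the frame for every slice")
    cropped = VolumeStack(voxels=out, pitch=stack.pitch,
                          z_is_scan_axis=stack.z_is_scan_axis,
                          metadata=dict(stack.metadata, crop="lightsheet"))
    return cropped, clipped


def mip_slab(stack: VolumeStack, axis: int = 0, center: int | None = None,
             n_slices: int = 10) -> np.ndarray:
    """Maximum-intensity projection over a slab of ``n_slices`` along an axis.

    The slab is centered on ``center`` (defaults to the middle of the axis)
    and clipped to the stack bounds with a warning flag in the metadata.
    """
    n = stack.voxels.shape[axis]
    if center is None:
        center = n // 2
    lo = center - n_slices // 2
    hi = lo + n_slices
    lo_c, hi_c = max(lo, 0), min(hi, n)
    if lo_c >= hi_c:
        raise ValueError("slab lies entirely outside the stack")
    sel = [slice(None)] * 3
    sel[axis] = slice(lo_c, hi_c)
    return stack.voxels[tuple(sel)].max(axis=axis)


# --------------------------------------------------------------------------
# bead detection
# --------------------------------------------------------------------------

def detect_beads(stack: VolumeStack, psf: PSFModel,
                 corr_threshold: float = 0.5, min_separation: float = 1.0,
                 brightness_nsigma: float = 5.0) -> pd.DataFrame:
    """Detect well-separated, sufficiently bright beads in a stack.

    Candidate (y, x) positions are local maxima of the normalized
    cross-correlation between the stack's Z MIP and the PSF model's Z MIP
    exceeding ``corr_threshold``; the bead Z is the argmax of the raw profile
    at that position.  Any pair of candidates closer than ``min_separation``
    (um, lateral) is rejected outright (both members), and candidates whose
    peak is below ``mean + brightness_nsigma * std`` of the background are
    dropped.  Returns a DataFrame with voxel indices and um positions.
    """
    if not np.allclose(psf.pitch, stack.pitch, rtol=1e-3):
        raise ValueError("PSF pitch must match the stack pitch")
    mip = stack.voxels.max(axis=0).astype(float)
    templ = psf.z_mip()
    if any(t >= s for t, s in zip(templ.shape, mip.shape)):
        raise ValueError("PSF model larger than the field")
    corr = match_template(mip, templ, pad_input=True)
    coords = peak_local_max(corr, threshold_abs=corr_threshold,
                            exclude_border=max(templ.shape) // 2)
    if len(coords) == 0:
        return _empty_detections()

    # merge sub-resolution candidate clusters (a bead centered between
    # voxels yields a correlation plateau with several argmax voxels)
    merge_px = 3
    merged, used = [], np.zeros(len(coords), dtype=bool)
    for i in range(len(coords)):
        if used[i]:
            continue
        cluster = [coords[i]]
        used[i] = True
        for j in range(i + 1, len(coords)):
            if not used[j] and np.max(np.abs(coords[j] - coords[i])) <= merge_px:
                cluster.append(coords[j])
                used[j] = True
        merged.append(np.round(np.mean(cluster, axis=0)).astype(int))
    coords = np.array(merged)

    # separation rule: reject every member of a too-close pair
    py, px = stack.pitch[1], stack.pitch[2]
    pos_um = coords * np.array([py, px])
    keep = np.ones(len(coords), dtype=bool)
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if np.linalg.norm(pos_um[i] - pos_um[j]) < min_separation:
                keep[i] = keep[j] = False
    coords = coords[keep]

    # brightness floor from a robust background estimate
    bg = np.median(mip)
    bg_sigma = 1.4826 * np.median(np.abs(mip - bg))
    floor = bg + brightness_nsigma * max(bg_sigma, 1e-12)

    rows = []
    for iy, ix in coords:
        profile = stack.voxels[:, iy, ix].astype(float)
        iz = int(np.argmax(profile))
        if mip[iy, ix] < floor:
            continue
        rows.append(dict(z_vox=iz, y_vox=int(iy), x_vox=int(ix),
                         z_um=iz * stack.pitch[0], y_um=iy * py,
                         x_um=ix * px, peak=float(mip[iy, ix]),
                         correlation=float(corr[iy, ix])))
    if not rows:
        return _empty_detections()
    return pd.DataFrame(rows)


def _empty_detections() -> pd.DataFrame:
    return pd.DataFrame(columns=["z_vox", "y_vox", "x_vox", "z_um", "y_um",
                                 "x_um", "peak", "correlation"])


# --------------------------------------------------------------------------
# FWHM measurement
# --------------------------------------------------------------------------

def _gaussian1d(x, amp, mu, sigma, baseline):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + baseline


def measure_fwhm(profile, pitch: float) -> tuple[float, float]:
    """Gaussian-fit FWHM of a 1D intensity profile.

    ``pitch`` is the sample spacing in um; the result is in nm, together with
    the residual norm of the fit.  Raises on non-convergence so callers can
    flag and exclude the measurement.
    """
    y = np.asarray(profile, dtype=float)
    if y.size < 7:
        raise ValueError("profile too short for a stable Gaussian fit")
    x = np.arange(y.size, dtype=float)
    baseline0 = y.min()
    amp0 = y.max() - baseline0
    if amp0 <= 0:
        raise ValueError("profile has no peak")
    mu0 = float(np.argmax(y))
    above = y - baseline0 > amp0 / 2
    sigma0 = max(above.sum() / FWHM_PER_SIGMA, 0.5)
    popt, _ = curve_fit(_gaussian1d, x, y,
                        p0=[amp0, mu0, sigma0, baseline0], maxfev=5000)
    sigma = abs(popt[2])
    resid = float(np.linalg.norm(y - _gaussian1d(x, *popt)))
    return FWHM_PER_SIGMA * sigma * pitch * 1e3, resid


@dataclass
class FWHMMeasurement:
    """Per-bead, per-axis Gaussian-fit widths at one scan position."""

    bead_id: int
    position_um: tuple        # (z, y, x)
    fwhm_x: float             # nm
    fwhm_y: float
    fwhm_z: float
    fit_quality: float        # summed residual norms
    valid: bool = True


def measure_bead_fwhm(stack: VolumeStack, position_vox, bead_id: int = 0,
                      lateral_mode: str = "mip", mip_slices: int = 10,
                      window_vox: int | None = None) -> FWHMMeasurement:
    """Per-axis FWHM of one bead.

    ``lateral_mode='mip'`` (default, matching the bead-figure protocol)
    measures X and Y on a MIP of ``mip_slices`` Z slices centered on the
    bead; ``'raw'`` uses raw profiles through the bead center.  The Z profile
    is always taken from the raw stack.
    """
    iz, iy, ix = (int(v) for v in position_vox)
    pz, py, px = stack.pitch
    if window_vox is None:
        window_vox = max(7, min(31, min(stack.voxels.shape[1:]) // 2))
    w = window_vox

    def clamp(c, n):
        lo = max(c - w, 0)
        hi = min(c + w + 1, n)
        return lo, hi

    nz, ny, nx = stack.voxels.shape
    ylo, yhi = clamp(iy, ny)
    xlo, xhi = clamp(ix, nx)
    zlo, zhi = clamp(iz, nz)

    if lateral_mode == "mip":
        lateral = mip_slab(stack, axis=0, center=iz, n_slices=mip_slices)
    elif lateral_mode == "raw":
        lateral = stack.voxels[iz]
    else:
        raise ValueError("lateral_mode must be 'mip' or 'raw'")

    resid = 0.0
    try:
        fx, r = measure_fwhm(lateral[iy, xlo:xhi], px)
        resid += r
        fy, r = measure_fwhm(lateral[ylo:yhi, ix], py)
        resid += r
        fz, r = measure_fwhm(stack.voxels[zlo:zhi, iy, ix], pz)
        resid += r
        valid = True
    except (ValueError, RuntimeError):
        fx = fy = fz = math.nan
        valid = False
    return FWHMMeasurement(bead_id=bead_id,
                           position_um=(iz * pz, iy * py, ix * px),
                           fwhm_x=fx, fwhm_y=fy, fwhm_z=fz,
                           fit_quality=resid, valid=valid)


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def summarize_resolution(measurements, segment_height: float = 5.0,
                         trend_degree: int | None = None) -> pd.DataFrame:
    """Per-Z-segment mean and std of the per-axis FWHMs.

    Measurements are grouped into axial segments of ``segment_height`` um
    (each measurement belongs to exactly one segment); invalid measurements
    are excluded, empty segments omitted.  If ``trend_degree`` is given, a
    polynomial trend is fit to the segment means and evaluated per segment.
    """
    rows = [m for m in measurements if m.valid]
    if not rows:
        raise ValueError("no valid measurements to summarize")
    df = pd.DataFrame([dict(bead_id=m.bead_id, z_um=m.position_um[0],
                            fwhm_x=m.fwhm_x, fwhm_y=m.fwhm_y,
                            fwhm_z=m.fwhm_z) for m in rows])
    df["segment"] = np.floor(df["z_um"] / segment_height).astype(int)
    out = df.groupby("segment").agg(
        z_center=("z_um", "mean"), n=("bead_id", "count"),
        fwhm_x_mean=("fwhm_x", "mean"), fwhm_x_std=("fwhm_x", "std"),
        fwhm_y_mean=("fwhm_y", "mean"), fwhm_y_std=("fwhm_y", "std"),
        fwhm_z_mean=("fwhm_z", "mean"), fwhm_z_std=("fwhm_z", "std"),
    ).reset_index()
    out = out.fillna({c: 0.0 for c in out.columns if c.endswith("_std")})
    if trend_degree is not None and len(out) > trend_degree:
        for axis in ("x", "y", "z"):
            coef = np.polyfit(out["z_center"], out[f"fwhm_{axis}_mean"],
                              trend_degree)
            out[f"fwhm_{axis}_trend"] = np.polyval(coef, out["z_center"])
    return out


@dataclass
class LightSheetQuant:
    """Light-sheet geometry recovered from bead axial widths."""

    tilt_a: float             # um of Y waist shift per um of Z
    poly_coeffs: np.ndarray   # even polynomial in y' (um), values in nm
    waist_fwhm_z: float       # nm, minimum of the fitted polynomial
    waist_y: float            # um, y' of the minimum
    fov_length: float         # um, width at 2x the minimum


def _fit_even_poly(y, w, degree):
    """Least-squares fit of w(y) with an even polynomial about ``y_c``;
    returns full polynomial coefficients (np.polyval order)."""
    # even design: 1, (y)^2, (y)^4, ...
    powers = list(range(0, degree + 1, 2))
    a = np.vstack([np.asarray(y) ** p for p in powers]).T
    coef, *_ = np.linalg.lstsq(a, np.asarray(w), rcond=None)
    full = np.zeros(degree + 1)
    for c, p in zip(coef, powers):
        full[degree - p] = c
    return full


def quantify_lightsheet(measurements: pd.DataFrame, degree: int = 6,
                        tilt_a: float | None = None) -> LightSheetQuant:
    """Waist thickness and usable FOV of the light sheet from bead widths.

    ``measurements`` needs columns ``y_um``, ``z_um`` and ``fwhm_z`` (nm).
    The waist line tilt ``a`` is estimated by locating, per Z slab, the Y of
    minimum axial width (vertex of a local parabola) and regressing it on Z;
    Y coordinates are then corrected to ``y' = y - a*z``, FWHM_z(y') is fit
    with an even polynomial of the given degree, and the waist (polynomial
    minimum) and FOV (width at twice the minimum) are extracted.
    """
    df = measurements.dropna(subset=["y_um", "z_um", "fwhm_z"])
    if len(df) < degree + 2:
        raise ValueError("too few beads to constrain the polynomial fit")

    if tilt_a is None:
        tilt_a = _estimate_tilt(df)
    y_center = _waist_center(df, tilt_a)
    yp = df["y_um"].to_numpy() - tilt_a * df["z_um"].to_numpy() - y_center
    w = df["fwhm_z"].to_numpy()

    coeffs = _fit_even_poly(yp, w, degree)
    # minimum of the fitted polynomial within the sampled range
    yy = np.linspace(yp.min(), yp.max(), 2001)
    vals = np.polyval(coeffs, yy)
    imin = int(np.argmin(vals))
    if imin in (0, len(yy) - 1):
        raise ValueError("polynomial minimum outside the sampled y' range")
    waist = float(vals[imin])
    waist_y = float(yy[imin])

    fov = _doubling_width(coeffs, waist, waist_y, yp)
    return LightSheetQuant(tilt_a=float(tilt_a), poly_coeffs=coeffs,
                           waist_fwhm_z=waist, waist_y=waist_y,
                           fov_length=fov)


def _estimate_tilt(df: pd.DataFrame) -> float:
    """Slope of the waist Y position vs Z (least squares over Z slabs)."""
    zs = df["z_um"].to_numpy()
    edges = np.linspace(zs.min(), zs.max() + 1e-9, 6)
    centers_z, centers_y = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sub = df[(zs >= lo) & (zs < hi)]
        if len(sub) < 3:
            continue
        # vertex of a parabola through (y, fwhm_z): waist y of this slab
        c = np.polyfit(sub["y_um"], sub["fwhm_z"], 2)
        if c[0] <= 0:
            continue
        centers_y.append(-c[1] / (2 * c[0]))
        centers_z.append(sub["z_um"].mean())
    if len(centers_z) < 2:
        return 0.0
    slope = np.polyfit(centers_z, centers_y, 1)[0]
    return float(slope)


def _waist_center(df: pd.DataFrame, tilt_a: float) -> float:
    yp = df["y_um"].to_numpy() - tilt_a * df["z_um"].to_numpy()
    c = np.polyfit(yp, df["fwhm_z"].to_numpy(), 2)
    if c[0] > 0:
        v = -c[1] / (2 * c[0])
        if yp.min() <= v <= yp.max():
            return float(v)
    return float(yp[np.argmin(df["fwhm_z"].to_numpy())])


def _doubling_width(coeffs, waist, waist_y, yp) -> float:
    """Width of the region where the fitted width stays below 2x the waist."""
    target = 2.0 * waist
    poly = np.polynomial.Polynomial(coeffs[::-1]) - target
    roots = poly.roots()
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    left = real[real < waist_y]
    right = real[real > waist_y]
    if len(left) == 0 or len(right) == 0:
        raise ValueError("doubling point outside the fitted polynomial range")
    return float(right.min() - left.max())
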