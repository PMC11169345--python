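"""Magnification calibration from parallel-line target images.

The lateral magnification of the remote-focusing path varies slightly with
the axial scan position, so a brightfield target of parallel lines (10 um
period) is imaged at each galvo position.  Relative magnification between
positions comes from the isotropic zoom of the best-fit similarity map to a
reference image; the absolute anchor comes from the mean peak spacing of the
smoothed line profile (pixel size at the sample = spacing / peak distance,
magnification = camera pixel / sample pixel size).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks

from .registration import scaled_crosscorr

__all__ = [
    "relative_zoom",
    "absolute_magnification",
    "magnification_curve",
]

CROP_SIZE = 700  # central crop applied before zoom estimation (px)


def _center_crop(img, size):
    ny, nx = img.shape
    size = min(size, ny, nx)
    y0, x0 = (ny - size) // 2, (nx - size) // 2
    return img[y0:y0 + size, x0:x0 + size]


def _zoom_about_center(img, s):
    """Resample so features scaled by s about the image center map back to
    the reference scale (content shrinks for s > 1)."""
    center = (np.array(img.shape) - 1) / 2
    offset = center - s * center
    return ndimage.affine_transform(img, np.diag([s, s]), offset=offset,
                                    order=1, mode="nearest")


def _match_score(img, ref):
    """Peak scaled cross-correlation, translation-invariant."""
    inner = [slice(n // 8, -n // 8 or None) for n in img.shape]
    surface = scaled_crosscorr(ref[tuple(inner)], img[tuple(inner)])
    return float(surface.values.max())


def relative_zoom(image, reference, bounds=(0.9, 1.1),
                  min_correlation: float = 0.2) -> float:
    """Isotropic zoom of the best-fit similarity map image -> reference.

    A zoom factor > 1 means the image's features are larger than the
    reference's (higher magnification).  The factor maximizes the
    translation-invariant scaled cross-correlation after resampling the
    image about its center; registration failure (peak correlation below
    ``min_correlation``) raises.
    """
    img = _center_crop(np.asarray(image, dtype=float), CROP_SIZE)
    ref = _center_crop(np.asarray(reference, dtype=float), CROP_SIZE)
    if img.shape != ref.shape:
        raise ValueError("image and reference crops must match in shape")

    grid = np.linspace(bounds[0], bounds[1], 11)
    scores = [_match_score(_zoom_about_center(img, s), ref) for s in grid]
    i = int(np.argmax(scores))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda s: -_match_score(_zoom_about_center(img, s), ref),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-5})
    if -res.fun < min_correlation:
        raise ValueError("registration failure: correlation below floor")
    return float(res.x)


def absolute_magnification(image, camera_pixel: float,
                           line_spacing: float = 10.0,
                           smooth_window: int = 30,
                           line_axis: int | None = None,
                           prominence_frac: float = 0.1):
    """Absolute magnification from the line-pattern peak spacing.

    The intensity profile is averaged along the line direction (auto-detected
    unless ``line_axis`` gives the axis the lines run along), smoothed with a
    centered running average (``smooth_window`` px, reflected edges), and all
    peaks above 10% prominence of the dynamic range are located with
    parabolic sub-pixel refinement.  With the known ``line_spacing`` (um) and
    mean consecutive-peak distance dd (px), the sample-plane pixel size is
    ``line_spacing / dd`` um and the magnification ``camera_pixel`` (um)
    divided by it.  Returns ``(magnification, pixel_size_at_sample)``.
    """
    img = np.asarray(image, dtype=float)
    if line_axis is None:
        # averaging over the line axis gives the peaky cross-profile;
        # averaging across it gives a flat one
        line_axis = int(np.argmax([img.mean(axis=ax).std()
                                   for ax in (0, 1)]))
    profile = img.mean(axis=line_axis)
    smooth = ndimage.uniform_filter1d(profile, size=smooth_window,
                                      mode="reflect")
    prom = prominence_frac * (smooth.max() - smooth.min())
    peaks, _ = find_peaks(smooth, prominence=prom)
    if len(peaks) < 3:
        raise ValueError("fewer than 3 line peaks found in the profile")
    refined = []
    for p in peaks:
        if 0 < p < len(smooth) - 1:
            a, b, c = smooth[p - 1], smooth[p], smooth[p + 1]
            denom = a - 2 * b + c
            refined.append(p + ((a - c) / (2 * denom) if denom != 0 else 0.0))
        else:
            refined.append(float(p))
    dd = float(np.mean(np.diff(refined)))
    pixel_size = line_spacing / dd
    return camera_pixel / pixel_size, pixel_size


def magnification_curve(images, positions, camera_pixel: float,
                        reference_index: int | None = None,
                        line_spacing: float = 10.0,
                        smooth_window: int = 30) -> pd.DataFrame:
    """Relative and absolute magnification across scan positions.

    ``images`` are the target images at the given scan positions (um);
    ``reference_index`` defaults to the position closest to 0.  The absolute
    magnification is anchored at the reference via the peak-spacing method
    and propagated through the per-image zoom factors.  Per-image failures
    skip the position (logged in the ``status`` column).
    """
    positions = np.asarray(positions, dtype=float)
    if len(images) != len(positions) or len(images) < 2:
        raise ValueError("need >= 2 images with matching positions")
    if reference_index is None:
        reference_index = int(np.argmin(np.abs(positions)))
    reference = images[reference_index]
    mag_ref, _ = absolute_magnification(reference, camera_pixel,
                                        line_spacing=line_spacing,
                                        smooth_window=smooth_window)
    rows = []
    for i, (img, pos) in enumerate(zip(images, positions)):
        if i == reference_index:
            zoom, status = 1.0, "reference"
        else:
            try:
                zoom = relative_zoom(img, reference)
                status = "ok"
            except ValueError as err:
                rows.append(dict(scan_position=pos, relative_zoom=np.nan,
                                 absolute_magnification=np.nan,
                                 pixel_size_at_sample=np.nan,
                                 status=f"skipped: {err}"))
                continue
        mag = mag_ref * zoom
        rows.append(dict(scan_position=pos, relative_zoom=zoom,
                         absolute_magnification=mag,
                         pixel_size_at_sample=camera_pixel / mag,
                         status=status))
    return pd.DataFrame(rows)
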