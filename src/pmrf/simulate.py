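"""Seeded generators for every input the analysis modules consume.

The generators emulate the study conditions of the instrument: 200 nm beads
in agarose imaged through a 3D Gaussian PSF under a light sheet whose waist
translates in Y while Z is scanned; S/P image pairs offset by a known
sub-pixel shift; brightfield parallel-line calibration targets; and
dual-color volumetric movies of granules undergoing Brownian and directed
motion with Poisson photon noise, Gaussian read noise and slow XYZ drift.
Every generator is a pure function of its spec and seed, and each returns
the ground truth needed for closed-loop (generate -> measure) tests.

Default conditions mirror the characterization experiments: 104 nm lateral /
500 nm axial voxel pitch, lateral PSF FWHMs of 570 nm (X) and 666 nm (Y),
924 nm axial width at the sheet center, a sheet waist of 850 nm FWHM with a
Rayleigh-like length of 2.3 um and a Y-per-Z tilt of 0.14, and granule
dynamics of D = 0.41 um^2/s sampled at 8.3 volumes/s for 80 volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import fourier_shift

from .pipeline import TimeSeries5D
from .psf import FWHM_PER_SIGMA, VolumeStack
from .tracking import Trajectory

__all__ = [
    "SimulationSpec",
    "generate_bead_stack",
    "generate_sp_pair",
    "generate_calibration_target",
    "simulate_granules",
    "render_movie",
]


@dataclass
class SimulationSpec:
    """All knobs of the synthetic-data generators, seeded and reproducible."""

    seed: int = 0
    shape: tuple = (41, 128, 128)              # (Z, Y, X) voxels
    pitch: tuple = (0.5, 0.104, 0.104)         # um/voxel
    # PSF widths (z, y, x), nm; the axial value is the width at the sheet
    # center when the light-sheet envelope is disabled
    psf_fwhm_nm: tuple = (924.0, 666.0, 570.0)
    # light-sheet envelope: FWHM_z(y') = W0 * sqrt(1 + (y'/yR)^2)
    lightsheet_waist_nm: float | None = None   # W0; None -> constant sigma_z
    lightsheet_yr_um: float = 2.3              # Rayleigh-like length
    lightsheet_tilt: float = 0.14              # um of Y shift per um of Z
    # noise model: Poisson on expected photons, then Gaussian read noise and
    # a constant camera offset
    photon_scale: float = 2000.0
    read_noise: float = 2.0
    camera_offset: float = 100.0
    noise: bool = True
    # beads
    n_beads: int = 20
    bead_positions_um: np.ndarray | None = None  # (n, 3) as (z, y, x)
    # granules / movies
    n_granules: int = 10
    diffusion_um2_s: float = 0.41
    velocity_um_s: tuple = (0.0, 0.0, 0.0)     # (x, y, z)
    frame_interval_s: float = 1.0 / 8.3
    n_frames: int = 80
    bounds_um: tuple = (15.0, 15.0, 15.0)      # (x, y, z) walk box
    drift_um_per_frame: tuple = (0.0, 0.0, 0.0)  # (z, y, x)
    channel_offset_vox: tuple = (0.0, 0.0, 0.0)  # (z, y, x)
    # fraction of the granule signal also visible in the membrane channel
    # (spectral bleed-through / shared cell structure); without shared
    # structure the inter-channel shift would be unobservable
    channel_crosstalk: float = 0.5


def _rng(spec_or_seed) -> np.random.Generator:
    seed = getattr(spec_or_seed, "seed", spec_or_seed)
    return np.random.default_rng(seed)


def _add_noise(expected, spec, rng):
    if not spec.noise:
        return expected + spec.camera_offset
    counts = rng.poisson(np.clip(expected, 0, None)).astype(float)
    counts += rng.normal(0.0, spec.read_noise, size=expected.shape)
    return counts + spec.camera_offset


def _render_gaussian(volume, center_vox, sigma_vox, amplitude,
                     n_sigma: float = 5.0):
    """Accumulate a 3D Gaussian into ``volume`` at a sub-voxel center."""
    shape = volume.shape
    slices, axes = [], []
    for ax in range(3):
        half = max(3, int(math.ceil(n_sigma * sigma_vox[ax])))
        c = center_vox[ax]
        lo = max(int(math.floor(c)) - half, 0)
        hi = min(int(math.floor(c)) + half + 1, shape[ax])
        if lo >= hi:
            return False
        slices.append(slice(lo, hi))
        g = np.arange(lo, hi, dtype=float)
        axes.append(np.exp(-0.5 * ((g - c) / sigma_vox[ax]) ** 2))
    volume[tuple(slices)] += amplitude * (
        axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :])
    return True


# --------------------------------------------------------------------------
# bead stacks
# --------------------------------------------------------------------------

def generate_bead_stack(spec: SimulationSpec):
    """Bead volume plus ground truth.

    Beads are 3D Gaussians with the spec PSF widths; when the light-sheet
    envelope is enabled the axial width of each bead is set by
    ``W0 * sqrt(1 + (y'/yR)^2)`` with ``y' = y - a*z`` measured from the
    volume center.  Returns ``(VolumeStack, DataFrame)`` with per-bead
    positions (um) and true per-axis FWHMs (nm).  Beads whose center falls
    outside the volume are dropped and noted in the stack metadata.
    """
    rng = _rng(spec)
    nz, ny, nx = spec.shape
    pz, py, px = spec.pitch
    extent = np.array([nz * pz, ny * py, nx * px])

    if spec.bead_positions_um is not None:
        pos = np.asarray(spec.bead_positions_um, dtype=float)
    else:
        margin = 0.12
        pos = rng.uniform(margin, 1 - margin, size=(spec.n_beads, 3)) * extent

    volume = np.zeros(spec.shape, dtype=float)
    rows, dropped = [], 0
    for i, (z_um, y_um, x_um) in enumerate(pos):
        if not (0 <= z_um < extent[0] and 0 <= y_um < extent[1]
                and 0 <= x_um < extent[2]):
            dropped += 1
            continue
        fz, fy, fx = spec.psf_fwhm_nm
        if spec.lightsheet_waist_nm is not None:
            zc = z_um - 0.5 * extent[0]
            yc = y_um - 0.5 * extent[1]
            yp = yc - spec.lightsheet_tilt * zc
            fz = spec.lightsheet_waist_nm * math.sqrt(
                1.0 + (yp / spec.lightsheet_yr_um) ** 2)
        sigma_um = np.array([fz, fy, fx]) * 1e-3 / FWHM_PER_SIGMA
        sigma_vox = sigma_um / np.array([pz, py, px])
        center_vox = np.array([z_um / pz, y_um / py, x_um / px])
        _render_gaussian(volume, center_vox, sigma_vox, spec.photon_scale)
        rows.append(dict(bead_id=i, z_um=z_um, y_um=y_um, x_um=x_um,
                         z_vox=center_vox[0], y_vox=center_vox[1],
                         x_vox=center_vox[2], fwhm_z_nm=fz, fwhm_y_nm=fy,
                         fwhm_x_nm=fx))

    noisy = _add_noise(volume, spec, rng)
    stack = VolumeStack(voxels=noisy, pitch=spec.pitch,
                        metadata=dict(seed=spec.seed, dropped_beads=dropped))
    return stack, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# S/P pairs
# --------------------------------------------------------------------------

def generate_sp_pair(base, offset, intensity_ratio: float = 1.0,
                     noise: float = 0.0, seed: int = 0):
    """S and P copies of a base image, P shifted by a known fractional offset.

    ``offset`` is in pixels, index order, positive meaning P displaced toward
    increasing index relative to S.  P is Fourier-shifted, intensity-scaled
    and (like S) independently Gaussian-noised.  Returns ``(s, p, offset)``.
    """
    img = np.asarray(base, dtype=float)
    offset = tuple(float(o) for o in offset)
    if any(abs(o) >= s / 4 for o, s in zip(offset, img.shape)):
        raise ValueError("offset too large relative to the image extent")
    rng = np.random.default_rng(seed)
    shifted = np.fft.ifftn(fourier_shift(np.fft.fftn(img), offset)).real
    s = img.copy()
    p = intensity_ratio * shifted
    if noise > 0:
        s = s + rng.normal(0, noise, img.shape)
        p = p + rng.normal(0, noise, img.shape)
    return s, p, offset


# --------------------------------------------------------------------------
# calibration targets
# --------------------------------------------------------------------------

def generate_calibration_target(line_spacing_um: float = 10.0,
                                pixel_size_um: float = 0.5,
                                shape: tuple = (800, 800),
                                line_fwhm_um: float = 2.0,
                                orientation: int = 0,
                                amplitude: float = 1000.0,
                                offset_px: float = 0.0):
    """Brightfield-like image of parallel Gaussian-profile lines.

    Lines run along rows (orientation 0) or columns (90) at exact sub-pixel
    positions spaced ``line_spacing_um``; returns ``(image, true_dd_px)``
    with the ground-truth peak spacing in pixels.  Raises when fewer than
    three lines fit in the frame.
    """
    if line_spacing_um <= line_fwhm_um:
        raise ValueError("line spacing must exceed the line width")
    ny, nx = shape
    dd_px = line_spacing_um / pixel_size_um
    sigma_px = line_fwhm_um / pixel_size_um / FWHM_PER_SIGMA
    first = dd_px / 2 + offset_px
    centers = np.arange(first, nx - dd_px / 2, dd_px)
    if len(centers) < 3:
        raise ValueError("fewer than 3 lines fit in the frame")
    x = np.arange(nx, dtype=float)
    profile = np.zeros(nx)
    for c in centers:
        profile += np.exp(-0.5 * ((x - c) / sigma_px) ** 2)
    img = amplitude * np.tile(profile, (ny, 1))
    if orientation == 90:
        img = img.T
    elif orientation != 0:
        raise ValueError("orientation must be 0 or 90 degrees")
    return img, float(dd_px)


# --------------------------------------------------------------------------
# granule dynamics and movies
# --------------------------------------------------------------------------

def simulate_granules(spec: SimulationSpec):
    """Ground-truth Brownian (+ optional directed) 3D trajectories.

    Per-axis steps are N(0, sqrt(2*D*dt)) plus v*dt, with reflecting
    boundaries at the walk box so track lengths stay fixed.  Positions are
    (x, y, z) in um.
    """
    rng = _rng(spec)
    dt = spec.frame_interval_s
    step_sigma = math.sqrt(2.0 * spec.diffusion_um2_s * dt)
    v = np.asarray(spec.velocity_um_s, dtype=float)
    bounds = np.asarray(spec.bounds_um, dtype=float)

    tracks = []
    for tid in range(spec.n_granules):
        start = rng.uniform(0.25, 0.75, size=3) * bounds
        steps = rng.normal(0.0, step_sigma, size=(spec.n_frames - 1, 3))
        steps = steps + v * dt
        path = np.empty((spec.n_frames, 3))
        path[0] = start
        for k in range(1, spec.n_frames):
            nxt = path[k - 1] + steps[k - 1]
            # reflecting boundaries
            for ax in range(3):
                if nxt[ax] < 0:
                    nxt[ax] = -nxt[ax]
                elif nxt[ax] > bounds[ax]:
                    nxt[ax] = 2 * bounds[ax] - nxt[ax]
                nxt[ax] = min(max(nxt[ax], 0.0), bounds[ax])
            path[k] = nxt
        t = np.arange(spec.n_frames) * dt
        tracks.append(Trajectory(track_id=tid, t=t, xyz=path))
    return tracks


def _shell_channel(shape, pitch, rng, radius_um=None, thickness_um=0.8,
                   amplitude=500.0):
    """Membrane-like spherical shell used as the second-color structure.

    The radius defaults to 30% of the smallest volume extent so the shell
    stays clear of the boundaries even after drift is applied (a clipped
    shell would bias registration through edge truncation).
    """
    nz, ny, nx = shape
    pz, py, px = pitch
    if radius_um is None:
        radius_um = 0.3 * min(nz * pz, ny * py, nx * px)
    zz, yy, xx = np.meshgrid((np.arange(nz) - nz / 2) * pz,
                             (np.arange(ny) - ny / 2) * py,
                             (np.arange(nx) - nx / 2) * px, indexing="ij")
    r = np.sqrt(zz ** 2 + yy ** 2 + xx ** 2)
    return amplitude * np.exp(-0.5 * ((r - radius_um) / thickness_um) ** 2)


def render_movie(trajectories, spec: SimulationSpec):
    """Dual-color 5D movie of the granule trajectories plus ground truth.

    Channel 0 carries the granules (rendered with the spec PSF each frame);
    channel 1 is a static membrane-like shell.  A global drift accumulates
    per frame and channel 1 is additionally displaced by the configured
    inter-channel offset; noise is applied independently per frame and
    channel.  Returns ``(TimeSeries5D, truth)`` with the rendered positions,
    per-frame drift (voxels) and channel offset in ``truth``.
    """
    rng = _rng(spec)
    nz, ny, nx = spec.shape
    pz, py, px = spec.pitch
    pitch_zyx = np.array([pz, py, px])
    sigma_vox = (np.asarray(spec.psf_fwhm_nm) * 1e-3 / FWHM_PER_SIGMA
                 / pitch_zyx)
    shell = _shell_channel(spec.shape, spec.pitch, rng)
    ch_off = np.asarray(spec.channel_offset_vox, dtype=float)
    drift_rate = np.asarray(spec.drift_um_per_frame, dtype=float)  # (z, y, x)

    n_frames = min(spec.n_frames, max(len(tr) for tr in trajectories))
    frames = np.zeros((n_frames, 2, nz, ny, nx), dtype=float)
    drift_vox = np.zeros((n_frames, 3))
    rendered = []
    for k in range(n_frames):
        drift_um = drift_rate * k
        drift_vox[k] = drift_um / pitch_zyx
        vol = np.zeros((nz, ny, nx), dtype=float)
        count = 0
        for tr in trajectories:
            if k >= len(tr):
                continue
            x, y, z = tr.xyz[k]
            center_um = np.array([z, y, x]) + drift_um
            center_vox = center_um / pitch_zyx
            if _render_gaussian(vol, center_vox, sigma_vox,
                                spec.photon_scale):
                count += 1
                rendered.append(dict(frame=k, track_id=tr.track_id,
                                     z_vox=center_vox[0], y_vox=center_vox[1],
                                     x_vox=center_vox[2]))
        frames[k, 0] = _add_noise(vol, spec, rng)
        # vol already carries the drift (applied to granule positions);
        # channel 1 gets the extra inter-channel offset on top
        ch1 = (_fractional_shift(shell, drift_vox[k] + ch_off)
               + spec.channel_crosstalk * _fractional_shift(vol, ch_off))
        frames[k, 1] = _add_noise(ch1, spec, rng)

    series = TimeSeries5D(data=frames, pitch=spec.pitch,
                          frame_interval_s=spec.frame_interval_s,
                          metadata=dict(seed=spec.seed))
    truth = dict(drift_vox=drift_vox, channel_offset_vox=ch_off,
                 positions=pd.DataFrame(rendered))
    return series, truth


def _fractional_shift(volume, shift):
    from scipy.ndimage import shift as nd_shift
    return nd_shift(volume, shift, order=1, mode="constant", cval=0.0,
                    prefilter=False)
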