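"""Bead FWHM measurement, detection, summaries and light-sheet geometry."""

import math

import numpy as np
import pandas as pd
import pytest

from pmrf.psf import (
    FWHM_PER_SIGMA,
    FWHMMeasurement,
    VolumeStack,
    crop_lightsheet_region,
    detect_beads,
    gaussian_psf_model,
    measure_bead_fwhm,
    measure_fwhm,
    mip_slab,
    quantify_lightsheet,
    summarize_resolution,
)
from pmrf.simulate import SimulationSpec, generate_bead_stack


def sampled_gaussian(sigma_px, n=41, center=None, amp=1000.0, baseline=0.0):
    x = np.arange(n, dtype=float)
    c = n // 2 if center is None else center
    return amp * np.exp(-0.5 * ((x - c) / sigma_px) ** 2) + baseline


class TestMeasureFWHM:
    def test_closed_form_sigma_two(self):
        # FWHM = 2 sqrt(2 ln 2) sigma = 4.7096 px = 489.8 nm at 104 nm pitch
        fwhm, _ = measure_fwhm(sampled_gaussian(2.0), pitch=0.104)
        assert fwhm == pytest.approx(2 * math.sqrt(2 * math.log(2)) * 2
                                     * 104, rel=1e-6)

    def test_baseline_invariance(self):
        f0, _ = measure_fwhm(sampled_gaussian(2.0), pitch=0.104)
        f1, _ = measure_fwhm(sampled_gaussian(2.0, baseline=100.0),
                             pitch=0.104)
        assert f1 == pytest.approx(f0, rel=1e-6)

    @pytest.mark.parametrize("sigma", [1.5, 2.5, 4.0, 6.0])
    def test_exact_on_noiseless_gaussians(self, sigma):
        fwhm, resid = measure_fwhm(sampled_gaussian(sigma, n=81), pitch=0.5)
        assert fwhm == pytest.approx(FWHM_PER_SIGMA * sigma * 500, rel=1e-6)
        assert resid < 1e-3

    def test_poisson_noise_mean_recovery(self, rng):
        # peak 1000 counts; the mean over 100 repeats lands within 2%
        truth = FWHM_PER_SIGMA * 2.0 * 104
        est = []
        for _ in range(100):
            noisy = rng.poisson(sampled_gaussian(2.0, amp=1000.0) + 10.0)
            f, _ = measure_fwhm(noisy.astype(float), pitch=0.104)
            est.append(f)
        assert np.mean(est) == pytest.approx(truth, rel=0.02)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            measure_fwhm(np.ones(5), pitch=0.1)


class TestMipSlab:
    def test_identical_slices_equal_one_slice(self, rng):
        slc = rng.random((16, 16))
        stack = VolumeStack(np.repeat(slc[None], 12, axis=0),
                            pitch=(0.5, 0.1, 0.1))
        assert np.array_equal(mip_slab(stack, axis=0, n_slices=10), slc)

    def test_mip_dominates_every_slice(self, rng):
        stack = VolumeStack(rng.random((12, 8, 8)), pitch=(0.5, 0.1, 0.1))
        mip = mip_slab(stack, axis=0, n_slices=10)
        lo = 12 // 2 - 5
        for z in range(lo, lo + 10):
            assert np.all(mip >= stack.voxels[z])

    def test_single_bright_voxel_appears(self):
        vox = np.zeros((12, 9, 9))
        vox[7, 3, 5] = 7.0
        stack = VolumeStack(vox, pitch=(0.5, 0.1, 0.1))
        assert mip_slab(stack, axis=0, n_slices=10)[3, 5] == 7.0

    def test_out_of_bounds_slab_clipped(self):
        stack = VolumeStack(np.ones((4, 5, 5)), pitch=(0.5, 0.1, 0.1))
        assert mip_slab(stack, axis=0, center=0, n_slices=10).shape == (5, 5)


class TestCropLightsheet:
    def make_stack(self, nz=11, ny=64, nx=16):
        return VolumeStack(np.zeros((nz, ny, nx)), pitch=(0.5, 0.104, 0.104))

    def test_zero_tilt_same_window_every_slice(self):
        stack = self.make_stack()
        stack.voxels[:, 30, :] = 5.0
        cropped, clipped = crop_lightsheet_region(stack, fov_length=2.0,
                                                  tilt_a=0.0)
        rows = [np.argmax(cropped.voxels[z, :, 0]) for z in range(11)]
        assert len(set(rows)) == 1
        assert not clipped.any()

    def test_window_shift_follows_waist_arithmetic(self):
        # a = 0.14 um/um with 0.5 um steps: 0.07 um per slice, i.e. about
        # 0.67 voxel per slice -- accumulated exactly via the carried
        # remainder: total shift over 10 slices = 1.4 um/0.104 = 13.5 vox
        stack = self.make_stack()
        fov = 2.0
        _, _ = crop_lightsheet_region(stack, fov, tilt_a=0.14)
        # track centers via a bright line on the waist
        for iz in range(11):
            z_um = (iz - 5) * 0.5
            y = int(round((0.5 * 64 * 0.104 + 0.14 * z_um) / 0.104))
            stack.voxels[iz, y, :] = 9.0
        cropped, _ = crop_lightsheet_region(stack, fov, tilt_a=0.14)
        centers = [np.argmax(cropped.voxels[z, :, 0]) for z in range(11)]
        assert max(centers) - min(centers) <= 1  # line stays centered

    def test_tilted_signal_inside_crop_brighter(self, rng):
        stack = self.make_stack()
        stack.voxels[:] = rng.random(stack.voxels.shape)
        for iz in range(11):
            z_um = (iz - 5) * 0.5
            y = int(round((0.5 * 64 * 0.104 + 0.14 * z_um) / 0.104))
            stack.voxels[iz, y - 2:y + 3, :] += 10.0
        cropped, _ = crop_lightsheet_region(stack, 1.0, tilt_a=0.14)
        for iz in range(11):
            assert (cropped.voxels[iz].mean()
                    > stack.voxels[iz].mean())

    def test_fov_exceeding_extent_rejected(self):
        with pytest.raises(ValueError):
            crop_lightsheet_region(self.make_stack(), fov_length=100.0,
                                   tilt_a=0.0)

    def test_waist_line_outside_frame_rejected(self):
        stack = self.make_stack()
        with pytest.raises(ValueError, match="exits the frame"):
            crop_lightsheet_region(stack, 1.0, tilt_a=0.0, y0=500.0)


class TestDetectBeads:
    pitch = (0.5, 0.104, 0.104)

    def bead_field(self, positions, seed=0, noise=False):
        spec = SimulationSpec(seed=seed, shape=(21, 128, 128),
                              pitch=self.pitch,
                              bead_positions_um=np.asarray(positions),
                              noise=noise)
        return generate_bead_stack(spec)

    def test_separated_beads_all_found(self):
        pos = [[5, 3, 3], [5, 3, 10], [5.5, 10, 3], [5, 10, 10], [5, 6.5, 6.5]]
        stack, truth = self.bead_field(pos)
        psf = gaussian_psf_model((924, 666, 570), self.pitch)
        det = detect_beads(stack, psf, min_separation=1.5)
        assert len(det) == 5
        for _, t in truth.iterrows():
            d = np.hypot(det.y_um - t.y_um, det.x_um - t.x_um)
            assert d.min() < 0.104  # within one voxel laterally

    def test_close_pair_both_rejected(self):
        # the pair sits at half the separation floor: both members are
        # rejected, the two isolated beads remain
        pos = [[5, 3, 3], [5, 3, 10], [5, 9.2, 6], [5, 10.7, 6]]
        stack, _ = self.bead_field(pos)
        psf = gaussian_psf_model((924, 666, 570), self.pitch)
        det = detect_beads(stack, psf, min_separation=3.0)
        assert len(det) == 2
        assert np.all(det.y_um < 5)

    def test_noise_only_stack_yields_nothing(self, rng):
        stack = VolumeStack(rng.normal(100, 2, (21, 64, 64)),
                            pitch=self.pitch)
        psf = gaussian_psf_model((924, 666, 570), self.pitch)
        det = detect_beads(stack, psf, corr_threshold=0.8)
        assert len(det) == 0

    def test_precision_and_recall_on_noiseless_field(self):
        pos = [[5, y, x] for y in (3, 6.4, 9.8) for x in (3, 6.4, 9.8)]
        stack, truth = self.bead_field(pos)
        psf = gaussian_psf_model((924, 666, 570), self.pitch)
        det = detect_beads(stack, psf, min_separation=1.5)
        assert len(det) == len(truth)  # recall 1
        for _, d in det.iterrows():  # precision 1
            dist = np.hypot(truth.y_um - d.y_um, truth.x_um - d.x_um)
            assert dist.min() < 0.104

    def test_pitch_mismatch_rejected(self):
        stack = VolumeStack(np.zeros((9, 32, 32)), pitch=self.pitch)
        psf = gaussian_psf_model((924, 666, 570), (0.5, 0.2, 0.2))
        with pytest.raises(ValueError, match="pitch"):
            detect_beads(stack, psf)


class TestSummarizeResolution:
    def make_measurements(self, fwhms, zs):
        return [FWHMMeasurement(bead_id=i, position_um=(z, 5.0, 5.0),
                                fwhm_x=f, fwhm_y=f + 50, fwhm_z=f + 300,
                                fit_quality=0.1)
                for i, (f, z) in enumerate(zip(fwhms, zs))]

    def test_identical_beads_zero_std(self):
        ms = self.make_measurements([570] * 8, [2.0] * 8)
        out = summarize_resolution(ms)
        assert len(out) == 1
        assert out.fwhm_x_mean[0] == 570 and out.fwhm_x_std[0] == 0

    def test_partition_into_segments(self):
        zs = [1, 4, 6, 9, 11, 14, 22]
        ms = self.make_measurements([500] * len(zs), zs)
        out = summarize_resolution(ms, segment_height=5.0)
        assert out.n.sum() == len(zs)
        assert sorted(out.segment) == [0, 1, 2, 4]  # empty segment omitted

    def test_permutation_invariance(self, rng):
        fwhms = rng.uniform(500, 700, 12)
        zs = rng.uniform(0, 20, 12)
        ms = self.make_measurements(fwhms, zs)
        out1 = summarize_resolution(ms)
        perm = [ms[i] for i in rng.permutation(12)]
        out2 = summarize_resolution(perm)
        pd.testing.assert_frame_equal(out1, out2)

    def test_simulated_recovery_within_one_std(self):
        from pmrf.workflows import bead_resolution_protocol
        df = bead_resolution_protocol(seed=3, n_beads=20)
        assert len(df) == 20
        assert abs(df.fwhm_x.mean() - 570) < 26
        assert abs(df.fwhm_y.mean() - 666) < 44

    def test_invalid_measurements_excluded(self):
        ms = self.make_measurements([570, 600], [1, 2])
        ms[1].valid = False
        out = summarize_resolution(ms)
        assert out.n.sum() == 1


class TestQuantifyLightsheet:
    @staticmethod
    def beam_samples(w0=850.0, yr=2.3, tilt=0.0, n=80, span=2.5, rng=None):
        y = np.linspace(-span * yr, span * yr, n)
        z = (np.zeros(n) if rng is None
             else rng.uniform(-10, 10, n))
        w = w0 * np.sqrt(1 + (y / yr) ** 2)
        return pd.DataFrame(dict(y_um=y + tilt * z, z_um=z, fwhm_z=w))

    def test_exact_beam_waist_and_fov(self):
        df = self.beam_samples()
        q = quantify_lightsheet(df)
        assert q.waist_fwhm_z == pytest.approx(850, rel=0.02)
        assert q.fov_length == pytest.approx(2 * math.sqrt(3) * 2.3,
                                             rel=0.02)

    def test_zero_tilt_data_gives_zero_tilt(self, rng):
        df = self.beam_samples(rng=rng)
        q = quantify_lightsheet(df)
        assert abs(q.tilt_a) < 0.02

    def test_tilt_recovered(self, rng):
        df = self.beam_samples(tilt=0.14, rng=rng)
        q = quantify_lightsheet(df)
        assert q.tilt_a == pytest.approx(0.14, abs=0.02)
        assert q.waist_fwhm_z == pytest.approx(850, rel=0.03)

    def test_noisy_repeats_waist_within_five_percent(self, rng):
        # 5% multiplicative noise, 100 repeats
        waists = []
        for _ in range(100):
            df = self.beam_samples(rng=rng)
            df["fwhm_z"] *= 1 + 0.05 * rng.normal(size=len(df))
            waists.append(quantify_lightsheet(df).waist_fwhm_z)
        assert np.mean(waists) == pytest.approx(850, rel=0.05)

    def test_minimum_outside_range_rejected(self):
        df = self.beam_samples()
        df = df[df.y_um > 1.0]  # one-sided sampling, minimum at the border
        with pytest.raises(ValueError):
            quantify_lightsheet(df, tilt_a=0.0)
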