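import numpy as np
import pytest
from hypothesis import given, strategies as st

from sampam.analytics import (contrast_ratio, count_local_maxima, cscan_map,
                              extract_bscan, noise_threshold,
                              occupancy_fraction, volume_histogram)
from sampam.phantom import PhantomConfig, generate_phantom, simulate_pam
from sampam.preprocess import (EnvelopeVolume, TimeWindow,
                               align_and_coregister, hilbert_envelope)

from conftest import make_layers


def env_volume(data, axis=None):
    data = np.asarray(data, dtype=float)
    if axis is None:
        axis = np.arange(data.shape[2], dtype=float)
    return EnvelopeVolume(data=data, depth_axis=axis, pixel_pitch=1e-5,
                          modality="PAM")


FULL = TimeWindow(0.0, 1e9)


class TestCScan:
    def test_constant_volume_constant_cscan(self):
        scan = cscan_map(env_volume(np.full((3, 4, 10), 2.5)), FULL)
        assert np.allclose(scan.data, 2.5)

    def test_single_bright_voxel(self):
        data = np.zeros((4, 4, 20))
        data[1, 2, 7] = 9.0
        scan = cscan_map(env_volume(data), FULL)
        expected = np.zeros((4, 4))
        expected[1, 2] = 9.0
        assert np.array_equal(scan.data, expected)

    def test_map_monotone_in_window(self):
        rng = np.random.default_rng(0)
        env = env_volume(rng.random((5, 5, 40)))
        small = cscan_map(env, TimeWindow(10.0, 20.0)).data
        large = cscan_map(env, TimeWindow(5.0, 30.0)).data
        assert np.all(large >= small)

    def test_empty_window_error(self):
        with pytest.raises(ValueError):
            cscan_map(env_volume(np.ones((2, 2, 5))), TimeWindow(100.0, 200.0))

    def test_phantom_blob_count_matches_ground_truth(self, transducer):
        """Well-separated pigment cells appear as one C-scan maximum each."""
        cfg = PhantomConfig(grid_nx=60, grid_ny=60,
                            layers=make_layers(skin_absorption=0.0),
                            pigment_count=9, scale_count=0, noise_std=0.0,
                            pigment_diameter_range=(20e-6, 60e-6),
                            skin_layer="skin", petridish_echo=False, seed=11)
        ph = generate_phantom(cfg)
        # pin the cells to a separated 3x3 lattice (spacing >> diameter+PSF)
        top, bottom = ph.skin_bounds()
        for k, cell in enumerate(ph.pigment_cells):
            cell.position[:] = ((1 + k % 3) * 150e-6, (1 + k // 3) * 150e-6,
                                top + 100e-6 + 50e-6 * (k % 4))
        env = hilbert_envelope(simulate_pam(ph, transducer))
        scan = cscan_map(env, FULL)
        # brute-force check that the ground truth really is unambiguous
        pos = np.array([c.position[:2] for c in ph.pigment_cells])
        sep = min(np.linalg.norm(a - b) for i, a in enumerate(pos)
                  for b in pos[i + 1:])
        assert sep > 100e-6
        assert count_local_maxima(scan, rel_threshold=0.5) == 9


class TestBScan:
    def test_slice_of_constant_volume(self):
        scan = extract_bscan(env_volume(np.full((3, 5, 8), 1.5)), 2)
        assert np.allclose(scan.data, 1.5)
        assert scan.data.shape == (3, 8)

    def test_exact_slice_and_reinsert(self):
        rng = np.random.default_rng(4)
        data = rng.random((4, 6, 12))
        env = env_volume(data)
        scan = extract_bscan(env, 3)
        assert np.array_equal(scan.data, data[:, 3, :])
        restored = data.copy()
        restored[:, 3, :] = scan.data
        assert np.array_equal(restored, data)

    def test_two_interface_bands_at_ground_truth_depths(self, transducer,
                                                        slab_phantom):
        from sampam.phantom import simulate_sam
        env = hilbert_envelope(simulate_sam(slab_phantom, transducer))
        scan = extract_bscan(env, 0)
        truth = slab_phantom.interface_depths(0, 0)
        for depth, _ in truth:
            t_two_way = 2.0 * slab_phantom.one_way_time(np.array(depth))
            idx = int(round(float(t_two_way) * transducer.sampling_rate))
            band = scan.data[0, max(idx - 2, 0):idx + 3]
            assert band.max() > 0.5 * scan.data[0].max() * 0.2

    def test_out_of_range_line_error(self):
        with pytest.raises(IndexError):
            extract_bscan(env_volume(np.ones((2, 3, 4))), 3)


class TestVolumeHistogram:
    def test_constant_volume_single_bin(self):
        hist = volume_histogram(env_volume(np.full((2, 2, 10), 7.0)))
        assert hist.counts.sum() == 40
        assert np.count_nonzero(hist.counts) == 1

    @given(seed=st.integers(0, 10_000))
    def test_counts_conserve_voxel_total(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(1, 8, size=3))
        env = env_volume(rng.random(shape))
        hist = volume_histogram(env)
        assert hist.counts.sum() == np.prod(shape)
        assert len(hist.bin_edges) == 257
        assert hist.bin_edges[0] == 0 and hist.bin_edges[-1] == 256

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        data = rng.random((3, 3, 20))
        h1 = volume_histogram(env_volume(data))
        h2 = volume_histogram(env_volume(data * 37.5))
        assert np.array_equal(h1.counts, h2.counts)

    def test_bimodal_mixture_two_modes(self):
        """Many weak voxels plus few strong ones give a bimodal histogram."""
        rng = np.random.default_rng(12)
        weak = rng.normal(20, 3, size=9000)
        strong = rng.normal(200, 5, size=1000)
        data = np.clip(np.concatenate([weak, strong]), 0, None)
        hist = volume_histogram(env_volume(data.reshape(10, 10, 100)),
                                fixed_max=255.0)
        counts = hist.counts.astype(float)
        # brute-force mode scan on the smoothed histogram
        smooth = np.convolve(counts, np.ones(5) / 5, mode="same")
        modes = [i for i in range(1, 255)
                 if smooth[i] > smooth[i - 1] and smooth[i] >= smooth[i + 1]
                 and smooth[i] > 5]
        assert len(modes) == 2
        assert counts[modes[0]] > counts[modes[1]]  # larger low-value peak

    def test_all_zero_volume_mass_in_bin_zero(self):
        hist = volume_histogram(env_volume(np.zeros((2, 2, 5))))
        assert hist.counts[0] == 20 and hist.counts[1:].sum() == 0


class TestOccupancy:
    def test_threshold_above_max_gives_zero(self):
        env = env_volume(np.random.default_rng(1).random((3, 3, 10)))
        assert occupancy_fraction(env, 2.0) == 0.0

    def test_constructed_fixture_22_of_10000(self):
        data = np.zeros(10_000)
        data[:22] = 5.0
        env = env_volume(data.reshape(10, 10, 100))
        assert occupancy_fraction(env, 1.0) == pytest.approx(0.22)

    def test_constructed_fixture_69_of_100000(self):
        data = np.zeros(100_000)
        data[:69] = 5.0
        env = env_volume(data.reshape(10, 10, 1000))
        assert occupancy_fraction(env, 1.0) == pytest.approx(0.069)

    def test_nonincreasing_in_threshold(self):
        env = env_volume(np.random.default_rng(2).random((4, 4, 25)))
        values = [occupancy_fraction(env, t) for t in np.linspace(0, 1.1, 23)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_noise_threshold_mean_plus_k_std(self):
        rng = np.random.default_rng(5)
        data = rng.random((2, 2, 50))
        env = env_volume(data)
        thr = noise_threshold(env, TimeWindow(0.0, 9.0), k=3.0)
        region = data[:, :, :10]
        assert thr == pytest.approx(region.mean() + 3 * region.std())


class TestContrastRatio:
    @staticmethod
    def scan_with(fg_value, bg_value):
        data = np.full((6, 6), bg_value, dtype=float)
        data[2:4, 2:4] = fg_value
        fg = np.zeros((6, 6), bool)
        fg[2:4, 2:4] = True
        from sampam.analytics import CScan
        return CScan(data=data, pixel_pitch=1e-5, source_window=FULL), fg, ~fg

    def test_identical_means_unity(self):
        scan, fg, bg = self.scan_with(3.0, 3.0)
        assert contrast_ratio(scan, fg, bg) == pytest.approx(1.0)

    def test_swapping_masks_inverts(self):
        scan, fg, bg = self.scan_with(8.0, 2.0)
        r = contrast_ratio(scan, fg, bg)
        assert contrast_ratio(scan, bg, fg) == pytest.approx(1.0 / r)

    def test_scale_invariant(self):
        scan, fg, bg = self.scan_with(14.0, 1.0)
        r1 = contrast_ratio(scan, fg, bg)
        scan.data *= 123.0
        assert contrast_ratio(scan, fg, bg) == pytest.approx(r1)

    def test_zero_background_flagged_infinite(self):
        scan, fg, bg = self.scan_with(5.0, 0.0)
        assert contrast_ratio(scan, fg, bg) == np.inf

    def test_overlapping_or_empty_masks_rejected(self):
        scan, fg, bg = self.scan_with(5.0, 1.0)
        with pytest.raises(ValueError, match="disjoint"):
            contrast_ratio(scan, fg, fg)
        with pytest.raises(ValueError, match="nonempty"):
            contrast_ratio(scan, np.zeros_like(fg), bg)

    def test_phantom_fourteen_to_one_recovery(self, transducer):
        """Cells 14x brighter than the skin haze give a ~14:1 C-scan ratio."""
        cfg = PhantomConfig(grid_nx=48, grid_ny=48,
                            layers=make_layers(skin_absorption=1.0 / 14.0),
                            pigment_count=10, scale_count=0,
                            pigment_diameter_range=(40e-6, 80e-6),
                            skin_layer="skin", petridish_echo=False, seed=21)
        ph = generate_phantom(cfg)
        env = hilbert_envelope(simulate_pam(ph, transducer))
        scan = cscan_map(env, FULL)
        fg = np.zeros(scan.data.shape, bool)
        near = np.zeros(scan.data.shape, bool)
        gx, gy = np.meshgrid(np.arange(48), np.arange(48), indexing="ij")
        for cell in ph.pigment_cells:
            cx = cell.position[0] / cfg.pixel_pitch
            cy = cell.position[1] / cfg.pixel_pitch
            d2 = (gx - cx) ** 2 + (gy - cy) ** 2
            fg |= d2 <= 1.0
            near |= d2 <= (cell.diameter / 2 / cfg.pixel_pitch + 4) ** 2
        bg = ~near
        assert fg.any() and bg.any()
        ratio = contrast_ratio(scan, fg, bg)
        assert ratio == pytest.approx(14.0, rel=0.1)
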