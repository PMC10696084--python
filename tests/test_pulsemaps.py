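"""Phase maps, arteriovenous delays, amplitude maps, signal contrast."""

import numpy as np
import pytest

import freewave as fw
from freewave.errors import ConfigurationError, MaskError, RoiError
from freewave.gating import CycleStats
from freewave.pulsemaps import RoiSet
from freewave.recon import PhaseResolvedSeries


def synthetic_series(n_phases=15, shape=(24, 24), peaks=None, base=1.0):
    """Phase series where region masks peak at given phases.

    ``peaks``: list of (mask, peak_phase, amplitude); everything else flat.
    """
    images = np.full((n_phases,) + shape, base)
    if peaks:
        for mask, peak, amp in peaks:
            for p in range(n_phases):
                d = min((p - peak) % n_phases, (peak - p) % n_phases)
                images[p][mask] += amp * max(0.0, 1.0 - d / 2.0)
    return PhaseResolvedSeries(images, shape)


@pytest.fixture
def stats_1s():
    return CycleStats(np.array([0.0, 1000.0]))


class TestBrainMask:
    def test_exact_on_noiseless_phantom(self, small_truth):
        mask = fw.brain_mask(small_truth.baseline_image())
        assert np.array_equal(mask, small_truth.brain_mask)

    def test_all_zero_errors(self):
        with pytest.raises(MaskError):
            fw.brain_mask(np.zeros((32, 32)))

    def test_noisy_phantom_dice_above_098(self, small_truth):
        rng = np.random.default_rng(0)
        img = small_truth.baseline_image()
        noisy = np.abs(img + rng.normal(0, img[small_truth.brain_mask].mean() / 20, img.shape))
        mask = fw.brain_mask(noisy)
        truth = small_truth.brain_mask
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice > 0.98


class TestPhaseMap:
    def test_homogeneous_waveform_gives_zero_delta(self):
        mask = np.ones((24, 24), dtype=bool)
        series = synthetic_series(peaks=[(mask, 5, 0.1)])
        pmap = fw.phase_map(series, mask)
        assert pmap.global_max_phase == 5
        assert np.all(pmap.phase_delta[mask] == 0)
        assert not pmap.is_flat

    def test_late_and_early_voxels_wrap(self):
        mask = np.ones((24, 24), dtype=bool)
        late = np.zeros_like(mask); late[0, 0] = True
        early = np.zeros_like(mask); early[0, 1] = True
        bulk = mask & ~late & ~early
        series = synthetic_series(
            peaks=[(bulk, 5, 0.1), (late, 6, 0.1), (early, 4, 0.1)]
        )
        pmap = fw.phase_map(series, mask)
        assert pmap.phase_delta[0, 0] == 1  # one phase after the brain peak
        assert pmap.phase_delta[0, 1] == 14  # one before: wraps to n-1
        assert np.all(pmap.phase_delta[bulk] == 0)

    def test_flat_series_flagged(self):
        mask = np.ones((16, 16), dtype=bool)
        series = synthetic_series(shape=(16, 16), peaks=None)
        pmap = fw.phase_map(series, mask)
        assert pmap.is_flat

    def test_shift_equivariance(self, small_gated):
        series, mask = small_gated["filtered"], small_gated["mask"]
        pmap = fw.phase_map(series, mask)
        shifted = PhaseResolvedSeries(
            np.roll(series.images, 4, axis=0), series.original_matrix, series.cycle_stats
        )
        pmap2 = fw.phase_map(shifted, mask)
        assert pmap2.global_max_phase == (pmap.global_max_phase + 4) % 15
        assert np.array_equal(pmap.phase_delta, pmap2.phase_delta)

    def test_scale_invariance(self, small_gated):
        series, mask = small_gated["filtered"], small_gated["mask"]
        scaled = PhaseResolvedSeries(
            series.images * 7.3, series.original_matrix, series.cycle_stats
        )
        assert np.array_equal(
            fw.phase_map(series, mask).phase_delta,
            fw.phase_map(scaled, mask).phase_delta,
        )


class TestArteriovenousDelays:
    def _rois(self, shape, terr_mask, sss_mask):
        masks = {t: terr_mask for t in fw.pulsemaps.TERRITORIES}
        masks["sinus"] = sss_mask
        masks["brain"] = np.ones(shape, dtype=bool)
        return RoiSet(masks)

    def test_known_phase_offsets(self, stats_1s):
        shape = (24, 24)
        terr = np.zeros(shape, dtype=bool); terr[2, 2] = True
        sss = np.zeros(shape, dtype=bool); sss[20, 20] = True
        bulk = ~(terr | sss)
        series = synthetic_series(
            shape=shape, peaks=[(bulk, 4, 0.05), (terr, 6, 0.3), (sss, 12, 0.3)]
        )
        mask = np.ones(shape, dtype=bool)
        pmap = fw.phase_map(series, mask)
        table = fw.arteriovenous_delays(pmap, self._rois(shape, terr, sss), stats_1s)
        assert np.all(table.delay_phases == 6)
        assert table.delay_ms.iloc[0] == pytest.approx(6 * 1000 / 15)

    def test_identical_phases_give_zero_delay(self, stats_1s):
        shape = (24, 24)
        terr = np.zeros(shape, dtype=bool); terr[2, 2] = True
        sss = np.zeros(shape, dtype=bool); sss[20, 20] = True
        series = synthetic_series(
            shape=shape, peaks=[(terr, 6, 0.3), (sss, 6, 0.3)]
        )
        pmap = fw.phase_map(series, np.ones(shape, dtype=bool))
        table = fw.arteriovenous_delays(pmap, self._rois(shape, terr, sss), stats_1s)
        assert np.all(table.delay_phases == 0)

    def test_voxel_min_uses_wrap_correction(self, stats_1s):
        # a territory voxel peaking 1 phase *before* the brain peak must not
        # be read as a 14-phase delay
        shape = (24, 24)
        terr = np.zeros(shape, dtype=bool); terr[2, 2:4] = True
        sss = np.zeros(shape, dtype=bool); sss[20, 20] = True
        bulk = ~(terr | sss)
        series = synthetic_series(
            shape=shape, peaks=[(bulk, 4, 0.05), (terr, 3, 0.3), (sss, 8, 0.3)]
        )
        pmap = fw.phase_map(series, np.ones(shape, dtype=bool))
        table = fw.arteriovenous_delays(
            pmap, self._rois(shape, terr, sss), stats_1s, method="voxel_min"
        )
        assert np.all(table.delay_phases == 5)  # (8-4) - (3-4) = 5

    def test_empty_roi_errors(self, stats_1s):
        shape = (24, 24)
        series = synthetic_series(shape=shape, peaks=None)
        pmap = fw.phase_map(series, np.ones(shape, dtype=bool))
        rois = self._rois(shape, np.zeros(shape, bool), np.ones(shape, bool))
        with pytest.raises(RoiError, match="aca_l"):
            fw.arteriovenous_delays(pmap, rois, stats_1s)

    def test_phantom_delay_recovered(self, small_truth, small_gated):
        """MCA arrival 200 ms, sinus 600 ms: 400 ms delay within one phase."""
        stats = small_gated["stats"]
        pmap = fw.phase_map(small_gated["filtered"], small_gated["mask"])
        rois = small_truth.roi_set(erode_vessels=1).resize_to(
            small_gated["filtered"].grid
        )
        table = fw.arteriovenous_delays(
            pmap, rois, stats, series=small_gated["filtered"]
        )
        mca = table.set_index("territory").loc["mca_l", "delay_ms"]
        assert abs(mca - 400.0) <= fw.phase_duration(stats, 15)


class TestAmplitudeMaps:
    def test_min_phase_map_is_zero(self, small_gated):
        amps = fw.amplitude_maps(small_gated["filtered"], small_gated["mask"])
        assert np.all(amps.per_phase[amps.min_phase] == 0)

    def test_static_series_all_zero(self):
        images = np.ones((15, 16, 16))
        series = PhaseResolvedSeries(images, (16, 16))
        amps = fw.amplitude_maps(series, np.ones((16, 16), dtype=bool))
        assert np.all(amps.per_phase == 0)

    def test_gray_white_amplitude_ratio_recovered(self):
        """Gray modulating twice as much as white: ratio lands in [1.6, 2.4]."""
        truth = fw.make_phantom(
            fw.PhantomConfig(
                n_pe=64, n_fe=64, n_coils=2,
                baseline={"gray": 1.0, "white": 1.0},
                modulation_amplitude={"gray": 0.012, "white": 0.006},
            )
        )
        acq = fw.AcquisitionConfig(
            n_pe=64, n_fe=64, n_repetitions=200, n_coils=2, noise_sd=0.01, seed=2
        )
        pmu = fw.simulate_pmu(1000.0, 0.0, acq.total_duration_ms, acq.tr_ms, seed=2)
        ks = fw.simulate_kspace(truth, pmu, acq)
        series, trace, _ = fw.discard_steady_state(ks, pmu, 10)
        stats = fw.detect_pmu_peaks(trace)
        gated = fw.bin_and_average(series, fw.assign_phases(trace, stats))
        phases = fw.reconstruct_phase_images(gated, upsample_to=None)
        mask = truth.brain_mask
        amps = fw.amplitude_maps(phases, mask)
        rois = truth.roi_set(erode=2)
        ratio = (
            amps.comparison_map[rois["gray"]].mean()
            / amps.comparison_map[rois["white"]].mean()
        )
        assert 1.6 <= ratio <= 2.4

    def test_comparison_modes(self, small_gated):
        a = fw.amplitude_maps(small_gated["filtered"], small_gated["mask"])
        b = fw.amplitude_maps(
            small_gated["filtered"], small_gated["mask"], comparison_mode="voxel_max"
        )
        assert np.all(b.comparison_map >= a.comparison_map - 1e-12)


class TestSignalContrast:
    def test_zero_amplitude_zero_percent(self):
        series = PhaseResolvedSeries(np.ones((15, 8, 8)), (8, 8))
        mask = np.ones((8, 8), dtype=bool)
        amps = fw.amplitude_maps(series, mask)
        assert fw.signal_contrast(amps, np.ones((8, 8)), mask) == 0.0

    def test_half_percent_by_construction(self, small_gated):
        mean_img = np.full((8, 8), 2.0)
        amps = fw.amplitude_maps(
            PhaseResolvedSeries(np.ones((15, 8, 8)), (8, 8)),
            np.ones((8, 8), dtype=bool),
        )
        object.__setattr__(amps, "comparison_map", 0.005 * mean_img)
        assert fw.signal_contrast(
            amps, mean_img, np.ones((8, 8), dtype=bool)
        ) == pytest.approx(0.5)

    def test_gray_contrast_exceeds_white(self, small_truth, small_gated):
        amps = fw.amplitude_maps(small_gated["filtered"], small_gated["mask"])
        rois = small_truth.roi_set(erode=1).resize_to(small_gated["filtered"].grid)
        gray = fw.signal_contrast(amps, small_gated["rep"].mean_signal_image, rois["gray"])
        white = fw.signal_contrast(amps, small_gated["rep"].mean_signal_image, rois["white"])
        assert gray > white > 0


class TestPhaseToMs:
    @pytest.mark.parametrize(
        "phases, expected", [(1, 1000 / 15), (0, 0.0), (14, 14000 / 15)]
    )
    def test_values(self, stats_1s, phases, expected):
        assert fw.phase_to_ms(phases, stats_1s, 15) == pytest.approx(expected)

    def test_out_of_range_rejected(self, stats_1s):
        with pytest.raises(ConfigurationError):
            fw.phase_to_ms(15, stats_1s, 15)
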