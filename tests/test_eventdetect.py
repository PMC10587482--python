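"""Exocytosis detection, event profiles, distance maps, relocalization."""

import numpy as np
import pytest
from scipy import ndimage, stats

from vesikin import eventdetect as ed
from vesikin import motion_sim as ms
from vesikin import photokinetics as pk

PX = 0.11
DT = 0.5


def _grid_positions(n, lo=1.5, hi=9.0):
    side = int(np.ceil(np.sqrt(n)))
    xs = np.linspace(lo, hi, side)
    pts = np.array([(x, y) for y in xs for x in xs])
    return pts[:n]


class TestDetectEvents:
    def test_noise_only_movie_has_no_events(self):
        stack = ms.simulate_flash_movie(60, (100, 100), np.empty((0, 2)),
                                        np.empty(0, int), seed=0)
        events, rate = ed.detect_events(stack, np.ones((100, 100), bool), PX, DT)
        assert rate.n_events == 0

    def test_programmed_flashes_counted_and_rated(self):
        """10 flashes, 10x noise sd, in a 100 μm² mask over 2 min."""
        n_px = int(round(100.0 / PX**2))  # mask of exactly 100 μm²
        mask = np.zeros((100, 100), bool)
        mask.ravel()[:n_px] = True
        pos = _grid_positions(10)
        frames = np.arange(10) * 20 + 15
        stack = ms.simulate_flash_movie(240, (100, 100), pos, frames,
                                        pixel_size=PX, frame_interval=DT,
                                        amplitude=50.0, noise_sd=5.0, seed=1)
        events, rate = ed.detect_events(stack, mask, PX, DT)
        assert rate.n_events == 10
        assert rate.cell_area == pytest.approx(100.0, rel=1e-4)
        assert rate.rate == pytest.approx(0.05, rel=1e-4)

    def test_poisson_rate_recovered_within_counting_error(self):
        rng = np.random.default_rng(4)
        true_rate = 0.5  # events per μm² per min
        area = 11.0 * 11.0 * PX**2 / PX**2  # use full 121 μm² field
        duration_min = 2.0
        lam = true_rate * 121.0 * duration_min
        n = rng.poisson(lam)
        pos = _grid_positions(n, lo=1.0, hi=9.9)
        frames = np.sort(rng.integers(8, 232, size=n))
        stack = ms.simulate_flash_movie(240, (100, 100), pos, frames,
                                        pixel_size=PX, frame_interval=DT,
                                        amplitude=60.0, noise_sd=4.0, seed=5)
        events, rate = ed.detect_events(stack, np.ones((100, 100), bool), PX, DT)
        tol = 2 * np.sqrt(n) / (121.0 * duration_min)  # Poisson counting error
        assert rate.rate == pytest.approx(true_rate, abs=tol)

    def test_empty_mask_rejected(self):
        stack = np.zeros((12, 8, 8))
        with pytest.raises(ValueError, match="mask"):
            ed.detect_events(stack, np.zeros((8, 8), bool), PX, DT)

    def test_invariant_to_global_intensity_scaling(self):
        pos = _grid_positions(6)
        frames = np.arange(6) * 30 + 20
        stack = ms.simulate_flash_movie(220, (100, 100), pos, frames,
                                        pixel_size=PX, amplitude=60.0,
                                        noise_sd=3.0, seed=7).astype(float)
        mask = np.ones((100, 100), bool)
        _, r1 = ed.detect_events(stack, mask, PX, DT, maxima_prominence=20)
        _, r2 = ed.detect_events(stack * 2.0, mask, PX, DT, maxima_prominence=40)
        assert r1.n_events == r2.n_events


class TestEventProfiles:
    def _identical_events(self, n=5):
        pos = _grid_positions(n, lo=2.0, hi=8.0)
        frames = np.full(n, 40)
        stack = ms.simulate_flash_movie(90, (100, 100), pos, frames,
                                        pixel_size=PX, frame_interval=DT,
                                        amplitude=80.0, rise_frames=2,
                                        decay_frames=6, noise_sd=0.01, seed=0)
        events, _ = ed.detect_events(stack, np.ones((100, 100), bool), PX, DT)
        return events

    def test_identical_flashes_have_zero_spread(self):
        events = self._identical_events()
        assert len(events) == 5
        prof = ed.event_profiles(events, DT, window=4.0)
        assert np.nanmax(prof["sd_trace"]) < 0.02
        # linear ramp over (rise_frames + 1) intervals: 10->90% spans 80%
        assert prof["rise_time"] == pytest.approx(0.8 * 3 * DT, rel=0.2)

    def test_amplitude_statistics_match_programmed_distribution(self):
        rng = np.random.default_rng(1)
        n = 16
        amps = rng.uniform(40.0, 120.0, n)
        pos = _grid_positions(n, lo=1.5, hi=9.5)
        frames = rng.integers(15, 200, n)
        base = 100.0
        stacks = [
            ms.simulate_flash_movie(220, (100, 100), pos[i], [frames[i]],
                                    pixel_size=PX, amplitude=amps[i],
                                    noise_sd=0.5, seed=int(i))
            for i in range(n)
        ]
        stack = (np.stack(stacks).astype(float).sum(axis=0)
                 - (n - 1) * base).clip(0).astype(np.uint16)
        events, _ = ed.detect_events(stack, np.ones((100, 100), bool), PX, DT)
        prof = ed.event_profiles(events, DT)
        got = np.sort(prof["amplitudes"])
        want = np.sort(amps / base)
        assert len(got) == n
        assert np.corrcoef(got, want)[0, 1] > 0.98

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            ed.event_profiles([], DT)

    def test_location_test_type_one_error(self):
        """Two event-amplitude samples from the same distribution: a
        two-sample location test at alpha=0.05 stays non-significant in
        >= 93/100 simulations."""
        rng = np.random.default_rng(9)
        non_sig = 0
        for _ in range(100):
            a = rng.lognormal(0.0, 0.3, 40)
            b = rng.lognormal(0.0, 0.3, 40)
            if stats.ttest_ind(a, b, equal_var=False).pvalue > 0.05:
                non_sig += 1
        assert non_sig >= 93


class TestDistanceMap:
    def test_hand_enumerable_single_voxel(self):
        target = np.zeros((3, 3, 3), bool)
        target[1, 1, 1] = True
        cell = np.ones((3, 3, 3), bool)
        res = ed.distance_map(target, cell, 1.0)
        assert len(res.voxel_distances) == 26
        assert res.median_distance == pytest.approx(np.sqrt(2))
        counts = {1.0: 6, round(np.sqrt(2), 6): 12, round(np.sqrt(3), 6): 8}
        got = {}
        for d in res.voxel_distances:
            got[round(d, 6)] = got.get(round(d, 6), 0) + 1
        assert got == counts

    def test_target_filling_cell_rejected(self):
        full = np.ones((4, 4, 4), bool)
        with pytest.raises(ValueError, match="measurable"):
            ed.distance_map(full, full, 1.0)

    def test_matches_brute_force_on_coarse_grid(self):
        """Random target spheres in a spherical cell: EDT median equals a
        brute-force all-pairs nearest-distance computation."""
        rng = np.random.default_rng(3)
        n = 16
        zz, yy, xx = np.mgrid[:n, :n, :n]
        center = (n - 1) / 2
        cell = (zz - center) ** 2 + (yy - center) ** 2 + (xx - center) ** 2 <= (n / 2) ** 2
        target = np.zeros_like(cell)
        for _ in range(4):
            c = rng.uniform(4, n - 4, 3)
            target |= ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= 4.0
        target &= cell
        voxel = (0.3, 0.2, 0.2)
        res = ed.distance_map(target, cell, voxel)
        t_pts = np.column_stack(np.nonzero(target)) * voxel
        m_pts = np.column_stack(np.nonzero(cell & ~target)) * voxel
        brute = np.array([np.min(np.linalg.norm(t_pts - p, axis=1)) for p in m_pts])
        assert res.median_distance == pytest.approx(np.median(brute), rel=1e-9)

    def test_median_robust_to_cell_boundary_dilation(self):
        rng = np.random.default_rng(5)
        n = 24
        zz, yy, xx = np.mgrid[:n, :n, :n]
        c = (n - 1) / 2
        cell = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= (n / 2 - 2) ** 2
        target = rng.random(cell.shape) < 0.02
        target &= cell
        res1 = ed.distance_map(target, cell, 1.0)
        dilated = ndimage.binary_dilation(cell)
        res2 = ed.distance_map(target, dilated, 1.0)
        assert res2.median_distance == pytest.approx(res1.median_distance, rel=0.10)


class TestMeasureRelocalization:
    @staticmethod
    def _stack(values, shape=(20, 20)):
        stack = np.zeros((len(values),) + shape)
        mask = np.zeros(shape, bool)
        mask[5:15, 5:15] = True
        bg_mask = np.zeros(shape, bool)
        bg_mask[:3, :3] = True
        for f, v in enumerate(values):
            stack[f][mask] = v
            stack[f][bg_mask] = 10.0
        return stack, mask, bg_mask

    def test_exponential_relocalization_fit(self):
        t = np.arange(0, 200, 2.0)
        tau = 38.6
        values = 100.0 * (1 + 0.8 * (1 - np.exp(-t / tau))) + 10.0
        stack, mask, bg = self._stack(values)
        curve = ed.measure_relocalization(stack, mask, bg, 1, frame_interval=2.0)
        fit = pk.fit_exponential(curve)
        assert fit.tau == pytest.approx(tau, rel=1e-6)

    def test_constant_stack_rejected_by_fit(self):
        stack, mask, bg = self._stack(np.full(30, 120.0))
        curve = ed.measure_relocalization(stack, mask, bg, 3)
        assert np.allclose(curve.intensity, 1.0)
        with pytest.raises(RuntimeError, match="flat"):
            pk.fit_exponential(curve)

    def test_mask_erosion_leaves_curve_unchanged(self):
        t = np.arange(0, 100, 2.0)
        values = 100.0 * (1 + 0.5 * (1 - np.exp(-t / 20))) + 10.0
        stack, mask, bg = self._stack(values)
        eroded = ndimage.binary_erosion(mask)
        c1 = ed.measure_relocalization(stack, mask, bg, 1, frame_interval=2.0)
        c2 = ed.measure_relocalization(stack, eroded, bg, 1, frame_interval=2.0)
        assert np.allclose(c1.intensity, c2.intensity, atol=1e-9)
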