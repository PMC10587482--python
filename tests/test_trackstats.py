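"""Per-track mobility statistics against brute-force oracles and closed
forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesikin import motion_sim as ms
from vesikin import trackstats as ts
from vesikin.trackcore import Track, TrackDataset

from conftest import brownian_track


def brute_force_msd(track):
    """O(N²) enumeration of all frame-lag displacement pairs."""
    frames = track.frames - track.frames[0]
    acc = {}
    for i in range(track.n_points):
        for j in range(i + 1, track.n_points):
            lag = int(frames[j] - frames[i])
            acc.setdefault(lag, []).append(
                float(np.sum((track.positions[j] - track.positions[i]) ** 2))
            )
    dt = track.duration / frames[-1]
    lags = sorted(acc)
    return (np.array([k * dt for k in lags]),
            np.array([np.mean(acc[k]) for k in lags]))


class TestTimeAvgMsd:
    def test_ballistic_closed_form(self, straight_track):
        v = 1.0
        curve = ts.time_avg_msd(straight_track, 1.0)
        assert np.allclose(curve.msd, (v * curve.lags) ** 2)

    def test_constant_position_zero(self):
        t = Track(id="0", frames=np.arange(4), times=np.arange(4.0),
                  positions=np.ones((4, 2)))
        assert np.all(ts.time_avg_msd(t, 1.0).msd == 0.0)

    def test_three_point_hand_enumeration(self):
        t = Track(id="0", frames=[0, 1, 2], times=[0.0, 1.0, 2.0],
                  positions=[[0, 0], [1, 0], [1, 1]])
        curve = ts.time_avg_msd(t, 1.0)
        assert curve.msd == pytest.approx([1.0, 2.0])
        assert list(curve.n_pairs) == [2, 1]

    def test_too_short_track_rejected(self):
        t = Track(id="0", frames=[0, 1], times=[0.0, 1.0],
                  positions=[[0, 0], [1, 1]])
        with pytest.raises(ValueError, match=">= 3"):
            ts.time_avg_msd(t)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 100))
        t = brownian_track(0.2, n, 0.06, seed)
        if seed % 2:  # knock out some frames to create gaps
            keep = np.sort(rng.choice(n + 1, size=max(4, n // 2), replace=False))
            t = Track(id="g", frames=t.frames[keep], times=t.times[keep],
                      positions=t.positions[keep])
        curve = ts.time_avg_msd(t, 1.0)
        lags, msd = brute_force_msd(t)
        assert np.allclose(curve.lags, lags)
        assert np.allclose(curve.msd, msd)


class TestFitAlphaD:
    def test_normal_diffusion_printed_parameters(self):
        lags = np.arange(1, 9) * 0.06
        curve = ts.MSDCurve(lags, 4 * 0.104 * lags, np.ones(8, int))
        alpha, D = ts.fit_alpha_D(curve)
        assert alpha == pytest.approx(1.0, abs=1e-9)
        assert D == pytest.approx(0.104, abs=1e-9)

    def test_ballistic_exponent(self):
        lags = np.arange(1, 9) * 0.1
        curve = ts.MSDCurve(lags, (1.5 * lags) ** 2, np.ones(8, int))
        alpha, _ = ts.fit_alpha_D(curve)
        assert alpha == pytest.approx(2.0, abs=1e-9)

    def test_subdiffusive_exponent(self):
        lags = np.arange(1, 9) * 0.06
        curve = ts.MSDCurve(lags, 4 * 0.2 * lags**0.5, np.ones(8, int))
        alpha, D = ts.fit_alpha_D(curve)
        assert alpha == pytest.approx(0.5, abs=1e-9)
        assert D == pytest.approx(0.2, abs=1e-9)

    def test_nonpositive_lags_excluded(self):
        lags = np.arange(1, 5) * 0.06
        curve = ts.MSDCurve(lags, [0.0, 0.0, 0.0, 0.1], np.ones(4, int))
        with pytest.raises(ValueError, match="usable"):
            ts.fit_alpha_D(curve)


class TestEfficiency:
    def test_straight_track_is_one(self, straight_track):
        assert ts.efficiency(straight_track) == pytest.approx(1.0)

    def test_closed_loop_is_zero(self):
        square = [[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]
        t = Track(id="0", frames=np.arange(5), times=np.arange(5.0),
                  positions=square)
        assert ts.efficiency(t) == pytest.approx(0.0)

    def test_hand_enumerated_zigzag(self):
        t = Track(id="0", frames=np.arange(4), times=np.arange(4.0),
                  positions=[[0, 0], [1, 0], [0, 0], [1, 0]])
        assert ts.efficiency(t) == pytest.approx(1.0 / 9.0)

    def test_immobile_track_zero_by_convention(self):
        t = Track(id="0", frames=np.arange(3), times=np.arange(3.0),
                  positions=np.ones((3, 2)))
        assert ts.efficiency(t) == 0.0

    @given(angle=st.floats(0, 2 * np.pi), dx=st.floats(-50, 50),
           dy=st.floats(-50, 50), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rigid_motion_invariance(self, angle, dx, dy, seed):
        t = brownian_track(0.3, 15, 0.06, seed)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = Track(id="m", frames=t.frames, times=t.times,
                      positions=t.positions @ rot.T + [dx, dy])
        assert ts.efficiency(moved) == pytest.approx(ts.efficiency(t), rel=1e-9)


class TestClassifyDirected:
    def _dataset(self, model, n, seed):
        return ms.simulate_tracks(model, n=n, extent=100, seed=seed)

    def test_all_ballistic_fraction_one(self):
        model = ms.MotionModel(v=1.0, state_set=(ms.DIRECTED,), dt=0.06,
                               duration=1.2)
        _, frac = ts.classify_directed(self._dataset(model, 50, 0), 0.142)
        assert frac == 1.0

    def test_all_immobile_fraction_zero(self):
        model = ms.MotionModel(state_set=(ms.IMMOBILE,), dt=0.06, duration=1.2)
        _, frac = ts.classify_directed(self._dataset(model, 50, 0), 0.142)
        assert frac == 0.0

    def test_mixed_set_fraction_near_truth(self):
        """10% ballistic / 90% Brownian: the directed fraction should sit
        near 0.10 plus the Brownian false-positive rate, which we estimate
        with an independent Monte-Carlo enumeration of the null."""
        threshold, n_steps, D, dt = 0.181, 20, 0.3, 0.06
        rng = np.random.default_rng(11)
        # brute-force null: efficiency of pure Brownian 20-step tracks
        steps = rng.normal(0, np.sqrt(2 * D * dt), size=(20_000, n_steps, 2))
        pos = np.cumsum(steps, axis=1)
        net_sq = np.sum(pos[:, -1] ** 2, axis=1)
        sum_sq = np.sum(steps**2, axis=(1, 2))
        null_eff = net_sq / (n_steps * sum_sq)
        fp_rate = float((null_eff > threshold).mean())

        n_total, n_dir = 1000, 100
        bro = ms.simulate_tracks(
            ms.MotionModel(D=D, state_set=(ms.BROWNIAN,), dt=dt,
                           duration=n_steps * dt),
            n=n_total - n_dir, extent=500, seed=1)
        bal = ms.simulate_tracks(
            ms.MotionModel(v=1.0, state_set=(ms.DIRECTED,), dt=dt,
                           duration=n_steps * dt),
            n=n_dir, extent=500, seed=2)
        ds = bro.with_tracks(list(bro.tracks) + list(bal.tracks))
        _, frac = ts.classify_directed(ds, threshold)
        expected = 0.1 + 0.9 * fp_rate
        sd = np.sqrt(expected * (1 - expected) / n_total)
        assert abs(frac - expected) < 4 * sd


class TestFeatures:
    def test_lone_track_has_no_neighbours(self, straight_track):
        ds = TrackDataset([straight_track], frame_interval=1.0)
        row = ts.features(ds).iloc[0]
        assert row["neighbours"] == 0.0
        assert row["density"] == 0.0

    def test_neighbour_to_density_conversion(self):
        assert 17.5 / np.pi == pytest.approx(5.57, abs=0.005)

    def test_straight_track_geometry(self, straight_track):
        ds = TrackDataset([straight_track], frame_interval=1.0)
        row = ts.features(ds).iloc[0]
        assert row["cumdist"] == pytest.approx(10.0)
        assert row["wide"] == pytest.approx(10.0)
        assert row["speed"] == pytest.approx(10.0 / row["cumtime"])
        assert row["fd"] == pytest.approx(1.0)

    def test_wide_never_exceeds_cumdist(self):
        model = ms.MotionModel(D=0.3, switch_rate=2.0, dt=0.06, duration=3.0)
        ds = ms.simulate_tracks(model, n=30, seed=4)
        table = ts.features(ds)
        assert (table["wide"] <= table["cumdist"] + 1e-9).all()

    def test_neighbours_counted_within_radius(self):
        tracks = []
        for i, x in enumerate([0.0, 0.5, 5.0]):
            pos = np.tile([x, 0.0], (3, 1)) + [[0, 0], [0.01, 0], [0.02, 0]]
            tracks.append(Track(id=str(i), frames=np.arange(3),
                                times=np.arange(3) * 0.06, positions=pos))
        ds = TrackDataset(tracks, frame_interval=0.06)
        table = ts.features(ds)
        assert list(table["neighbours"]) == [1.0, 1.0, 0.0]


def test_brownian_population_alpha_and_D():
    """Simulated Brownian datasets recover the generative D and a median
    MSD exponent near 1 (normal diffusion)."""
    D = 0.2
    model = ms.MotionModel(D=D, state_set=(ms.BROWNIAN,), dt=0.06, duration=3.0)
    ds = ms.simulate_tracks(model, n=200, extent=60, seed=8)
    alphas, Ds = [], []
    for t in ds:
        a, d = ts.fit_alpha_D(ts.time_avg_msd(t))
        alphas.append(a)
        Ds.append(d)
    assert 0.9 <= np.median(alphas) <= 1.1
    assert np.median(Ds) == pytest.approx(D, rel=0.15)
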